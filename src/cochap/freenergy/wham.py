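"""Weighted histogram analysis of umbrella-sampling windows.

The self-consistent WHAM equations for windows i with n_i samples and
restraint energies U_i evaluated at bin centres b are

    p(b) = H(b) / sum_i n_i exp((F_i - U_i(b)) / kT)
    F_i  = -kT ln sum_b p(b) exp(-U_i(b) / kT),

iterated to a fixed point.  The unbiased profile is F(b) = -kT ln p(b),
re-zeroed at its minimum; unvisited bins are +inf and never extrapolated.
Uncertainties come from a Monte Carlo bootstrap that resamples each
window's samples with replacement and re-solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .._rng import stream
from ..constants import KB
from .surface import FreeEnergySurface
from .windows import UmbrellaWindowSet

__all__ = ["WHAM", "WHAMResults", "wham", "bootstrap_wham_errors"]


def _solve(
    counts: np.ndarray,      # (n_bins,) pooled histogram
    n_samples: np.ndarray,   # (n_windows,)
    exp_bias: np.ndarray,    # (n_windows, n_bins) exp(-U_i(b)/kT)
    kT: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Return (probability per bin, offsets F_i, converged, n_iter)."""
    n_windows = len(n_samples)
    f = np.zeros(n_windows)
    visited = counts > 0
    p = np.zeros_like(counts, dtype=float)
    for it in range(1, max_iter + 1):
        a = np.exp(f / kT)  # (n_windows,)
        denom = (n_samples * a) @ exp_bias  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(visited & (denom > 0), counts / np.maximum(denom, 1e-300), 0.0)
        p_sum = p.sum()
        if p_sum <= 0:
            raise ValueError("WHAM produced an empty distribution")
        p /= p_sum
        z = exp_bias @ p
        f_new = -kT * np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return p, f, True, it
    return p, f, False, max_iter


@dataclass
class WHAMResults:
    fes: FreeEnergySurface
    offsets: np.ndarray          # per-window free energies F_i (kJ/mol)
    converged: bool
    n_iter: int
    model: "WHAM" = field(repr=False, default=None)

    def bootstrap(self, n_boot: int, seed: int, resample: bool = True) -> np.ndarray:
        """Per-bin standard error of the profile from a Monte Carlo bootstrap.

        ``resample=False`` re-solves on the original samples (a degenerate
        bootstrap whose spread is exactly zero; useful for validation).
        """
        return self.model.bootstrap_errors(n_boot, seed, resample=resample)

    def summary(self) -> str:
        finite = np.isfinite(self.fes.values)
        return "\n".join([
            f"windows: {len(self.offsets)}",
            f"bins: {len(self.fes.axes[0])} ({int(finite.sum())} visited)",
            f"converged: {self.converged} after {self.n_iter} iterations",
            "window offsets F_i (kJ/mol): "
            + ", ".join(f"{v:.4f}" for v in self.offsets),
            f"profile range (kJ/mol): 0 .. {self.fes.values[finite].max():.4f}",
        ])


class WHAM:
    """WHAM estimator for one :class:`UmbrellaWindowSet`."""

    def __init__(
        self,
        windows: UmbrellaWindowSet,
        n_bins: int = 100,
        bin_range: Optional[tuple[float, float]] = None,
    ):
        self.windows = windows
        self.n_bins = int(n_bins)
        pooled = windows.pooled_samples()
        lo, hi = bin_range if bin_range is not None else (pooled.min(), pooled.max())
        if not hi > lo:
            hi = lo + 1e-9
        self.edges = np.linspace(lo, hi, self.n_bins + 1)
        self.centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        self.kT = KB * windows.temperature
        self._exp_bias = np.stack(
            [np.exp(-w.bias(self.centers) / self.kT) for w in windows.windows]
        )

    def _histogram(self, samples_list) -> np.ndarray:
        counts = np.zeros(self.n_bins)
        for samples in samples_list:
            counts += np.histogram(samples, bins=self.edges)[0]
        return counts

    def _check_support(self, counts: np.ndarray) -> None:
        """Reject histograms whose sampled region splits into separated
        islands: the free-energy offset across an unsampled gap would be
        an extrapolation.  Islands holding <5% of the samples (stray
        excursions) are tolerated."""
        if not (counts > 0).any():
            raise ValueError("no samples fall inside the histogram range")
        visited = counts > 0
        islands = []
        start = None
        for i, v in enumerate(visited):
            if v and start is None:
                start = i
            if not v and start is not None:
                islands.append((start, i - 1))
                start = None
        if start is not None:
            islands.append((start, len(visited) - 1))
        total = counts.sum()
        major = [
            isl for isl in islands if counts[isl[0]: isl[1] + 1].sum() >= 0.05 * total
        ]
        if len(major) > 1:
            gap_lo = self.edges[major[0][1] + 1]
            gap_hi = self.edges[major[1][0]]
            raise ValueError(
                "histogram support is disconnected: empty gap in "
                f"[{gap_lo:.4g}, {gap_hi:.4g}] nm"
            )

    def fit(self, tol: float = 1e-8, max_iter: int = 100_000) -> WHAMResults:
        samples = [w.samples for w in self.windows.windows]
        counts = self._histogram(samples)
        self._check_support(counts)
        n_samples = np.array([len(s) for s in samples], dtype=float)
        p, f, converged, n_iter = _solve(
            counts, n_samples, self._exp_bias, self.kT, tol, max_iter
        )
        values = np.where(p > 0, -self.kT * np.log(np.maximum(p, 1e-300)), np.inf)
        fes = FreeEnergySurface(
            axes=(self.centers,), values=values, temperature=self.windows.temperature
        )
        return WHAMResults(fes=fes, offsets=f, converged=converged,
                           n_iter=n_iter, model=self)

    def bootstrap_errors(
        self, n_boot: int, seed: int, resample: bool = True,
        tol: float = 1e-8, max_iter: int = 100_000,
    ) -> np.ndarray:
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        rng = stream(seed, "wham-bootstrap")
        n_samples = np.array(
            [len(w.samples) for w in self.windows.windows], dtype=float
        )
        profiles = np.full((n_boot, self.n_bins), np.nan)
        for b in range(n_boot):
            if resample:
                samples = [
                    w.samples[rng.integers(len(w.samples), size=len(w.samples))]
                    for w in self.windows.windows
                ]
            else:
                samples = [w.samples for w in self.windows.windows]
            counts = self._histogram(samples)
            p, _, _, _ = _solve(
                counts, n_samples, self._exp_bias, self.kT, tol, max_iter
            )
            vals = np.where(p > 0, -self.kT * np.log(np.maximum(p, 1e-300)), np.nan)
            finite = np.isfinite(vals)
            if finite.any():
                vals = vals - vals[finite].min()
            profiles[b] = vals
        return np.nanstd(profiles, axis=0, ddof=1)


def wham(
    windows: UmbrellaWindowSet,
    n_bins: int = 100,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[FreeEnergySurface, np.ndarray]:
    """Functional wrapper: (1D profile, per-window offsets F_i)."""
    res = WHAM(windows, n_bins=n_bins).fit(tol=tol, max_iter=max_iter)
    if not res.converged:
        raise RuntimeError(f"WHAM did not converge in {res.n_iter} iterations")
    return res.fes, res.offsets


def bootstrap_wham_errors(
    windows: UmbrellaWindowSet, n_boot: int, seed: int, n_bins: int = 100
) -> np.ndarray:
    return WHAM(windows, n_bins=n_bins).bootstrap_errors(n_boot, seed)
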