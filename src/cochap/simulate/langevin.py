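"""Overdamped Langevin sampling: umbrella windows and 2D metadynamics.

The integrator is Euler-Maruyama for the overdamped Langevin equation

    dx = -grad(U)/friction dt + sqrt(2 kT dt / friction) xi,

adequate for one or two collective variables.  Umbrella sampling runs all
windows as a vectorized walker array.  Well-tempered metadynamics keeps
the accumulated bias (and its analytic gradient) on a regular grid that
is updated at each Gaussian deposition and bilinearly interpolated for
the force; the hot inner loop is numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .._rng import stream
from ..constants import KB
from ..freenergy.surface import BiasGrid
from ..freenergy.windows import UmbrellaWindow, UmbrellaWindowSet
from .config import SimulationConfig

__all__ = ["sample_umbrella_windows", "run_wt_metadynamics", "MetadynamicsRun"]


def sample_umbrella_windows(
    potential,
    centers: Sequence[float],
    spring_k: float,
    config: SimulationConfig,
    n_equil: int = 2000,
) -> UmbrellaWindowSet:
    """Sample every harmonic window under ``potential`` + restraint.

    Walkers start at their window centres and are equilibrated for
    ``n_equil`` unrecorded steps; ``config.n_steps`` samples per window
    are then recorded at every step.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size < 1:
        raise ValueError("need at least one window")
    if config.n_steps == 0:
        raise ValueError("n_steps must be positive")
    if not spring_k >= 0:
        raise ValueError("spring_k must be >= 0")
    rng = stream(config.seed, "umbrella")
    dt, kT, gamma = config.langevin_dt, config.langevin_kT, config.langevin_friction
    noise_scale = np.sqrt(2.0 * kT * dt / gamma)

    x = centers.copy()
    samples = np.empty((centers.size, config.n_steps))
    total = n_equil + config.n_steps
    for step in range(total):
        force = -np.asarray(potential.grad(x)) - spring_k * (x - centers)
        x = x + force * dt / gamma + noise_scale * rng.standard_normal(centers.size)
        if step >= n_equil:
            samples[:, step - n_equil] = x
    windows = [
        UmbrellaWindow(center=float(c), spring_k=float(spring_k), samples=samples[i])
        for i, c in enumerate(centers)
    ]
    return UmbrellaWindowSet(windows=windows, temperature=config.langevin_kT / KB)


@dataclass
class MetadynamicsRun:
    """Trajectory and bias record of one well-tempered metadynamics run."""

    steps: np.ndarray       # recorded step indices
    cvs: np.ndarray         # (n_recorded, 2) coordinates
    bias: np.ndarray        # instantaneous bias at the walker (kJ/mol)
    bias_grid: BiasGrid     # final accumulated bias
    snapshots: list         # list of BiasGrid taken at regular intervals


@njit(cache=False)
def _metad_core(
    x0, y0, n_steps, dt, kT, gamma, noise,
    xs, ys, ux, uy,                 # static potential gradient on grid nodes
    hill_h, hill_w, stride, gamma_wt,
    v, vx, vy,                      # bias value/gradient grids (updated in place)
    record_stride, rec_xy, rec_bias,
    snapshot_stride, snaps,
):
    nx, ny = xs.shape[0], ys.shape[0]
    hx = xs[1] - xs[0]
    hy = ys[1] - ys[0]
    x, y = x0, y0
    noise_scale = np.sqrt(2.0 * kT * dt / gamma)
    cut = 4.0 * hill_w
    n_rec = 0
    n_snap = 0
    for step in range(n_steps):
        # bilinear interpolation of total gradient and bias at (x, y)
        fx = (x - xs[0]) / hx
        fy = (y - ys[0]) / hy
        i = int(fx)
        j = int(fy)
        if i < 0:
            i = 0
        if i > nx - 2:
            i = nx - 2
        if j < 0:
            j = 0
        if j > ny - 2:
            j = ny - 2
        tx = fx - i
        ty = fy - j
        if tx < 0.0:
            tx = 0.0
        if tx > 1.0:
            tx = 1.0
        if ty < 0.0:
            ty = 0.0
        if ty > 1.0:
            ty = 1.0
        w00 = (1 - tx) * (1 - ty)
        w10 = tx * (1 - ty)
        w01 = (1 - tx) * ty
        w11 = tx * ty
        gx = (
            w00 * (ux[i, j] + vx[i, j]) + w10 * (ux[i + 1, j] + vx[i + 1, j])
            + w01 * (ux[i, j + 1] + vx[i, j + 1]) + w11 * (ux[i + 1, j + 1] + vx[i + 1, j + 1])
        )
        gy = (
            w00 * (uy[i, j] + vy[i, j]) + w10 * (uy[i + 1, j] + vy[i + 1, j])
            + w01 * (uy[i, j + 1] + vy[i, j + 1]) + w11 * (uy[i + 1, j + 1] + vy[i + 1, j + 1])
        )
        vb = (
            w00 * v[i, j] + w10 * v[i + 1, j]
            + w01 * v[i, j + 1] + w11 * v[i + 1, j + 1]
        )

        if record_stride > 0 and step % record_stride == 0:
            rec_xy[n_rec, 0] = x
            rec_xy[n_rec, 1] = y
            rec_bias[n_rec] = vb
            n_rec += 1

        # deposition of a tempered Gaussian hill
        if hill_h > 0.0 and (step + 1) % stride == 0:
            h_t = hill_h * np.exp(-vb / ((gamma_wt - 1.0) * kT))
            i_lo = int((x - cut - xs[0]) / hx)
            i_hi = int((x + cut - xs[0]) / hx) + 1
            j_lo = int((y - cut - ys[0]) / hy)
            j_hi = int((y + cut - ys[0]) / hy) + 1
            if i_lo < 0:
                i_lo = 0
            if j_lo < 0:
                j_lo = 0
            if i_hi > nx - 1:
                i_hi = nx - 1
            if j_hi > ny - 1:
                j_hi = ny - 1
            inv2w2 = 1.0 / (2.0 * hill_w * hill_w)
            for ii in range(i_lo, i_hi + 1):
                dx_ = xs[ii] - x
                ex = np.exp(-dx_ * dx_ * inv2w2)
                for jj in range(j_lo, j_hi + 1):
                    dy_ = ys[jj] - y
                    g = h_t * ex * np.exp(-dy_ * dy_ * inv2w2)
                    v[ii, jj] += g
                    vx[ii, jj] += -dx_ / (hill_w * hill_w) * g
                    vy[ii, jj] += -dy_ / (hill_w * hill_w) * g

        if snapshot_stride > 0 and (step + 1) % snapshot_stride == 0 and n_snap < snaps.shape[0]:
            for ii in range(nx):
                for jj in range(ny):
                    snaps[n_snap, ii, jj] = v[ii, jj]
            n_snap += 1

        # Euler-Maruyama update with reflective walls at the grid edges
        x = x - gx * dt / gamma + noise_scale * noise[step, 0]
        y = y - gy * dt / gamma + noise_scale * noise[step, 1]
        if x < xs[0]:
            x = 2.0 * xs[0] - x
        if x > xs[nx - 1]:
            x = 2.0 * xs[nx - 1] - x
        if y < ys[0]:
            y = 2.0 * ys[0] - y
        if y > ys[ny - 1]:
            y = 2.0 * ys[ny - 1] - y
    return n_rec, n_snap


def run_wt_metadynamics(
    potential2d,
    config: SimulationConfig,
    x_range: tuple[float, float] = (-0.35, 0.35),
    y_range: tuple[float, float] = (-0.25, 0.25),
    grid_spacing: float = 0.01,
    start: tuple[float, float] = None,
    record_stride: int = 10,
    n_snapshots: int = 0,
) -> MetadynamicsRun:
    """Well-tempered 2D metadynamics on an analytic potential.

    Gaussians of height ``config.hill_height`` (tempered by
    exp(-V/((gamma-1) kT)) with gamma = ``config.bias_factor``) and width
    ``config.hill_width`` are deposited every ``config.deposition_stride``
    steps.  ``n_snapshots`` > 0 additionally records evenly spaced copies
    of the accumulated bias for block averaging.
    """
    if not config.hill_width > 0:
        raise ValueError("hill_width must be positive")
    if not config.bias_factor > 1:
        raise ValueError("bias_factor must be > 1")
    rng = stream(config.seed, "metadynamics")
    xs = np.arange(x_range[0], x_range[1] + grid_spacing / 2, grid_spacing)
    ys = np.arange(y_range[0], y_range[1] + grid_spacing / 2, grid_spacing)
    XY = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    grads = np.asarray(potential2d.grad(XY))
    ux, uy = grads[..., 0].copy(), grads[..., 1].copy()

    v = np.zeros((len(xs), len(ys)))
    vx = np.zeros_like(v)
    vy = np.zeros_like(v)

    n_steps = config.n_steps
    noise = rng.standard_normal((max(n_steps, 1), 2))
    n_rec = (n_steps + record_stride - 1) // record_stride if record_stride > 0 else 0
    rec_xy = np.zeros((max(n_rec, 1), 2))
    rec_bias = np.zeros(max(n_rec, 1))
    snapshot_stride = n_steps // n_snapshots if n_snapshots > 0 else 0
    snaps = np.zeros((max(n_snapshots, 1), len(xs), len(ys)))

    if start is None:
        start = (-abs(getattr(potential2d, "x0", xs.mean())), 0.0)

    n_rec_out, n_snap_out = _metad_core(
        float(start[0]), float(start[1]), n_steps,
        config.langevin_dt, config.langevin_kT, config.langevin_friction, noise,
        xs, ys, ux, uy,
        config.hill_height, config.hill_width, config.deposition_stride,
        config.bias_factor,
        v, vx, vy,
        record_stride, rec_xy, rec_bias,
        snapshot_stride, snaps if n_snapshots > 0 else np.zeros((0, len(xs), len(ys))),
    )

    temperature = config.langevin_kT / KB
    bias_grid = BiasGrid(
        axes=(xs, ys), values=v, bias_factor=config.bias_factor,
        temperature=temperature,
    )
    snapshots = [
        BiasGrid(axes=(xs, ys), values=snaps[i].copy(),
                 bias_factor=config.bias_factor, temperature=temperature)
        for i in range(n_snap_out)
    ]
    steps = np.arange(0, n_steps, record_stride) if record_stride > 0 else np.zeros(0, int)
    return MetadynamicsRun(
        steps=steps[:n_rec_out],
        cvs=rec_xy[:n_rec_out],
        bias=rec_bias[:n_rec_out],
        bias_grid=bias_grid,
        snapshots=snapshots,
    )
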