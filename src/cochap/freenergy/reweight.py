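"""Reweighting of biased observables along a coordinate.

Umbrella-sampled frames are returned to the unbiased ensemble with the
factor exp((U_i(r) - F_i)/kT), where U_i(r) is the restraint energy of
the frame and F_i the window's WHAM offset.  Binned along the coordinate
this yields unbiased profiles of any observable (e.g. interdomain contact
counts against domain separation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..constants import KB

__all__ = ["reweight_observable"]


def reweight_observable(
    coordinate,
    observable,
    bias_energy,
    window_offset,
    temperature: float,
    bins,
) -> pd.DataFrame:
    """Per-bin unbiased weighted mean of an observable.

    Parameters are per-sample arrays (equal length): the coordinate value,
    the observable, the biasing energy U_i(r) of the sample's window at
    the sample, and the window offset F_i.  ``bins`` is an array of bin
    edges or an integer bin count over the sampled range.  Empty bins are
    reported with NaN mean and count 0, never as zero signal.
    """
    x = np.asarray(coordinate, dtype=float).ravel()
    y = np.asarray(observable, dtype=float).ravel()
    u = np.asarray(bias_energy, dtype=float).ravel()
    f = np.asarray(window_offset, dtype=float).ravel()
    if not (len(x) == len(y) == len(u) == len(f)):
        raise ValueError("all sample arrays must have equal length")
    kT = KB * temperature
    log_w = (u - f) / kT
    log_w -= log_w.max()  # common factor cancels inside each bin
    w = np.exp(log_w)

    if np.isscalar(bins):
        edges = np.linspace(x.min(), x.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    n_bins = len(edges) - 1
    idx = np.digitize(x, edges) - 1
    idx[x == edges[-1]] = n_bins - 1  # closed right edge
    inside = (idx >= 0) & (idx < n_bins)

    wsum = np.bincount(idx[inside], weights=w[inside], minlength=n_bins)
    wy = np.bincount(idx[inside], weights=(w * y)[inside], minlength=n_bins)
    count = np.bincount(idx[inside], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wsum > 0, wy / np.where(wsum > 0, wsum, 1.0), np.nan)
    return pd.DataFrame(
        {
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "mean": mean,
            "weight": wsum,
            "count": count,
        }
    )
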