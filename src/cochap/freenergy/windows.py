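"""Umbrella-sampling window containers and CSV I/O.

Each window holds a harmonic restraint (centre c in nm, spring constant k
in kJ/mol/nm^2, bias U(x) = 0.5 k (x - c)^2 + offset) and its scalar
collective-variable samples.  The CSV layout is long format with header
``window,center,spring_k,step,x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..constants import DEFAULT_TEMPERATURE

__all__ = ["UmbrellaWindow", "UmbrellaWindowSet"]


@dataclass
class UmbrellaWindow:
    center: float
    spring_k: float
    samples: np.ndarray
    energy_offset: float = 0.0  # additive constant of the bias (gauge)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")
        if len(self.samples) < 1:
            raise ValueError("window must contain at least one sample")

    def bias(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 0.5 * self.spring_k * (x - self.center) ** 2 + self.energy_offset


@dataclass
class UmbrellaWindowSet:
    windows: list[UmbrellaWindow]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not self.windows:
            raise ValueError("need at least one window")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def pooled_samples(self) -> np.ndarray:
        return np.concatenate([w.samples for w in self.windows])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.windows):
            rows.append(
                pd.DataFrame(
                    {
                        "window": i,
                        "center": w.center,
                        "spring_k": w.spring_k,
                        "step": np.arange(len(w.samples)),
                        "x": w.samples,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, temperature: float = DEFAULT_TEMPERATURE) -> "UmbrellaWindowSet":
        df = pd.read_csv(path)
        windows = []
        for _, grp in df.groupby("window", sort=True):
            windows.append(
                UmbrellaWindow(
                    center=float(grp["center"].iloc[0]),
                    spring_k=float(grp["spring_k"].iloc[0]),
                    samples=grp.sort_values("step")["x"].to_numpy(),
                )
            )
        return cls(windows=windows, temperature=temperature)
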