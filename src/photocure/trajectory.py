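"""Shared depth-and-time-resolved simulation output container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]

#: oxygen-depletion crossing threshold, as a fraction of Y0
INDUCTION_EPS = 1e-6


@dataclass
class Trajectory:
    """Concentration, intensity and efficacy fields on shared grids.

    Every entry of ``fields`` is an array of shape (nz, nt).
    """

    z_grid: np.ndarray
    t_grid: np.ndarray
    fields: dict[str, np.ndarray]
    A0: float
    diagnostics: dict[str, Any] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nz, nt = self.z_grid.size, self.t_grid.size
        for name, arr in self.fields.items():
            if arr.shape != (nz, nt):
                raise ValueError(
                    f"field {name!r} has shape {arr.shape}, expected {(nz, nt)}"
                )

    @property
    def efficacy(self) -> np.ndarray:
        """Conversion efficacy 1 - A/A0, clipped to [0, 1]."""
        return np.clip(1.0 - self.fields["A"] / self.A0, 0.0, 1.0)

    def at_depth(self, z: float) -> dict[str, np.ndarray]:
        """Time series of every field at the grid node nearest ``z``."""
        i = int(np.argmin(np.abs(self.z_grid - z)))
        out = {name: arr[i, :] for name, arr in self.fields.items()}
        out["efficacy"] = self.efficacy[i, :]
        return out

    def induction_times(self, Y0: float, eps_frac: float = INDUCTION_EPS) -> np.ndarray:
        """Per-depth time at which oxygen first drops below eps_frac * Y0.

        Linear interpolation between bracketing samples; NaN where the
        threshold is never crossed (or no oxygen channel exists).
        """
        out = np.full(self.z_grid.size, np.nan)
        if "O2" not in self.fields or Y0 <= 0:
            return out
        thr = eps_frac * Y0
        O2 = self.fields["O2"]
        t = self.t_grid
        for i in range(self.z_grid.size):
            below = np.nonzero(O2[i, :] <= thr)[0]
            if below.size == 0:
                continue
            j = below[0]
            if j == 0:
                out[i] = t[0]
            else:
                o0, o1 = O2[i, j - 1], O2[i, j]
                frac = (o0 - thr) / (o0 - o1) if o1 < o0 else 1.0
                out[i] = t[j - 1] + frac * (t[j] - t[j - 1])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: z_cm, t_s, one column per field, efficacy."""
        nz, nt = self.z_grid.size, self.t_grid.size
        data = {
            "z_cm": np.repeat(self.z_grid, nt),
            "t_s": np.tile(self.t_grid, nz),
        }
        for name in ("C", "T", "Rp", "R", "X", "O2", "A", "I"):
            if name in self.fields:
                data[name] = self.fields[name].ravel()
        data["efficacy"] = self.efficacy.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def summary(self, Y0: float | None = None) -> dict[str, Any]:
        out: dict[str, Any] = {
            "final_efficacy_by_depth": self.efficacy[:, -1].tolist(),
            "z_grid_cm": self.z_grid.tolist(),
            "t_end_s": float(self.t_grid[-1]),
        }
        if Y0 is not None:
            tind = self.induction_times(Y0)
            out["induction_time_by_depth_s"] = [
                None if np.isnan(x) else float(x) for x in tind
            ]
        out.update(self.diagnostics)
        return out
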