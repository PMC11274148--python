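"""Verification utilities: mesh-sensitivity analysis and CFL time-step choice.

The mesh study compares mean and maximum WSS of successively refined grids
against the finest one via relative percentage differences; a mesh is accepted
when both quantities are within tolerance. The CFL rule sizes the transient
time step from the smallest cell edge and the largest velocity and reports
whether it falls in the 0.5-2 ms band typical of patient-specific solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MeshStudy", "CFLResult", "sensitivity_curve", "select_mesh", "cfl_timestep"]

#: time-step band (s) reported by the CFL helper
CFL_BAND_S = (0.0005, 0.002)


@dataclass
class MeshStudy:
    """Element counts with mean and maximum WSS (Pa) per mesh."""

    n_elements: np.ndarray
    mean_wss_pa: np.ndarray
    max_wss_pa: np.ndarray

    def __post_init__(self) -> None:
        self.n_elements = np.asarray(self.n_elements, dtype=int)
        self.mean_wss_pa = np.asarray(self.mean_wss_pa, dtype=float)
        self.max_wss_pa = np.asarray(self.max_wss_pa, dtype=float)
        if len(self.n_elements) < 2:
            raise ValueError("a mesh study needs at least two meshes")
        if np.any(np.diff(self.n_elements) <= 0):
            raise ValueError("element counts must be strictly increasing")
        if len({len(self.n_elements), len(self.mean_wss_pa), len(self.max_wss_pa)}) != 1:
            raise ValueError("per-mesh arrays must have matching length")

    @classmethod
    def from_csv(cls, path) -> "MeshStudy":
        df = pd.read_csv(path)
        return cls(df["n_elements"], df["mean_wss_pa"], df["max_wss_pa"])


@dataclass(frozen=True)
class CFLResult:
    dt_s: float
    in_band: bool


def sensitivity_curve(study: MeshStudy) -> pd.DataFrame:
    """Relative % difference of each mesh against the finest one.

    rpd_i = 100 |x_i - x_finest| / |x_finest|; the finest row is 0 by
    construction.
    """
    for ref in (study.mean_wss_pa[-1], study.max_wss_pa[-1]):
        if ref == 0:
            raise ValueError("finest-mesh WSS is zero; relative difference undefined")
    rpd = lambda x: 100.0 * np.abs(x - x[-1]) / np.abs(x[-1])
    return pd.DataFrame(
        {
            "n_elements": study.n_elements,
            "rpd_mean_pct": rpd(study.mean_wss_pa),
            "rpd_max_pct": rpd(study.max_wss_pa),
        }
    )


def select_mesh(study: MeshStudy, tolerance_pct: float = 2.0) -> int:
    """Smallest mesh with BOTH mean and max WSS within tolerance of the finest.

    Falls back to the finest mesh (with a warning) if none qualifies.
    """
    curve = sensitivity_curve(study)
    ok = (curve["rpd_mean_pct"] <= tolerance_pct) & (curve["rpd_max_pct"] <= tolerance_pct)
    if not ok.any():
        warnings.warn(
            f"no mesh within {tolerance_pct}% of the finest; returning the finest",
            stacklevel=2,
        )
        return int(study.n_elements[-1])
    return int(study.n_elements[np.flatnonzero(ok.to_numpy())[0]])


def cfl_timestep(
    min_edge_m: float, max_velocity_m_s: float, courant: float = 1.0
) -> CFLResult:
    """dt = C h / u, with a flag for the 0.5-2 ms patient-specific band."""
    if max_velocity_m_s <= 0:
        raise ValueError("maximum velocity must be positive")
    if min_edge_m <= 0 or courant <= 0:
        raise ValueError("edge length and Courant number must be positive")
    dt = courant * min_edge_m / max_velocity_m_s
    return CFLResult(dt_s=dt, in_band=bool(CFL_BAND_S[0] <= dt <= CFL_BAND_S[1]))
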