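"""Flow partition and inter-lumen pressure analysis.

Covers the outflow boundary split (55% of time-averaged flow through the
descending aorta, the remainder divided among the arch branches by outlet
area), the false-lumen flow fraction at the systolic peak, and FL - TL
pressure-difference profiles along the descending aorta at the three cardiac
phases (systolic peak, systolic deceleration, diastolic peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PlaneSeries

__all__ = [
    "OutflowSplit",
    "PressureProfile",
    "CardiacPhases",
    "outflow_split",
    "fl_flow_fraction",
    "cardiac_phases",
    "pressure_difference_profile",
    "plot_pressure_profile",
]

DESCENDING_FLOW_FRACTION = 0.55


@dataclass(frozen=True)
class OutflowSplit:
    """Outlet flow fractions; descending + branches sum to 1 exactly."""

    descending: float
    branches: tuple[float, ...]

    def __post_init__(self) -> None:
        total = self.descending + sum(self.branches)
        if abs(total - 1.0) > 1e-12:
            raise ValueError("outflow fractions must sum to 1")
        if not (0 < self.descending < 1) or any(not 0 < b < 1 for b in self.branches):
            raise ValueError("all outflow fractions must lie in (0, 1)")


@dataclass(frozen=True)
class CardiacPhases:
    """Representative cycle times (s): systolic peak, mid systolic
    deceleration, diastolic peak (minimum flow in the diastolic window)."""

    peak: float
    deceleration: float
    diastole: float


@dataclass
class PressureProfile:
    """FL minus TL lumen-averaged pressure (Pa) along the descending aorta.

    Positive values mean the false lumen is at higher pressure. NaN marks
    planes without a false lumen.
    """

    s_mm: np.ndarray
    dp_peak_pa: np.ndarray
    dp_decel_pa: np.ndarray
    dp_diast_pa: np.ndarray
    phases: CardiacPhases


def outflow_split(
    branch_areas_mm2, descending_fraction: float = DESCENDING_FLOW_FRACTION
) -> OutflowSplit:
    """Area-weighted branch outflow fractions.

    branch_i = (1 - descending_fraction) * a_i / sum(a); the total is exactly 1.
    """
    areas = np.asarray(branch_areas_mm2, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("branch cap areas must be positive")
    if not 0 < descending_fraction < 1:
        raise ValueError("descending fraction must lie in (0, 1)")
    fr = (1.0 - descending_fraction) * areas / areas.sum()
    return OutflowSplit(descending=descending_fraction, branches=tuple(fr))


def fl_flow_fraction(planes: PlaneSeries, plane_index: int = 0) -> float:
    """FL flow percentage of total descending flow at the systolic peak.

    Evaluated at the proximal descending plane (just distal to the entry
    tear) at the time sample where the total descending flux peaks.
    """
    q_fl = planes.q_fl[plane_index]
    q_tl = planes.q_tl[plane_index]
    if np.all(~np.isfinite(q_fl)):
        raise ValueError("no false-lumen flux at the requested plane")
    total = q_tl + np.nan_to_num(q_fl)
    k = int(np.argmax(total))
    if total[k] == 0:
        raise ValueError("zero total flux at the systolic peak")
    return float(100.0 * np.nan_to_num(q_fl)[k] / total[k])


def cardiac_phases(times: np.ndarray, total_flux: np.ndarray) -> CardiacPhases:
    """Resolve the three analysis phases from the flux waveform.

    Peak = argmax Q; deceleration = first time after the peak where Q drops
    through the midpoint of the descending systolic limb; diastole = argmin Q
    over the window after end systole (first minimum following deceleration).
    """
    times = np.asarray(times, dtype=float)
    q = np.asarray(total_flux, dtype=float)
    k_peak = int(np.argmax(q))
    q_min = float(q.min())
    mid = 0.5 * (q[k_peak] + q_min)
    after = np.arange(k_peak + 1, len(q))
    below = after[q[after] <= mid]
    k_dec = int(below[0]) if len(below) else min(k_peak + 1, len(q) - 1)
    dia_window = np.arange(k_dec, len(q))
    k_dia = int(dia_window[np.argmin(q[dia_window])])
    return CardiacPhases(
        peak=float(times[k_peak]), deceleration=float(times[k_dec]), diastole=float(times[k_dia])
    )


def pressure_difference_profile(
    planes: PlaneSeries, phases: CardiacPhases | None = None
) -> PressureProfile:
    """Delta P(s) = mean FL pressure - mean TL pressure at the three phases.

    Phase times are taken at the nearest stored sample; if not supplied they
    are resolved from the total descending flux.
    """
    if phases is None:
        phases = cardiac_phases(planes.times, planes.total_flux().sum(axis=0))
    dp = planes.p_fl - planes.p_tl  # NaN where no FL

    def at(t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(np.asarray(planes.times) - t)))
        return dp[:, k]

    return PressureProfile(
        s_mm=planes.s_mm.copy(),
        dp_peak_pa=at(phases.peak),
        dp_decel_pa=at(phases.deceleration),
        dp_diast_pa=at(phases.diastole),
        phases=phases,
    )


def plot_pressure_profile(profile: PressureProfile, path=None):
    """Three-phase Delta P(s) line plot; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for dp, label in (
        (profile.dp_peak_pa, "systolic peak"),
        (profile.dp_decel_pa, "systolic deceleration"),
        (profile.dp_diast_pa, "diastolic peak"),
    ):
        ax.plot(profile.s_mm, dp, marker="o", label=label)
    ax.axhline(0.0, color="k", lw=0.6)
    ax.set_xlabel("descending arclength [mm]")
    ax.set_ylabel("FL - TL pressure [Pa]")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
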