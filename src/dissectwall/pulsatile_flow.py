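"""Analytic Womersley pulsatile flow in a rigid straight tube.

This module is the field-generating surrogate for the transient CFD solve and
the independent oracle for all wall-descriptor tests. A periodic volumetric
flow waveform Q(t) is decomposed into complex Fourier harmonics; each harmonic
drives the classical Womersley velocity profile

    u_n(r) = (Q_n / (pi R^2)) * (1 - J0(z r/R)/J0(z)) / g(z),
    g(z)   = 1 - 2 J1(z) / (z J0(z)),     z = i^{3/2} alpha_n,

with alpha_n = R sqrt(n omega / nu) the harmonic Womersley number. The wall
shear stress follows from the analytic J1-based derivative, never from finite
differences; the n = 0 term reproduces Poiseuille flow exactly.

Also provided is the flow-regime screening used to justify a laminar model:
Womersley and Strouhal numbers, inlet peak Reynolds number, and a critical
Reynolds number from a pluggable empirical correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
from scipy.special import jv

__all__ = [
    "FluidProperties",
    "FlowWaveform",
    "DimensionlessNumbers",
    "decompose_waveform",
    "reconstruct_waveform",
    "womersley_velocity",
    "womersley_wall_shear",
    "womersley_pressure_gradient",
    "womersley_number",
    "peacock_critical_reynolds",
    "dimensionless_numbers",
]

# |i^{3/2} alpha| above which J0/J1 are evaluated through their large-argument
# asymptotics instead of scipy (scipy overflows near |Im z| ~ 700).
_BESSEL_ASYMPTOTIC_CUTOFF = 600.0


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1060.0
    viscosity: float = 0.00319

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, m^2/s."""
        return self.viscosity / self.density


class FlowWaveform:
    """Periodic volumetric flow-rate curve Q(t), SI units (s, m^3/s).

    Samples live on a uniform open grid covering one period: ``times[0] = 0``
    and ``times[-1] < period``. A closing sample at t = period, if present and
    consistent with Q(0), is dropped on construction.
    """

    def __init__(self, times: np.ndarray, flow: np.ndarray, period: float):
        if period <= 0:
            raise ValueError("waveform period must be positive")
        times = np.asarray(times, dtype=float)
        flow = np.asarray(flow, dtype=float)
        if times.shape != flow.shape or times.ndim != 1:
            raise ValueError("times and flow must be matching 1-D arrays")
        if np.isclose(times[-1], period):
            scale = max(abs(flow).max(), 1e-30)
            if abs(flow[-1] - flow[0]) > 0.02 * scale:
                raise ValueError("waveform is not periodic: Q(T) != Q(0)")
            times, flow = times[:-1], flow[:-1]
        if times[0] != 0.0 or times[-1] >= period:
            raise ValueError("times must start at 0 and stay below the period")
        self.times = times
        self.flow = flow
        self.period = float(period)

    @property
    def mean_flow(self) -> float:
        return float(np.mean(self.flow))

    @property
    def peak_flow(self) -> float:
        return float(np.max(self.flow))

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of Q at arbitrary times."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.concatenate([self.times, [self.period]])
        qp = np.concatenate([self.flow, [self.flow[0]]])
        return np.interp(tt, tp, qp)

    def scaled(self, factor: float) -> "FlowWaveform":
        return FlowWaveform(self.times.copy(), self.flow * factor, self.period)

    @classmethod
    def from_csv(cls, path, period: float | None = None) -> "FlowWaveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, q = data[:, 0], data[:, 1]
        if period is None:
            period = t[-1] + (t[1] - t[0]) if not np.isclose(t[-1], 0.8) else 0.8
        return cls(t, q, period)

    @classmethod
    def default(cls) -> "FlowWaveform":
        """Packaged thoracic-aorta-like waveform (0.8 s cycle, peak 290 ml/s)."""
        ref = resources.files("dissectwall") / "data" / "aortic_waveform.csv"
        with resources.as_file(ref) as path:
            data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], 0.8)


def decompose_waveform(
    waveform: FlowWaveform, n_harmonics: int, on_nonuniform: str = "error"
) -> np.ndarray:
    """Complex Fourier coefficients c_0..c_N of the flow waveform.

    The expansion convention is
    Q(t) = c_0 + sum_{n>=1} 2 Re(c_n exp(i n omega t)), so c_0 equals the
    time-averaged flow. Requires at least 2N+1 samples per period. Non-uniform
    grids are resampled (``on_nonuniform="resample"``) or rejected.
    """
    t, q = waveform.times, waveform.flow
    if len(t) < 2 * n_harmonics + 1:
        raise ValueError(
            f"{len(t)} samples cannot resolve {n_harmonics} harmonics "
            f"(need >= {2 * n_harmonics + 1})"
        )
    dt = np.diff(np.concatenate([t, [waveform.period]]))
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        if on_nonuniform == "resample":
            tu = np.linspace(0.0, waveform.period, len(t), endpoint=False)
            q = waveform.sample(tu)
        else:
            raise ValueError("waveform time grid is not uniform; pass on_nonuniform='resample'")
    c = np.fft.rfft(q) / len(q)
    return c[: n_harmonics + 1]


def reconstruct_waveform(coeffs: np.ndarray, period: float, times: np.ndarray) -> np.ndarray:
    """Evaluate the harmonic expansion at the given times."""
    omega = 2.0 * np.pi / period
    n = np.arange(1, len(coeffs))
    phase = np.exp(1j * np.outer(n, omega * np.asarray(times)))
    return coeffs[0].real + 2.0 * np.real(coeffs[1:] @ phase)


def _j_ratios(zeta: complex, x: np.ndarray) -> tuple[np.ndarray, complex]:
    """(J0(zeta x)/J0(zeta), J1(zeta)/J0(zeta)) with overflow-safe asymptotics.

    For |zeta| beyond the scipy overflow range the large-argument forms
    J0(z x)/J0(z) -> x^{-1/2} exp(i z (1 - x)) and J1/J0 -> i are used (valid
    for Im z > 0, which holds for z = i^{3/2} alpha); this keeps very large
    Womersley numbers finite instead of silently returning NaN.
    """
    x = np.asarray(x, dtype=float)
    if abs(zeta) < _BESSEL_ASYMPTOTIC_CUTOFF:
        j0 = jv(0, zeta)
        profile = jv(0, zeta * x) / j0
        ratio10 = jv(1, zeta) / j0
        # guard: overflow inside scipy would surface as nan/inf
        if np.all(np.isfinite(profile.real)) and np.isfinite(ratio10.real):
            return profile, ratio10
    with np.errstate(over="ignore"):
        safe_x = np.where(x > 0, x, 1.0)
        profile = np.where(
            x > 0,
            np.exp(1j * zeta * (1.0 - safe_x)) / np.sqrt(safe_x),
            0.0,  # core of the profile: exp(-Im(zeta)) ~ 0 at these alphas
        )
    return profile, 1j


def _harmonic_factors(coeffs: np.ndarray, radius: float, props: FluidProperties, period: float):
    """Per-harmonic (zeta, g) with g = 1 - 2 J1(z)/(z J0(z)); zeta[0] unused."""
    omega = 2.0 * np.pi / period
    nu = props.kinematic_viscosity
    out = []
    for n in range(1, len(coeffs)):
        alpha = radius * np.sqrt(n * omega / nu)
        zeta = 1j ** 1.5 * alpha
        _, r10 = _j_ratios(zeta, np.array([1.0]))
        g = 1.0 - 2.0 * r10 / zeta
        out.append((zeta, g))
    return out


def womersley_velocity(
    coeffs: np.ndarray,
    radius: float,
    props: FluidProperties,
    period: float,
    times: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Axial velocity u(r, t) (m/s) for the harmonic flow expansion.

    ``radius`` and ``r`` in metres; returns shape (len(r), len(times)).
    Satisfies no-slip u(R, t) = 0 exactly and recovers the parabolic
    Poiseuille profile for a steady-only expansion.
    """
    if radius <= 0:
        raise ValueError("tube radius must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > radius * (1 + 1e-12)):
        raise ValueError("radial positions must satisfy |r| <= R")
    times = np.asarray(times, dtype=float)
    omega = 2.0 * np.pi / period
    x = np.abs(r) / radius
    area = np.pi * radius**2
    u = np.outer(2.0 * coeffs[0].real / area * (1.0 - x**2), np.ones_like(times))
    for n, (zeta, g) in enumerate(_harmonic_factors(coeffs, radius, props, period), start=1):
        profile, _ = _j_ratios(zeta, x)
        shape = (1.0 - profile) / g
        phase = np.exp(1j * n * omega * times)
        u += 2.0 * np.real(np.outer(coeffs[n] / area * shape, phase))
    return u


def womersley_wall_shear(
    coeffs: np.ndarray,
    radius: float,
    props: FluidProperties,
    period: float,
    times: np.ndarray,
) -> np.ndarray:
    """Wall shear stress tau_w(t) (Pa), positive in the forward-flow direction.

    Uses the analytic derivative: tau_n = -mu Q_n/(pi R^3) * z J1(z)/(J0(z) g),
    whose steady limit (g -> -z^2/8) is the Poiseuille value 4 mu Q/(pi R^3).
    """
    times = np.asarray(times, dtype=float)
    omega = 2.0 * np.pi / period
    mu = props.viscosity
    tau = np.full_like(times, 4.0 * mu * coeffs[0].real / (np.pi * radius**3))
    for n, (zeta, g) in enumerate(_harmonic_factors(coeffs, radius, props, period), start=1):
        _, r10 = _j_ratios(zeta, np.array([1.0]))
        tau_n = -mu * coeffs[n] / (np.pi * radius**3) * zeta * r10 / g
        tau += 2.0 * np.real(tau_n * np.exp(1j * n * omega * times))
    return tau


def womersley_pressure_gradient(
    coeffs: np.ndarray,
    radius: float,
    props: FluidProperties,
    period: float,
    times: np.ndarray,
) -> np.ndarray:
    """Driving pressure gradient G(t) = -dp/dx (Pa/m) for the flow expansion.

    Per harmonic, G_n = i rho n omega Q_n / (pi R^2 g); the steady term is
    the Poiseuille drop 8 mu Q / (pi R^4).
    """
    times = np.asarray(times, dtype=float)
    omega = 2.0 * np.pi / period
    g_t = np.full_like(
        times, 8.0 * props.viscosity * coeffs[0].real / (np.pi * radius**4)
    )
    for n, (zeta, g) in enumerate(_harmonic_factors(coeffs, radius, props, period), start=1):
        gn = 1j * props.density * n * omega * coeffs[n] / (np.pi * radius**2 * g)
        g_t += 2.0 * np.real(gn * np.exp(1j * n * omega * times))
    return g_t


def womersley_number(radius: float, period: float, nu: float) -> float:
    """alpha = R sqrt(omega/nu) with omega = 2 pi / T (all SI)."""
    return radius * np.sqrt(2.0 * np.pi / (period * nu))


def peacock_critical_reynolds(alpha: float, strouhal: float) -> float:
    """Empirical pulsatile transition threshold Re_crit = 169 a^0.83 St^-0.27."""
    return 169.0 * alpha**0.83 * strouhal**-0.27


@dataclass(frozen=True)
class DimensionlessNumbers:
    """Flow-regime screening numbers for a tube of diameter D."""

    alpha: float
    strouhal: float
    re_peak: float
    re_crit: float

    @property
    def subcritical(self) -> bool:
        return self.re_peak < self.re_crit

    def __post_init__(self) -> None:
        if min(self.alpha, self.strouhal, self.re_peak, self.re_crit) <= 0:
            raise ValueError("dimensionless numbers must be positive")


def dimensionless_numbers(
    waveform: FlowWaveform,
    diameter: float,
    props: FluidProperties = FluidProperties(),
    u_char: str = "peak",
    re_crit_correlation: Callable[[float, float], float] = peacock_critical_reynolds,
) -> DimensionlessNumbers:
    """Womersley/Strouhal numbers, inlet peak Reynolds and critical Reynolds.

    ``u_char`` selects the Strouhal characteristic velocity: "peak" (default;
    with the Peacock correlation this lands Re_crit in the physiologic
    4000-5500 range) or "mean".
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    nu = props.kinematic_viscosity
    area = np.pi * diameter**2 / 4.0
    u_peak = waveform.peak_flow / area
    u_mean = waveform.mean_flow / area
    if u_mean <= 1e-9 * abs(u_peak):
        raise ValueError("Strouhal number undefined for zero mean flow")
    alpha = womersley_number(diameter / 2.0, waveform.period, nu)
    u_ref = {"peak": u_peak, "mean": u_mean}[u_char]
    strouhal = diameter / (waveform.period * u_ref)
    re_peak = props.density * u_peak * diameter / props.viscosity
    re_crit = re_crit_correlation(alpha, strouhal)
    return DimensionlessNumbers(alpha, strouhal, re_peak, re_crit)
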