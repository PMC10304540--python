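"""Local diffusion coefficients from restraint-force autocorrelation.

In each umbrella window the solute is held at fixed depth z and the restraint
force F(z, t) is recorded. The time-dependent friction felt by the solute is
the autocorrelation of the force fluctuations ΔF(t) = F(t) − ⟨F⟩, scaled by
RT; its time integral is the static friction coefficient

    ξ(z) = (1/RT) ∫₀^∞ ⟨ΔF(z, t) ΔF(z, 0)⟩ dt,

and the local diffusion coefficient follows as D(z) = RT / ξ(z). The integral
is evaluated by the trapezoidal rule up to the ACF's first zero crossing: a
finite noisy ACF summed over all lags does not converge, and truncating at the
first crossing is the standard positive-plateau rule. The cutoff actually
used is recorded per window for audit.

Units: forces kJ mol⁻¹ nm⁻¹, ξ in kJ mol⁻¹ nm⁻² ps, D in nm²/ps
(1 nm²/ps = 10⁻² cm²/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import NM2_PER_PS_TO_CM2_PER_S, T_DEFAULT, rt


class ZeroFluctuationError(ValueError):
    """Force series has no fluctuations; friction and D are undefined."""


@dataclass(frozen=True)
class WindowForceSeries:
    """Restraint-force time series recorded at fixed depth z0 (nm)."""

    z0: float
    dt: float
    F: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.F.size == 0:
            raise ValueError("force series is empty")

    @property
    def n(self) -> int:
        return int(self.F.size)


@dataclass(frozen=True)
class FrictionResult:
    """Static friction ξ with the ACF and integration cutoff that produced it."""

    xi: float  # kJ mol⁻¹ nm⁻² ps
    acf: np.ndarray  # (kJ mol⁻¹ nm⁻¹)², lag-indexed
    cutoff_lag: float  # ps

    def diffusion(self, T: float = T_DEFAULT) -> float:
        """Local diffusion coefficient D = RT/ξ, nm²/ps."""
        return rt(T) / self.xi


@dataclass
class DepthProfile:
    """A quantity sampled on a strictly increasing depth grid."""

    QUANTITIES = ("diffusion", "partition", "resistance_density", "cumulative_resistance")

    z: np.ndarray
    values: np.ndarray
    quantity: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z.ndim != 1 or self.z.size == 0:
            raise ValueError("depth grid must be a non-empty 1D array")
        if self.z.size != self.values.size:
            raise ValueError("z and values must have equal length")
        if self.z.size > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("depth grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.quantity not in self.QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {self.QUANTITIES}"
            )
        if self.quantity in ("diffusion", "partition", "resistance_density"):
            if np.any(self.values <= 0):
                raise ValueError(f"{self.quantity} values must be strictly positive")

    def interp(self, z) :
        return np.interp(z, self.z, self.values)


def force_fluctuations(series: WindowForceSeries) -> np.ndarray:
    """ΔF(t) = F(t) − ⟨F⟩; the output has exactly zero mean."""
    dF = series.F - series.F.mean()
    return dF - dF.mean()  # second pass removes residual rounding


def autocorrelation(dF: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/N) autocorrelation of a fluctuation series, lags 0..max_lag.

    The 1/N normalization keeps the estimated ACF positive semidefinite so
    its time integral is bounded. Computed via FFT; identical (to rounding)
    to the direct sum Σ_t ΔF(t)ΔF(t+k)/N.
    """
    dF = np.asarray(dF, dtype=float)
    n = dF.size
    if not 0 <= max_lag < n:
        raise ValueError(f"max_lag must be in [0, {n - 1}], got {max_lag}")
    n_fft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(dF, n_fft)
    acov = np.fft.irfft(spec * np.conj(spec), n_fft)[: max_lag + 1]
    return acov / n


def static_friction(
    acf: np.ndarray,
    dt: float,
    T: float = T_DEFAULT,
    cutoff: str = "first_zero",
) -> FrictionResult:
    """Static friction ξ from a lag-ACF by trapezoidal time integration.

    ``cutoff="first_zero"`` truncates at the first lag where the ACF is ≤ 0
    (that lag's value included in the trapezoid); ``cutoff="full"`` integrates
    the whole array.
    """
    acf = np.asarray(acf, dtype=float)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if acf.size == 0 or np.all(acf == 0):
        raise ZeroFluctuationError(
            "force series has zero fluctuation; the diffusion coefficient "
            "is undefined"
        )
    if cutoff == "first_zero":
        below = np.nonzero(acf[1:] <= 0)[0]
        k = int(below[0]) + 1 if below.size else acf.size - 1
    elif cutoff == "full":
        k = acf.size - 1
    else:
        raise ValueError(f"unknown cutoff rule {cutoff!r}")
    if k == 0:
        xi_integral = 0.5 * acf[0] * dt  # single-point series: half interval
    else:
        xi_integral = np.trapezoid(acf[: k + 1], dx=dt)
    return FrictionResult(xi=float(xi_integral / rt(T)), acf=acf, cutoff_lag=k * dt)


def window_friction(
    series: WindowForceSeries,
    T: float = T_DEFAULT,
    max_lag: int | None = None,
    cutoff: str = "first_zero",
) -> FrictionResult:
    """ACF → static friction for one window (max_lag defaults to n // 10)."""
    dF = force_fluctuations(series)
    if max_lag is None:
        max_lag = max(1, series.n // 10)
    acf = autocorrelation(dF, min(max_lag, series.n - 1))
    return static_friction(acf, series.dt, T=T, cutoff=cutoff)


def diffusion_profile(
    series_list,
    T: float = T_DEFAULT,
    max_lag: int | None = None,
    cutoff: str = "first_zero",
) -> DepthProfile:
    """Assemble D(z) = RT/ξ(z) from per-window force series, sorted by depth.

    The result's ``meta`` records the per-window ACF integration cutoffs (ps)
    and the cm²/s conversion of the values.
    """
    if not series_list:
        raise ValueError("need at least one force series")
    z0 = np.array([s.z0 for s in series_list])
    uniq, counts = np.unique(z0, return_counts=True)
    if np.any(counts > 1):
        raise ValueError(f"duplicate window depth(s): {uniq[counts > 1]} nm")
    order = np.argsort(z0)
    RT = rt(T)
    D = np.empty(len(series_list))
    cutoffs = np.empty(len(series_list))
    for j, i in enumerate(order):
        fr = window_friction(series_list[i], T=T, max_lag=max_lag, cutoff=cutoff)
        D[j] = RT / fr.xi
        cutoffs[j] = fr.cutoff_lag
    return DepthProfile(
        z=z0[order],
        values=D,
        quantity="diffusion",
        meta={
            "T": T,
            "cutoff_ps": cutoffs,
            "D_cm2_per_s": D * NM2_PER_PS_TO_CM2_PER_S,
        },
    )
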