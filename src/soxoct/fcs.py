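"""Fluorescence correlation spectroscopy: ACF simulation, fitting, conversions.

The autocorrelation function of fluorescence fluctuations from molecules
diffusing through a 3D Gaussian confocal volume, with an optional fast
photophysical (triplet) term, is

    G(tau) = (1/N) * [1 + T exp(-tau/tau_t) / (1 - T)]
             * sum_i f_i * (1 + tau/tau_Di)^-1 * (1 + tau/(K^2 tau_Di))^-1/2

where N is the mean particle number in the effective volume, f_i the
amplitude fraction of diffusing component i with diffusion time tau_Di,
K = z0/w0 the axial-to-lateral aspect ratio of the volume, and T the triplet
fraction with lifetime tau_t.  The amplitude gives concentration through
N = C * N_A * V_eff with V_eff = pi^(3/2) w0^2 z0; a two-component fit of a
labeled-DNA sample separates free DNA from the slower protein-bound DNA, and
the slow amplitude fraction is the bound fraction entering titration
analysis (equal molecular brightness assumed by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import lmfit
import numpy as np
from scipy.constants import Avogadro

from .errors import FitError, ValidationError

__all__ = [
    "ConfocalVolume",
    "AcfModelParams",
    "AcfCurve",
    "AcfFitResult",
    "DEFAULT_VOLUME",
    "make_lag_grid",
    "acf_model",
    "simulate_acf",
    "fit_acf",
    "concentration_from_n",
    "n_from_concentration",
    "bound_fraction_from_fit",
    "IdentifiabilityWarning",
]


class IdentifiabilityWarning(UserWarning):
    """Two-component fit with nearly equal diffusion times."""


@dataclass(frozen=True)
class ConfocalVolume:
    """Confocal observation volume geometry (1/e^2 radii in micrometres)."""

    w0_um: float = 0.2
    z0_um: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w0_um > 0 and self.z0_um > 0):
            raise ValidationError("confocal radii must be positive")

    @property
    def structure_factor(self) -> float:
        """Axial-to-lateral aspect ratio K = z0/w0."""
        return self.z0_um / self.w0_um

    @property
    def v_eff_fL(self) -> float:
        """Effective volume pi^(3/2) w0^2 z0 in femtolitres (1 um^3 = 1 fL)."""
        return float(np.pi**1.5 * self.w0_um**2 * self.z0_um)


#: w0 = 0.2 um, z0 = 1.0 um: structure factor 5, V_eff ~ 0.22 fL.
DEFAULT_VOLUME = ConfocalVolume()


@dataclass
class AcfModelParams:
    """Parameters of the diffusion + triplet ACF model.

    ``components`` is a list of ``(tau_d_seconds, fraction)`` with fractions
    summing to 1.  The triplet lifetime must be faster than every diffusion
    time for the factorized model to make sense.
    """

    n_particles: float
    components: List[Tuple[float, float]]
    triplet_fraction: float = 0.0
    triplet_tau: float = 2e-6

    def __post_init__(self) -> None:
        if not self.n_particles > 0:
            raise ValidationError("n_particles must be positive")
        if not self.components:
            raise ValidationError("at least one diffusing component is required")
        fractions = [f for _, f in self.components]
        if any(f < -1e-12 or f > 1 + 1e-12 for f in fractions):
            raise ValidationError("component fractions must lie in [0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValidationError("component fractions must sum to 1")
        if any(t <= 0 for t, _ in self.components):
            raise ValidationError("diffusion times must be positive")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValidationError("triplet fraction must be in [0, 1)")
        if self.triplet_fraction > 0 and self.triplet_tau >= min(
            t for t, _ in self.components
        ):
            raise ValidationError("triplet_tau must be faster than all diffusion times")


@dataclass
class AcfCurve:
    """Measured or simulated autocorrelation curve."""

    lags: np.ndarray
    g: np.ndarray
    se: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise ValidationError("lags must be a non-empty 1-D array")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lags must be positive and strictly increasing")
        if self.g.shape != self.lags.shape or not np.all(np.isfinite(self.g)):
            raise ValidationError("g must be finite and match lags in length")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.lags.shape:
                raise ValidationError("se must match lags in length")


def make_lag_grid(
    tmin: float = 1e-6, tmax: float = 1.0, points_per_decade: int = 50
) -> np.ndarray:
    """Log-spaced lag grid, default 1 us - 1 s at 50 points/decade."""
    n = int(np.log10(tmax / tmin) * points_per_decade) + 1
    return np.geomspace(tmin, tmax, n)


def acf_model(
    params: AcfModelParams, volume: ConfocalVolume, lags: np.ndarray
) -> np.ndarray:
    """Evaluate the closed-form ACF model on a lag grid."""
    lags = np.asarray(lags, dtype=float)
    k2 = volume.structure_factor**2
    diff = np.zeros_like(lags)
    for tau_d, frac in params.components:
        diff += frac / ((1.0 + lags / tau_d) * np.sqrt(1.0 + lags / (k2 * tau_d)))
    trip = 1.0
    if params.triplet_fraction > 0:
        t = params.triplet_fraction
        trip = 1.0 + t * np.exp(-lags / params.triplet_tau) / (1.0 - t)
    return trip * diff / params.n_particles


def simulate_acf(
    params: AcfModelParams,
    volume: ConfocalVolume = DEFAULT_VOLUME,
    lags: Optional[np.ndarray] = None,
    noise_sd_scale: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> AcfCurve:
    """Seeded noisy ACF: model plus Gaussian noise proportional to amplitude.

    The per-lag noise sd is ``noise_sd_scale * (G(tau) + 0.01 * G(0))``; the
    small floor keeps the long-lag tail from being noiseless, mimicking the
    residual shot noise of real correlators.
    """
    if noise_sd_scale < 0:
        raise ValidationError("noise_sd_scale must be non-negative")
    if lags is None:
        lags = make_lag_grid()
    g0 = acf_model(params, volume, lags)
    if noise_sd_scale == 0:
        return AcfCurve(lags=lags, g=g0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = noise_sd_scale * (g0 + 0.01 * g0[0])
    return AcfCurve(lags=lags, g=g0 + rng.normal(0.0, sd), se=sd)


@dataclass
class AcfFitResult:
    """Fitted ACF parameters plus fit diagnostics."""

    params: AcfModelParams
    redchi: float
    success: bool
    message: str


def fit_acf(
    curve: AcfCurve,
    n_components: int = 1,
    volume: ConfocalVolume = DEFAULT_VOLUME,
    fixed_taus: Optional[Sequence[float]] = None,
    fit_triplet: bool = False,
) -> AcfFitResult:
    """Weighted nonlinear least-squares fit of the ACF model.

    With ``fixed_taus`` supplying the free/bound diffusion times only the
    particle number, the amplitude fractions and (optionally) the triplet
    parameters are free — the standard strategy for a DNA-binding titration
    where both diffusion times are calibrated once.
    """
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if curve.lags.size < 20 or curve.lags[-1] / curve.lags[0] < 1e3:
        raise ValidationError("need >= 20 lag points spanning >= 3 decades")
    if fixed_taus is not None and len(fixed_taus) != n_components:
        raise ValidationError("fixed_taus must supply one tau per component")

    lags, g = curve.lags, curve.g
    weights = None
    if curve.se is not None and np.all(curve.se > 0):
        weights = 1.0 / curve.se

    g0_est = max(float(np.max(g[: max(3, lags.size // 20)])), 1e-6)
    # lag at half amplitude as the diffusion-time seed
    half_idx = int(np.argmin(np.abs(g - 0.5 * g0_est)))
    tau_seed = float(lags[half_idx])

    p = lmfit.Parameters()
    p.add("n", value=1.0 / g0_est, min=1e-6)
    if n_components == 1:
        p.add("tau1", value=fixed_taus[0] if fixed_taus else tau_seed,
              min=lags[0] / 10, max=lags[-1] * 10, vary=fixed_taus is None)
    else:
        t1 = fixed_taus[0] if fixed_taus else tau_seed / 2
        t2 = fixed_taus[1] if fixed_taus else tau_seed * 4
        p.add("tau1", value=t1, min=lags[0] / 10, max=lags[-1] * 10,
              vary=fixed_taus is None)
        p.add("tau2", value=t2, min=lags[0] / 10, max=lags[-1] * 10,
              vary=fixed_taus is None)
        p.add("f2", value=0.5, min=0.0, max=1.0)
    p.add("trip", value=0.1 if fit_triplet else 0.0, min=0.0, max=0.8,
          vary=fit_triplet)
    p.add("trip_tau", value=2e-6, min=1e-8, max=5e-5, vary=fit_triplet)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        mp = _params_from_lmfit(pars, n_components)
        r = acf_model(mp, volume, lags) - g
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, p, method="leastsq")
    if not result.success:
        raise FitError(f"ACF fit did not converge: {result.message}")
    fitted = _params_from_lmfit(result.params, n_components)
    if n_components == 2 and fixed_taus is None:
        t1, t2 = (t for t, _ in fitted.components)
        ratio = max(t1, t2) / min(t1, t2)
        if ratio < 1.5:
            warnings.warn(
                f"two-component diffusion times differ by only x{ratio:.2f}; "
                "amplitude fractions are poorly identified",
                IdentifiabilityWarning,
                stacklevel=2,
            )
    return AcfFitResult(
        params=fitted,
        redchi=float(result.redchi),
        success=bool(result.success),
        message=str(result.message),
    )


def _params_from_lmfit(pars: lmfit.Parameters, n_components: int) -> AcfModelParams:
    trip = float(pars["trip"].value)
    if n_components == 1:
        comps = [(float(pars["tau1"].value), 1.0)]
    else:
        f2 = float(pars["f2"].value)
        comps = [
            (float(pars["tau1"].value), 1.0 - f2),
            (float(pars["tau2"].value), f2),
        ]
    return AcfModelParams(
        n_particles=float(pars["n"].value),
        components=comps,
        triplet_fraction=trip,
        triplet_tau=float(pars["trip_tau"].value),
    )


def concentration_from_n(n_particles: float, volume: ConfocalVolume) -> float:
    """Convert mean particle number to molar concentration in nM."""
    if n_particles < 0:
        raise ValidationError("n_particles must be non-negative")
    v_litres = volume.v_eff_fL * 1e-15
    if v_litres <= 0:
        raise ValidationError("effective volume must be positive")
    return n_particles / (Avogadro * v_litres) * 1e9


def n_from_concentration(conc_nM: float, volume: ConfocalVolume) -> float:
    """Inverse of :func:`concentration_from_n`."""
    if conc_nM < 0:
        raise ValidationError("concentration must be non-negative")
    return conc_nM * 1e-9 * Avogadro * volume.v_eff_fL * 1e-15


def bound_fraction_from_fit(
    fit: AcfModelParams,
    bound_component_index: Optional[int] = None,
    brightness_ratio: float = 1.0,
) -> float:
    """Bound-DNA fraction from a two-component fit.

    By default the slower component is taken as bound.  With equal
    molecular brightness (default) the amplitude fraction *is* the number
    fraction; a brightness ratio q (bound/free) re-weights amplitudes by
    q^2 before converting.
    """
    if len(fit.components) != 2:
        raise ValidationError(
            "bound fraction requires a two-component fit (free + bound DNA)"
        )
    if bound_component_index is None:
        bound_component_index = int(np.argmax([t for t, _ in fit.components]))
    if bound_component_index not in (0, 1):
        raise ValidationError("bound_component_index must be 0 or 1")
    a_bound = fit.components[bound_component_index][1]
    a_free = fit.components[1 - bound_component_index][1]
    q2 = brightness_ratio**2
    denom = a_bound / q2 + a_free
    if denom == 0:
        return 0.0
    return float((a_bound / q2) / denom)
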