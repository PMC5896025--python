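"""Mass-action equilibrium of Sox2 and Oct4 on a two-site DNA element.

One DNA duplex carries adjacent Sox and Oct half-sites.  Four DNA species
coexist at equilibrium — free DNA, Sox2-DNA, Oct4-DNA and the ternary
Sox2-Oct4-DNA complex — governed by the intrinsic dissociation constants
``kd_sox`` and ``kd_oct`` and a dimensionless cooperativity ``omega`` that
multiplies the statistical weight of the ternary complex:

    [Sox2-DNA]   = D_free * s / kd_sox
    [Oct4-DNA]   = D_free * o / kd_oct
    [ternary]    = omega * D_free * s * o / (kd_sox * kd_oct)

with ``s``/``o`` the free monomer concentrations.  ``omega = 1`` is
independent binding; ``omega > 1`` stabilizes the heterodimer on DNA, which
is the mechanistic origin of the *apparent* cooperativity factor observed as
a drop in fitted aKd when the partner protein is present.  All
concentrations are nM throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import SolverError, ValidationError
from .titration import TitrationCurve, fit_akd

__all__ = [
    "BindingParameters",
    "MixtureComposition",
    "EquilibriumState",
    "ReadoutMode",
    "solve_equilibrium",
    "bound_fraction",
    "simulate_titration",
    "infer_omega",
    "DEFAULT_TITRANT_GRID",
]

#: Default titration design: 10 log-spaced totals from 1 to 500 nM.
DEFAULT_TITRANT_GRID = np.geomspace(1.0, 500.0, 10)


class ReadoutMode(enum.Enum):
    """Which shifted species count as "bound" DNA.

    Gel quantification sums every band containing the titrated protein
    (monomer + ternary): that is ``TITRANT_BOUND``, the default.
    ``ANY_BOUND`` counts every protein-containing species and
    ``TERNARY_ONLY`` just the heterodimer band.
    """

    TITRANT_BOUND = "titrant_bound"
    TERNARY_ONLY = "ternary_only"
    ANY_BOUND = "any_bound"


@dataclass(frozen=True)
class BindingParameters:
    """Intrinsic two-site model parameters (concentrations in nM)."""

    kd_sox: float
    kd_oct: float
    omega: float = 1.0

    def __post_init__(self) -> None:
        if not self.kd_sox > 0:
            raise ValidationError("kd_sox must be positive")
        if not self.kd_oct > 0:
            raise ValidationError("kd_oct must be positive")
        if self.omega < 0:
            raise ValidationError("omega must be non-negative")


@dataclass(frozen=True)
class MixtureComposition:
    """Total concentrations of DNA and the two proteins (nM)."""

    dna_total: float = 5.0
    sox_total: float = 0.0
    oct_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dna_total", "sox_total", "oct_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (nM) of every species, plus the totals."""

    free_dna: float
    sox_dna: float
    oct_dna: float
    ternary: float
    free_sox: float
    free_oct: float
    dna_total: float
    sox_total: float
    oct_total: float


def _dna_partition(s: float, o: float, p: BindingParameters) -> Tuple[float, float, float, float]:
    """Per-duplex statistical weights (free, sox-bound, oct-bound, ternary)."""
    zs = s / p.kd_sox
    zo = o / p.kd_oct
    zt = p.omega * zs * zo
    return 1.0, zs, zo, zt


def solve_equilibrium(
    params: BindingParameters,
    mix: MixtureComposition,
    active_fraction: float = 1.0,
) -> EquilibriumState:
    """Solve the two-site mass-action equilibrium.

    The DNA species are eliminated through the site partition function,
    reducing the system to the two free-monomer concentrations.  For a
    trial free-Oct4 the Sox2 conservation equation is an explicit
    quadratic in free Sox2, so a single bracketed root find on free Oct4
    in [0, oct_total] suffices — the residual is monotone, guaranteeing a
    unique solution.

    ``active_fraction`` scales both protein totals, modeling preparations
    that are not 100% binding-competent (default 1.0).
    """
    if not 0.0 < active_fraction <= 1.0:
        raise ValidationError("active_fraction must be in (0, 1]")
    S = mix.sox_total * active_fraction
    O = mix.oct_total * active_fraction
    D = mix.dna_total
    ks, ko, w = params.kd_sox, params.kd_oct, params.omega

    def free_sox_given(o: float) -> float:
        if S == 0.0:
            return 0.0
        a = 1.0 + o / ko
        b = (1.0 + w * o / ko) / ks
        # s + D*b*s/(a + b*s) = S  =>  b s^2 + (a + D b - S b) s - S a = 0
        c1 = a + D * b - S * b
        s = (-c1 + math.sqrt(c1 * c1 + 4.0 * b * S * a)) / (2.0 * b)
        return min(max(s, 0.0), S)

    def oct_residual(o: float) -> float:
        s = free_sox_given(o)
        _, zs, zo, zt = _dna_partition(s, o, params)
        z = 1.0 + zs + zo + zt
        bound_o = D * (zo + zt) / z
        return o + bound_o - O

    if O == 0.0:
        o = 0.0
    else:
        try:
            o = brentq(
                oct_residual, 0.0, O, xtol=1e-14 * max(O, 1.0), rtol=1e-14, maxiter=200
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
            raise SolverError(f"equilibrium solve failed for {mix}: {exc}") from exc
    s = free_sox_given(o)

    _, zs, zo, zt = _dna_partition(s, o, params)
    z = 1.0 + zs + zo + zt
    free_dna = D / z if D > 0 else 0.0
    state = EquilibriumState(
        free_dna=free_dna,
        sox_dna=free_dna * zs,
        oct_dna=free_dna * zo,
        ternary=free_dna * zt,
        free_sox=s,
        free_oct=o,
        dna_total=D,
        sox_total=S,
        oct_total=O,
    )
    _check_conservation(state, mix=mix)
    return state


def _check_conservation(state: EquilibriumState, mix: MixtureComposition) -> None:
    checks = [
        ("DNA", state.dna_total, state.free_dna + state.sox_dna + state.oct_dna + state.ternary),
        ("Sox2", state.sox_total, state.free_sox + state.sox_dna + state.ternary),
        ("Oct4", state.oct_total, state.free_oct + state.oct_dna + state.ternary),
    ]
    for name, total, summed in checks:
        if total > 0:
            # relative check with a sub-femtomolar absolute floor
            if abs(summed - total) > max(1e-8 * total, 1e-12):
                raise SolverError(
                    f"{name} conservation violated for {mix}: "
                    f"sum {summed:.6g} vs total {total:.6g}"
                )
        elif abs(summed) > 1e-12:
            raise SolverError(f"{name} appears from nothing for {mix}")


def bound_fraction(
    state: EquilibriumState,
    mode: ReadoutMode = ReadoutMode.TITRANT_BOUND,
    titrant: str = "sox",
) -> float:
    """Fraction of DNA counted as bound under the chosen readout."""
    if state.dna_total == 0:
        raise ValidationError("bound fraction undefined at zero DNA")
    if titrant not in ("sox", "oct"):
        raise ValidationError("titrant must be 'sox' or 'oct'")
    d = state.dna_total
    if mode is ReadoutMode.TITRANT_BOUND:
        monomer = state.sox_dna if titrant == "sox" else state.oct_dna
        return (monomer + state.ternary) / d
    if mode is ReadoutMode.TERNARY_ONLY:
        return state.ternary / d
    return 1.0 - state.free_dna / d


def simulate_titration(
    params: BindingParameters,
    dna_total: float = 5.0,
    titrant: str = "sox",
    titrant_grid: Optional[Iterable[float]] = None,
    cofactor: Optional[Tuple[str, float]] = None,
    mode: ReadoutMode = ReadoutMode.TITRANT_BOUND,
    active_fraction: float = 1.0,
) -> TitrationCurve:
    """Noiseless bound-fraction titration predicted by the two-site model.

    ``cofactor`` is ``(species, total_nM)`` with species ``"sox"`` or
    ``"oct"`` held constant while the other protein is titrated.
    """
    grid = DEFAULT_TITRANT_GRID if titrant_grid is None else np.asarray(
        list(titrant_grid), dtype=float
    )
    if grid.size == 0:
        raise ValidationError("titrant grid must be non-empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValidationError("titrant grid must be non-negative, strictly increasing")
    if titrant not in ("sox", "oct"):
        raise ValidationError("titrant must be 'sox' or 'oct'")
    cof_name, cof_total = (None, 0.0)
    if cofactor is not None:
        cof_name, cof_total = cofactor
        if cof_name not in ("sox", "oct"):
            raise ValidationError("cofactor species must be 'sox' or 'oct'")
        if cof_name == titrant:
            raise ValidationError("cofactor species must differ from the titrant")

    fractions = np.empty_like(grid)
    for i, total in enumerate(grid):
        sox = total if titrant == "sox" else (cof_total if cof_name == "sox" else 0.0)
        oct_ = total if titrant == "oct" else (cof_total if cof_name == "oct" else 0.0)
        state = solve_equilibrium(
            params,
            MixtureComposition(dna_total=dna_total, sox_total=sox, oct_total=oct_),
            active_fraction=active_fraction,
        )
        fractions[i] = bound_fraction(state, mode, titrant)
    return TitrationCurve(
        titrant_total=grid,
        bound_fraction=fractions,
        titrant_name=titrant,
        dna_total=dna_total,
        cofactor=None if cofactor is None else (cof_name, cof_total),
    )


_OMEGA_BOUNDS = (1e-3, 1e4)


def infer_omega(
    akd_alone: float,
    akd_with: float,
    cofactor_total: float,
    kd_cofactor: float,
    dna_total: float = 5.0,
    titrant_grid: Optional[Iterable[float]] = None,
    mode: ReadoutMode = ReadoutMode.TITRANT_BOUND,
) -> float:
    """Invert the apparent-Kd shift to the mechanistic cooperativity omega.

    Finds the omega for which a forward-simulated titration of the probe
    (intrinsic Kd ``akd_alone``) in the presence of the cofactor, fitted
    with the depletion isotherm, reproduces ``akd_with``.  The apparent Kd
    decreases monotonically in omega, so a bracketed root find in
    log-omega over [1e-3, 1e4] is exact.
    """
    for name, v in (
        ("akd_alone", akd_alone),
        ("akd_with", akd_with),
        ("cofactor_total", cofactor_total),
        ("kd_cofactor", kd_cofactor),
        ("dna_total", dna_total),
    ):
        if not v > 0:
            raise ValidationError(f"{name} must be positive")
    grid = DEFAULT_TITRANT_GRID if titrant_grid is None else np.asarray(
        list(titrant_grid), dtype=float
    )

    def apparent(omega: float) -> float:
        params = BindingParameters(kd_sox=akd_alone, kd_oct=kd_cofactor, omega=omega)
        curve = simulate_titration(
            params,
            dna_total=dna_total,
            titrant="sox",
            titrant_grid=grid,
            cofactor=("oct", cofactor_total),
            mode=mode,
        )
        return fit_akd(curve, fix_fmax=True, n_boot=0).akd

    lo, hi = np.log10(_OMEGA_BOUNDS)
    f_lo = apparent(10.0**lo) - akd_with
    f_hi = apparent(10.0**hi) - akd_with
    if f_lo * f_hi > 0:
        raise ValidationError(
            f"no omega in [{_OMEGA_BOUNDS[0]}, {_OMEGA_BOUNDS[1]}] reproduces "
            f"aKd(with) = {akd_with} nM given aKd(alone) = {akd_alone} nM"
        )
    log_omega = brentq(lambda lw: apparent(10.0**lw) - akd_with, lo, hi, xtol=1e-7)
    return float(10.0**log_omega)
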