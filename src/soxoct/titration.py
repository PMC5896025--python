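"""Apparent-Kd inference from bound-fraction titration curves.

A titration measures the fraction of a fixed amount of labeled DNA (typically
5 nM) bound by a protein as the total protein concentration is raised.  Because
the DNA concentration is comparable to the dissociation constants involved
(tens of nM), free and total protein differ appreciably and the hyperbolic
isotherm is replaced by the ligand-depletion quadratic

    f(P; Kd, fmax) = fmax * ((P + D + Kd) - sqrt((P + D + Kd)^2 - 4 P D)) / (2 D)

with P the total titrant, D the total DNA and fmax the saturation plateau.
The fitted Kd is an *apparent* dissociation constant (aKd): the underlying
system may involve a second site and cooperative stabilization, which is
exactly what the apparent cooperativity factor (ratio of aKd without/with a
cofactor present) quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    FitError,
    ReportingError,
    ValidationError,
)

__all__ = [
    "TitrationCurve",
    "KdEstimate",
    "CooperativityFactor",
    "TitrationResult",
    "isotherm",
    "fit_akd",
    "akd_from_half_saturation",
    "cooperativity_factor",
    "summarize_table",
    "read_titration_csv",
    "write_titration_csv",
    "round_half_up",
]

#: Bound fractions may overshoot 1 slightly under measurement noise.
_FRACTION_MAX = 1.05


def isotherm(
    p: np.ndarray | float, kd: float, dna_total: float, fmax: float = 1.0
) -> np.ndarray | float:
    """Depletion-corrected single-site binding isotherm.

    Reduces to the hyperbola ``fmax * p / (p + kd)`` in the limit of
    vanishing DNA concentration.
    """
    p = np.asarray(p, dtype=float)
    if dna_total < 1e-9:
        out = fmax * p / (p + kd)
    else:
        s = p + dna_total + kd
        disc = np.maximum(s * s - 4.0 * p * dna_total, 0.0)
        out = fmax * (s - np.sqrt(disc)) / (2.0 * dna_total)
    return out if out.ndim else float(out)


@dataclass
class TitrationCurve:
    """Bound-fraction-vs-total-titrant data at fixed DNA concentration.

    Attributes
    ----------
    titrant_total
        Total titrant concentrations in nM, strictly increasing.
    bound_fraction
        Bound DNA fraction at each point, in [0, 1.05] (noise overshoot
        above 1 is tolerated).
    se
        Optional per-point standard errors; used as weights when fitting.
    titrant_name
        Label of the titrated species (e.g. ``"sox2"``).
    dna_total
        Total labeled DNA in nM.
    cofactor
        Optional ``(name, total_nM)`` of a second protein held constant.
    """

    titrant_total: np.ndarray
    bound_fraction: np.ndarray
    se: Optional[np.ndarray] = None
    titrant_name: str = "sox2"
    dna_total: float = 5.0
    cofactor: Optional[Tuple[str, float]] = None

    def __post_init__(self) -> None:
        self.titrant_total = np.asarray(self.titrant_total, dtype=float)
        self.bound_fraction = np.asarray(self.bound_fraction, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.titrant_total.shape:
                raise ValidationError("se must match titrant_total in length")
        if self.titrant_total.ndim != 1 or self.titrant_total.size == 0:
            raise ValidationError("titration grid must be a non-empty 1-D array")
        if self.bound_fraction.shape != self.titrant_total.shape:
            raise ValidationError("bound_fraction must match titrant_total in length")
        if np.any(self.titrant_total < 0):
            raise ValidationError("titrant totals must be non-negative")
        if np.any(np.diff(self.titrant_total) <= 0):
            raise ValidationError("titrant totals must be strictly increasing")
        if np.any(self.bound_fraction < -1e-12) or np.any(
            self.bound_fraction > _FRACTION_MAX + 1e-12
        ):
            raise ValidationError(
                f"bound fractions must lie in [0, {_FRACTION_MAX}]"
            )
        if self.dna_total < 0:
            raise ValidationError("dna_total must be non-negative")

    @property
    def n(self) -> int:
        return int(self.titrant_total.size)


@dataclass
class KdEstimate:
    """Fitted apparent dissociation constant with uncertainty.

    ``se`` is a residual-bootstrap standard error by default (see
    :func:`fit_akd`); when constructed directly from published numbers the
    remaining fields may be left at their defaults.
    """

    akd: float
    se: float = 0.0
    fitted_fmax: float = 1.0
    residual_sse: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.akd > 0:
            raise ValidationError("akd must be positive")
        if self.se < 0:
            raise ValidationError("se must be non-negative")


@dataclass
class CooperativityFactor:
    """Ratio of aKd without a cofactor to aKd with it, with propagated SE."""

    value: float
    se: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError("cooperativity factor must be positive")
        if self.se < 0:
            raise ValidationError("se must be non-negative")

    def rounded(self, ndigits: int = 1) -> Tuple[float, float]:
        """Reporting helper: half-up rounding as printed in affinity tables."""
        return round_half_up(self.value, ndigits), round_half_up(self.se, ndigits)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.25 -> 0.3), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fit_core(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    dna_total: float,
    fix_fmax: bool,
    kd0: float,
    fmax0: float,
) -> Tuple[float, float, np.ndarray]:
    """Weighted least-squares fit of the depletion isotherm.

    Kd is optimized in log10 space to enforce positivity.  Returns
    (kd, fmax, residuals) where residuals are unweighted.
    """

    if fix_fmax:

        def resid(theta: np.ndarray) -> np.ndarray:
            return (isotherm(x, 10.0 ** theta[0], dna_total, 1.0) - y) * weights

        theta0 = np.array([np.log10(kd0)])
        bounds = ([-6.0], [7.0])
    else:

        def resid(theta: np.ndarray) -> np.ndarray:
            return (isotherm(x, 10.0 ** theta[0], dna_total, theta[1]) - y) * weights

        theta0 = np.array([np.log10(kd0), fmax0])
        bounds = ([-6.0, 1e-3], [7.0, 2.0])

    sol = least_squares(resid, theta0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"isotherm fit did not converge: {sol.message}")
    kd = 10.0 ** sol.x[0]
    fmax = 1.0 if fix_fmax else float(sol.x[1])
    residuals = y - isotherm(x, kd, dna_total, fmax)
    return float(kd), fmax, residuals


def fit_akd(
    curve: TitrationCurve,
    fix_fmax: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> KdEstimate:
    """Fit the apparent dissociation constant of a titration curve.

    Parameters
    ----------
    curve
        The titration data; at least 4 points required.
    fix_fmax
        Fix the saturation plateau at 1.0 (default).  Free it for
        gel-quantified data that plateaus below full saturation.
    n_boot
        Residual-bootstrap replicates for the standard error.  ``0``
        falls back to a Gauss-Newton covariance estimate (cheaper; useful
        inside simulation loops).
    seed
        Seed for the bootstrap resampler.
    """
    if curve.n < 4:
        raise ValidationError("at least 4 titration points are required for fitting")
    x, y = curve.titrant_total, curve.bound_fraction
    if float(np.max(np.abs(y))) < 1e-3:
        raise DegenerateDataError("all bound fractions are ~0; nothing to fit")
    if curve.se is not None and np.all(curve.se > 0):
        weights = 1.0 / curve.se
    else:
        weights = np.ones_like(y)

    fmax0 = min(max(float(np.max(y)), 0.1), 2.0)
    half = 0.5 * fmax0
    idx = int(np.argmin(np.abs(y - half)))
    kd0 = max(float(x[idx]), 1e-3)

    kd, fmax, residuals = _fit_core(x, y, weights, curve.dna_total, fix_fmax, kd0, fmax0)
    sse = float(np.sum(residuals**2))

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        yhat = y - residuals
        boots = []
        for _ in range(n_boot):
            ystar = yhat + rng.choice(residuals, size=residuals.size, replace=True)
            ystar = np.clip(ystar, 0.0, _FRACTION_MAX)
            try:
                kd_b, _, _ = _fit_core(
                    x, ystar, weights, curve.dna_total, fix_fmax, kd, fmax
                )
            except FitError:
                continue
            boots.append(kd_b)
        if len(boots) < max(10, n_boot // 2):
            raise FitError("bootstrap failed on too many replicates")
        se = float(np.std(boots, ddof=1))
    else:
        # Gauss-Newton covariance on log10(kd); delta-method back to kd.
        eps = 1e-6
        grad = (
            isotherm(x, 10 ** (np.log10(kd) + eps), curve.dna_total, fmax)
            - isotherm(x, kd, curve.dna_total, fmax)
        ) / eps
        jtj = float(np.sum((grad * weights) ** 2))
        dof = max(curve.n - (1 if fix_fmax else 2), 1)
        sigma2 = float(np.sum((residuals * weights) ** 2)) / dof
        var_log = sigma2 / max(jtj, 1e-300)
        se = float(kd * np.log(10.0) * np.sqrt(var_log))

    return KdEstimate(akd=kd, se=se, fitted_fmax=fmax, residual_sse=sse, n_points=curve.n)


def akd_from_half_saturation(curve: TitrationCurve) -> float:
    """Alternative aKd estimator: depletion-corrected half-saturation point.

    Interpolates the titrant total at which the bound fraction crosses half
    its plateau and subtracts the bound-DNA offset D/2.  Cruder than the
    full fit but model-light; provided for cross-checking.
    """
    x, y = curve.titrant_total, curve.bound_fraction
    fmax = float(np.max(y))
    if fmax < 1e-3:
        raise DegenerateDataError("curve never rises above zero")
    half = 0.5 * fmax
    above = np.nonzero(y >= half)[0]
    if above.size == 0 or above[0] == 0:
        raise FitError("half-saturation point not bracketed by the grid")
    i = above[0]
    x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    p_half = x0 + (half - y0) * (x1 - x0) / (y1 - y0)
    return float(p_half - 0.5 * curve.dna_total * fmax)


def cooperativity_factor(
    alone: KdEstimate, with_cofactor: KdEstimate
) -> CooperativityFactor:
    """Apparent cooperativity factor: aKd(alone) / aKd(with cofactor).

    The standard error follows first-order ratio propagation:
    ``se = value * sqrt((se_a/a)^2 + (se_w/w)^2)``.
    """
    value = alone.akd / with_cofactor.akd
    se = value * float(
        np.sqrt(
            (alone.se / alone.akd) ** 2 + (with_cofactor.se / with_cofactor.akd) ** 2
        )
    )
    return CooperativityFactor(value=value, se=se)


@dataclass
class TitrationResult:
    """One fitted titration, labeled for tabulation."""

    element: str
    titrant: str
    cofactor: Optional[Tuple[str, float]]
    estimate: KdEstimate


_TABLE_COLUMNS = [
    "element",
    "titrant",
    "cofactor_name",
    "cofactor_nM",
    "akd_nM",
    "akd_se_nM",
    "coop_factor",
    "coop_se",
    "formatted",
]


def summarize_table(
    results: Sequence[TitrationResult], ndigits: int = 1
) -> pd.DataFrame:
    """Tabulate aKds and cooperativity factors per element and titrant.

    Within each (element, titrant) group the cofactor-free entry is the
    baseline; every cofactor entry gets a parenthetical cooperativity
    factor relative to it, formatted the way affinity tables print them,
    e.g. ``"13.8 ± 3.0 (2.0 ± 0.6)*"``.
    """
    rows = []
    groups: dict[tuple[str, str], list[TitrationResult]] = {}
    for r in results:
        groups.setdefault((r.element, r.titrant), []).append(r)
    for (element, titrant), group in groups.items():
        baselines = [r for r in group if r.cofactor is None]
        cofs = [r for r in group if r.cofactor is not None]
        if cofs and not baselines:
            raise ReportingError(
                f"no cofactor-free baseline for element {element!r}, titrant {titrant!r}"
            )
        base = baselines[0] if baselines else None
        for r in group:
            akd_r = round_half_up(r.estimate.akd, ndigits)
            se_r = round_half_up(r.estimate.se, ndigits)
            if r.cofactor is None:
                coop_v = coop_s = float("nan")
                formatted = f"{akd_r} ± {se_r}"
            else:
                cf = cooperativity_factor(base.estimate, r.estimate)
                coop_v, coop_s = cf.rounded(ndigits)
                formatted = f"{akd_r} ± {se_r} ({coop_v} ± {coop_s})*"
            rows.append(
                {
                    "element": element,
                    "titrant": titrant,
                    "cofactor_name": None if r.cofactor is None else r.cofactor[0],
                    "cofactor_nM": float("nan") if r.cofactor is None else r.cofactor[1],
                    "akd_nM": r.estimate.akd,
                    "akd_se_nM": r.estimate.se,
                    "coop_factor": coop_v,
                    "coop_se": coop_s,
                    "formatted": formatted,
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    """Write `titrant_total_nM,bound_fraction[,se]` plus a JSON sidecar."""
    path = Path(path)
    cols = {"titrant_total_nM": curve.titrant_total, "bound_fraction": curve.bound_fraction}
    if curve.se is not None:
        cols["se"] = curve.se
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "dna_total_nM": curve.dna_total,
        "titrant": curve.titrant_name,
        "cofactor_name": None if curve.cofactor is None else curve.cofactor[0],
        "cofactor_total_nM": None if curve.cofactor is None else curve.cofactor[1],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_titration_csv(
    path: str | Path, sidecar: Optional[str | Path] = None
) -> TitrationCurve:
    """Read a titration CSV; metadata from the sidecar JSON when present."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"titrant_total_nM", "bound_fraction"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    meta: dict = {}
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    cof = None
    if meta.get("cofactor_name") is not None:
        cof = (meta["cofactor_name"], float(meta["cofactor_total_nM"]))
    return TitrationCurve(
        titrant_total=df["titrant_total_nM"].to_numpy(),
        bound_fraction=df["bound_fraction"].to_numpy(),
        se=df["se"].to_numpy() if "se" in df.columns else None,
        titrant_name=meta.get("titrant", "sox2"),
        dna_total=float(meta.get("dna_total_nM", 5.0)),
        cofactor=cof,
    )
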