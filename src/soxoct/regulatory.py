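"""Sox2-threshold model of target-gene response in the preimplantation embryo.

Maps per-cell Sox2 concentrations to motif occupancy and on/off expression
calls for Nanog, Fgf4 and Fgfr2.  Occupancy follows the single-site binding
isotherm with Kd equal to the gene's apparent dissociation constant for
Sox2; a gene under activation is called "on" when occupancy reaches a
threshold, while Fgfr2 — repressed by Sox2 through its intronic Sox motif —
is "on" when occupancy stays below it.  Because the Sox2 aKds order as
Nanog (31.7 nM) < Fgf4 (70.2 nM) <= Fgfr2 (81.2 nM), rising Sox2 switches
Nanog first, then Fgf4, and finally silences Fgfr2: the dose-response logic
that segregates epiblast (high Sox2: Fgf4 on, Fgfr2 off) from primitive
endoderm precursors (lower Sox2: Fgf4 off, Fgfr2 on) within the inner cell
mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .titration import isotherm

__all__ = [
    "TargetGeneParams",
    "CellState",
    "GeneResponse",
    "DEFAULT_GENES",
    "DEFAULT_THRESHOLD",
    "DEFAULT_STAGE_SOX2",
    "KNOWN_STAGES",
    "occupancy_profile",
    "classify_expression",
    "simulate_lineage_scenario",
    "default_scenario_cells",
]

#: Occupancy threshold separating "on" from "off".  Chosen below the
#: half-occupancy point so that a gene whose aKd modestly exceeds the
#: prevailing Sox2 level still switches; 0.4 places every default stage on
#: the correct side of the switch for all three genes.
DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class TargetGeneParams:
    """Apparent-Kd parameterization of one Sox2 target gene.

    ``akd_sox_alone`` is the Sox2-only aKd on the gene's element — the
    half-point of the Sox2 dose-response used by the lineage model.
    ``akd_with_cofactor`` (optional) is the aKd with Oct4 present at
    ``cofactor_oct4_nM``; it describes Oct4-assisted recruitment on
    composite motifs and is only used when explicitly requested.
    """

    name: str
    akd_sox_alone: float
    akd_with_cofactor: Optional[float] = None
    cofactor_oct4_nM: float = 40.0
    regulation_sign: str = "activated"

    def __post_init__(self) -> None:
        if not self.akd_sox_alone > 0:
            raise ValidationError("akd_sox_alone must be positive")
        if self.akd_with_cofactor is not None and not self.akd_with_cofactor > 0:
            raise ValidationError("akd_with_cofactor must be positive")
        if self.regulation_sign not in ("activated", "repressed"):
            raise ValidationError("regulation_sign must be 'activated' or 'repressed'")

    def effective_akd(self, oct4_nM: float = 0.0, oct4_assisted: bool = False) -> float:
        """aKd governing the Sox2 response at a given Oct4 level."""
        if (
            oct4_assisted
            and self.akd_with_cofactor is not None
            and oct4_nM > self.cofactor_oct4_nM
        ):
            return self.akd_with_cofactor
        return self.akd_sox_alone


DEFAULT_GENES = (
    TargetGeneParams("Nanog", akd_sox_alone=31.7, akd_with_cofactor=13.2),
    TargetGeneParams("Fgf4", akd_sox_alone=70.2, akd_with_cofactor=23.3),
    TargetGeneParams("Fgfr2", akd_sox_alone=81.2, regulation_sign="repressed"),
)

KNOWN_STAGES = (
    "4-cell",
    "8-cell",
    "16-cell",
    "morula",
    "early-inner",
    "late-inner",
    "ICM",
    "TE",
    "sox2-null",
)

#: Stand-in per-stage nuclear Sox2 concentrations (nM).  The inner-cell
#: values are the two assay concentrations the affinity measurements
#: contrast (37 and 72 nM); TE and maternal-only (Sox2-null) levels are
#: nominal, chosen so maternal Sox2 sustains Nanog but not Fgf4/Fgfr2
#: occupancy.  These are not measured cellular concentrations.
DEFAULT_STAGE_SOX2 = {
    "4-cell": 60.0,
    "8-cell": 45.0,
    "16-cell": 35.0,
    "morula": 35.0,
    "early-inner": 72.0,
    "late-inner": 37.0,
    "ICM": 72.0,
    "TE": 10.0,
    "sox2-null": 30.0,
}


@dataclass(frozen=True)
class CellState:
    """Per-cell transcription-factor concentrations (nM)."""

    cell_id: str
    stage: str
    sox2: float
    oct4: float = 40.0

    def __post_init__(self) -> None:
        if self.stage not in KNOWN_STAGES:
            raise ValidationError(
                f"unknown stage {self.stage!r}; known: {KNOWN_STAGES}"
            )
        if self.sox2 < 0 or self.oct4 < 0:
            raise ValidationError("concentrations must be non-negative")


@dataclass(frozen=True)
class GeneResponse:
    """Occupancy and expression call of one gene in one cell."""

    gene: str
    occupancy: float
    call: str


def occupancy_profile(
    gene: TargetGeneParams,
    sox2_grid: Iterable[float],
    dna_total: float = 0.0,
    oct4_nM: float = 40.0,
    oct4_assisted: bool = False,
) -> np.ndarray:
    """Motif occupancy across a Sox2 concentration grid.

    Uses the depletion-corrected isotherm; with ``dna_total = 0`` (the
    in-vivo regime, where a genomic locus is far below nM) this is the
    plain hyperbola S/(S + aKd).
    """
    grid = np.asarray(list(sox2_grid), dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValidationError("sox2 grid must be non-negative and non-decreasing")
    kd = gene.effective_akd(oct4_nM, oct4_assisted)
    return np.asarray(isotherm(grid, kd, dna_total), dtype=float)


def classify_expression(
    occupancy: float, threshold: float = DEFAULT_THRESHOLD, sign: str = "activated"
) -> str:
    """Threshold an occupancy into an on/off call.

    Activated targets are on when occupancy >= threshold; repressed targets
    (Fgfr2) are on when occupancy < threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    if sign not in ("activated", "repressed"):
        raise ValidationError("sign must be 'activated' or 'repressed'")
    if sign == "activated":
        return "on" if occupancy >= threshold else "off"
    return "on" if occupancy < threshold else "off"


def simulate_lineage_scenario(
    cells: Sequence[CellState],
    genes: Sequence[TargetGeneParams] = DEFAULT_GENES,
    threshold: float = DEFAULT_THRESHOLD,
    dna_total: float = 0.0,
    oct4_assisted: bool = False,
) -> pd.DataFrame:
    """Per-cell, per-gene occupancy and expression calls.

    Deterministic: each row is (cell_id, stage, gene, occupancy, call).
    """
    if not cells or not genes:
        raise ValidationError("cells and genes must be non-empty")
    rows = []
    for cell in cells:
        for gene in genes:
            occ = float(
                occupancy_profile(
                    gene, [cell.sox2], dna_total, cell.oct4, oct4_assisted
                )[0]
            )
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "stage": cell.stage,
                    "gene": gene.name,
                    "occupancy": occ,
                    "call": classify_expression(occ, threshold, gene.regulation_sign),
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "stage", "gene", "occupancy", "call"])


def default_scenario_cells() -> List[CellState]:
    """One representative cell per lineage-relevant condition."""
    return [
        CellState("early-inner-1", "early-inner", DEFAULT_STAGE_SOX2["early-inner"]),
        CellState("late-inner-1", "late-inner", DEFAULT_STAGE_SOX2["late-inner"]),
        CellState("TE-1", "TE", DEFAULT_STAGE_SOX2["TE"]),
        CellState("sox2-null-1", "sox2-null", DEFAULT_STAGE_SOX2["sox2-null"]),
    ]
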