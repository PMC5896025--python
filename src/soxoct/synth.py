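"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its configuration and seed and returns
a manifest recording the ground truth alongside the data, so any downstream
stage can be scored without re-deriving it.  Default noise levels emulate
the corresponding wet-lab readouts: Gaussian noise of sd 0.05 on bound
fractions (titration scatter), amplitude-proportional noise on ACF curves,
and lognormal (sigma 0.3) per-cell protein levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

from . import binding, fcs, motifs, regulatory
from .binding import BindingParameters, ReadoutMode
from .errors import ValidationError
from .titration import TitrationCurve, _FRACTION_MAX

__all__ = [
    "GeneratorConfig",
    "generate_titration_dataset",
    "generate_acf_dataset",
    "generate_promoter_set",
    "generate_cell_population",
    "write_fasta",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generator defaults; the study conditions, not tuning dials."""

    seed: int = 0
    titration_noise_sd: float = 0.05
    titration_n_points: int = 10
    titrant_min_nM: float = 1.0
    titrant_max_nM: float = 500.0
    acf_noise_scale: float = 0.02
    lognormal_sigma: float = 0.3
    embed_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("titration_noise_sd", "acf_noise_scale", "lognormal_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def _grid(config_n: int, lo: float = 1.0, hi: float = 500.0) -> np.ndarray:
    return np.geomspace(lo, hi, config_n)


def generate_titration_dataset(
    params: BindingParameters,
    dna_total: float = 5.0,
    titrant: str = "sox",
    cofactor: Optional[Tuple[str, float]] = None,
    noise_sd: float = 0.05,
    n_points: int = 10,
    grid: Optional[Iterable[float]] = None,
    mode: ReadoutMode = ReadoutMode.TITRANT_BOUND,
    seed: int | np.random.Generator = 0,
) -> Tuple[TitrationCurve, Dict]:
    """Noisy bound-fraction titration from known truth, with manifest.

    Bound fractions are the two-site model prediction plus Gaussian noise
    of sd ``noise_sd``, clipped to [0, 1.05].
    """
    if n_points < 4:
        raise ValidationError("n_points must be >= 4")
    g = _grid(n_points) if grid is None else np.asarray(list(grid), dtype=float)
    clean = binding.simulate_titration(
        params, dna_total=dna_total, titrant=titrant, titrant_grid=g,
        cofactor=cofactor, mode=mode,
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = np.clip(
        clean.bound_fraction + rng.normal(0.0, noise_sd, size=g.size), 0.0, _FRACTION_MAX
    )
    curve = TitrationCurve(
        titrant_total=g,
        bound_fraction=noisy,
        se=np.full(g.size, noise_sd) if noise_sd > 0 else None,
        titrant_name=titrant,
        dna_total=dna_total,
        cofactor=cofactor,
    )
    manifest = {
        "kd_sox": params.kd_sox,
        "kd_oct": params.kd_oct,
        "omega": params.omega,
        "dna_total": dna_total,
        "titrant": titrant,
        "cofactor": cofactor,
        "noise_sd": noise_sd,
        "mode": mode.value,
        "true_bound_fraction": clean.bound_fraction.tolist(),
    }
    return curve, manifest


def generate_acf_dataset(
    params: BindingParameters,
    dna_total: float = 5.0,
    titrant: str = "sox",
    cofactor: Optional[Tuple[str, float]] = None,
    titrant_grid: Optional[Iterable[float]] = None,
    volume: fcs.ConfocalVolume = fcs.DEFAULT_VOLUME,
    tau_free: float = 1e-4,
    tau_bound: float = 4e-4,
    triplet_fraction: float = 0.0,
    triplet_tau: float = 2e-6,
    noise_sd_scale: float = 0.02,
    mode: ReadoutMode = ReadoutMode.TITRANT_BOUND,
    seed: int = 0,
) -> Tuple[List[fcs.AcfCurve], Dict]:
    """One ACF curve per titration point, tracking labeled DNA.

    At each titrant level the bound DNA fraction comes from the equilibrium
    model; the ACF mixes a fast free-DNA component (``tau_free``) and a
    slow bound component (``tau_bound``) with those fractions.  The
    particle number reflects the constant DNA concentration in the
    confocal volume.
    """
    g = binding.DEFAULT_TITRANT_GRID if titrant_grid is None else np.asarray(
        list(titrant_grid), dtype=float
    )
    clean = binding.simulate_titration(
        params, dna_total=dna_total, titrant=titrant, titrant_grid=g,
        cofactor=cofactor, mode=mode,
    )
    n_dna = fcs.n_from_concentration(dna_total, volume)
    rng = np.random.default_rng(seed)
    curves = []
    for bf in clean.bound_fraction:
        acf_params = fcs.AcfModelParams(
            n_particles=n_dna,
            components=[(tau_free, 1.0 - float(bf)), (tau_bound, float(bf))],
            triplet_fraction=triplet_fraction,
            triplet_tau=triplet_tau,
        )
        curves.append(
            fcs.simulate_acf(
                acf_params, volume, noise_sd_scale=noise_sd_scale, seed=rng
            )
        )
    manifest = {
        "kd_sox": params.kd_sox,
        "kd_oct": params.kd_oct,
        "omega": params.omega,
        "dna_total": dna_total,
        "titrant": titrant,
        "cofactor": cofactor,
        "titrant_grid": g.tolist(),
        "tau_free": tau_free,
        "tau_bound": tau_bound,
        "n_particles": n_dna,
        "noise_sd_scale": noise_sd_scale,
        "true_bound_fraction": clean.bound_fraction.tolist(),
    }
    return curves, manifest


def _sample_instance(
    spec: motifs.CompositeMotifSpec, rng: np.random.Generator
) -> Tuple[str, int, str]:
    """Draw one concrete (sequence, spacer, order) from the degenerate spec."""
    spacer = int(rng.integers(spec.spacer_min, spec.spacer_max + 1))
    order = spec.orders[int(rng.integers(len(spec.orders)))]
    sox = "".join(rng.choice(list(motifs.IUPAC[s].replace("N", ""))) if s == "N"
                  else rng.choice(list(motifs.IUPAC[s])) for s in spec.sox_pattern)
    oct_ = "".join(rng.choice(list(motifs.IUPAC[s].replace("N", ""))) if s == "N"
                   else rng.choice(list(motifs.IUPAC[s])) for s in spec.oct_pattern)
    spacer_seq = "".join(rng.choice(list("ACGT"), size=spacer))
    if order == "sox_first":
        text = sox + spacer_seq + oct_
    else:
        text = oct_ + spacer_seq + sox
    return text, spacer, order


def generate_promoter_set(
    n: int,
    length: int = 500,
    spec: motifs.CompositeMotifSpec = motifs.CompositeMotifSpec(),
    embed_rate: float = 1.0,
    seed: int = 0,
    clean_background: bool = True,
    max_resample: int = 50,
) -> Tuple[List[SeqRecord], pd.DataFrame]:
    """Random promoter-like sequences with embedded composite motifs.

    Each sequence gets an embedded instance with probability ``embed_rate``,
    sampled from the degenerate patterns at a random position, spacer and
    (if scanning both strands) strand; the manifest records every plant.
    With ``clean_background`` (default) backgrounds that happen to contain
    spurious pattern matches are resampled, so the manifest is the complete
    ground truth for scanner scoring.
    """
    max_len = (
        len(spec.sox_pattern) + len(spec.oct_pattern) + spec.spacer_max
    )
    if length < max_len:
        raise ValidationError(
            f"length {length} cannot hold a motif of up to {max_len} bp"
        )
    if not 0.0 <= embed_rate <= 1.0:
        raise ValidationError("embed_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records: List[SeqRecord] = []
    manifest_rows = []
    for i in range(n):
        seq_id = f"promoter_{i:04d}"
        plant = rng.random() < embed_rate
        for _ in range(max_resample):
            background = "".join(rng.choice(list("ACGT"), size=length))
            expected = []
            seq = background
            if plant:
                text, spacer, order = _sample_instance(spec, rng)
                strand = "+"
                if spec.strands == "both" and rng.random() < 0.5:
                    strand = "-"
                insert = text if strand == "+" else str(Seq(text).reverse_complement())
                pos = int(rng.integers(0, length - len(text) + 1))
                seq = background[:pos] + insert + background[pos + len(insert):]
                expected.append(
                    {
                        "seq_id": seq_id,
                        "start": pos,
                        "end": pos + len(insert),
                        "strand": strand,
                        "spacer": spacer,
                        "order": order,
                        "instance": text,
                    }
                )
            if not clean_background:
                break
            hits = motifs.scan_sequence(seq, spec, seq_id=seq_id)
            keys = {(h.start, h.end, h.strand) for h in hits}
            want = {(e["start"], e["end"], e["strand"]) for e in expected}
            if keys == want:
                break
        else:
            raise ValidationError(
                "could not generate a clean background; sequence too short or "
                "pattern too permissive"
            )
        records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
        manifest_rows.extend(expected)
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["seq_id", "start", "end", "strand", "spacer", "order", "instance"],
    )
    return records, manifest


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def generate_cell_population(
    stage_means: Optional[Dict[str, float]] = None,
    lognormal_sigma: float = 0.3,
    n_per_stage: int = 50,
    seed: int = 0,
    oct4_mean: float = 40.0,
    oct4_sigma: float = 0.1,
) -> List[regulatory.CellState]:
    """Lognormal per-cell Sox2 (and Oct4) levels across embryo stages.

    Stage means default to the developmental trend — high at the 4-cell
    stage, declining to the 16-cell morula, rising again in the ICM and
    lowest in the TE.  ``lognormal_sigma = 0`` collapses every cell onto
    its stage mean; means are preserved exactly (mu = ln m - sigma^2/2).
    """
    if stage_means is None:
        stage_means = {
            s: regulatory.DEFAULT_STAGE_SOX2[s]
            for s in ("4-cell", "8-cell", "16-cell", "ICM", "TE")
        }
    for stage, m in stage_means.items():
        if stage not in regulatory.KNOWN_STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        if not m > 0:
            raise ValidationError("stage means must be positive")
    rng = np.random.default_rng(seed)
    cells = []
    for stage, mean in stage_means.items():
        for j in range(n_per_stage):
            if lognormal_sigma > 0:
                mu = np.log(mean) - 0.5 * lognormal_sigma**2
                sox2 = float(rng.lognormal(mu, lognormal_sigma))
            else:
                sox2 = mean
            if oct4_sigma > 0:
                mu_o = np.log(oct4_mean) - 0.5 * oct4_sigma**2
                oct4 = float(rng.lognormal(mu_o, oct4_sigma))
            else:
                oct4 = oct4_mean
            cells.append(
                regulatory.CellState(f"{stage}_{j:03d}", stage, sox2=sox2, oct4=oct4)
            )
    return cells
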