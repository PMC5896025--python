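"""Composite Sox/Oct motif scanning and conservation profiling.

The composite element is a Sox2 half-site (consensus CTTTG(A/T)(A/T)) next
to an octamer half-site (ATGC(A/T)AA(T/A)) separated by a 0-3 bp spacer.
The default Sox pattern here is relaxed to CWTTGTW because characterized
elements vary at exactly positions 2 and 7 (Nanog CATTGTA, Utf1 CATTGTT,
Sox2 CATTGTG, Fgf4 CTTTGTT); the stricter consensus remains available as
:data:`CANONICAL_SOX_PATTERN`.  Coordinates are 0-based half-open (BED
convention); overlapping hits are all reported.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

__all__ = [
    "IUPAC",
    "CANONICAL_SOX_PATTERN",
    "DEFAULT_OCT_PATTERN",
    "CompositeMotifSpec",
    "MotifHit",
    "ConservationProfile",
    "scan_sequence",
    "scan_fasta",
    "hits_to_frame",
    "hits_to_bed",
    "conservation_profile",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Strict Sox half-site consensus, CTTTG(A/T)(A/T).
CANONICAL_SOX_PATTERN = "CTTTGWW"
#: Octamer half-site, ATGC(A/T)AA(T/A).
DEFAULT_OCT_PATTERN = "ATGCWAAW"


def _iupac_regex(pattern: str) -> str:
    parts = []
    for sym in pattern:
        allowed = IUPAC[sym]
        # An N in the scanned sequence only ever matches a pattern N.
        if sym == "N":
            parts.append("[ACGTN]")
        elif len(allowed) == 1:
            parts.append(allowed)
        else:
            parts.append(f"[{allowed}]")
    return "".join(parts)


@dataclass(frozen=True)
class CompositeMotifSpec:
    """Two degenerate half-sites with a bounded spacer.

    ``order`` controls whether the Sox half-site precedes the octamer
    (``sox_first``, the arrangement of the characterized elements), the
    reverse (``oct_first``), or both are scanned.  ``strands`` is
    ``"forward"`` or ``"both"``.
    """

    sox_pattern: str = "CWTTGTW"
    oct_pattern: str = DEFAULT_OCT_PATTERN
    spacer_min: int = 0
    spacer_max: int = 3
    order: str = "sox_first"
    strands: str = "both"

    def __post_init__(self) -> None:
        for name, pat in (("sox_pattern", self.sox_pattern), ("oct_pattern", self.oct_pattern)):
            if not pat:
                raise ValidationError(f"{name} must be non-empty")
            bad = [s for s in pat if s not in IUPAC]
            if bad:
                raise ValidationError(f"{name} contains non-IUPAC symbols: {bad}")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValidationError("need 0 <= spacer_min <= spacer_max")
        if self.order not in ("sox_first", "oct_first", "both"):
            raise ValidationError("order must be sox_first, oct_first or both")
        if self.strands not in ("forward", "both"):
            raise ValidationError("strands must be forward or both")

    @property
    def orders(self) -> Tuple[str, ...]:
        return ("sox_first", "oct_first") if self.order == "both" else (self.order,)


@dataclass(frozen=True)
class MotifHit:
    """One composite-motif match, 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    spacer: int
    order: str
    matched_text: str
    sox_site: Tuple[int, int]
    oct_site: Tuple[int, int]

    @property
    def half_site_coords(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return self.sox_site, self.oct_site


def _forward_hits(
    seq: str, spec: CompositeMotifSpec, seq_id: str, strand: str, seq_len: int
) -> List[MotifHit]:
    """Scan one strand's text; map coordinates back if it is the minus strand."""
    hits: List[MotifHit] = []
    lsox, loct = len(spec.sox_pattern), len(spec.oct_pattern)
    for order in spec.orders:
        first_re, first_len = (
            (_iupac_regex(spec.sox_pattern), lsox)
            if order == "sox_first"
            else (_iupac_regex(spec.oct_pattern), loct)
        )
        second_re, second_len = (
            (_iupac_regex(spec.oct_pattern), loct)
            if order == "sox_first"
            else (_iupac_regex(spec.sox_pattern), lsox)
        )
        for spacer in range(spec.spacer_min, spec.spacer_max + 1):
            pat = re.compile(
                f"(?=({first_re}[ACGTN]{{{spacer}}}{second_re}))"
            )
            total = first_len + spacer + second_len
            for m in pat.finditer(seq):
                p = m.start()
                first_iv = (p, p + first_len)
                second_iv = (p + first_len + spacer, p + total)
                sox_iv, oct_iv = (
                    (first_iv, second_iv) if order == "sox_first" else (second_iv, first_iv)
                )
                if strand == "+":
                    start, end = p, p + total
                    sox_g, oct_g = sox_iv, oct_iv
                else:
                    start, end = seq_len - (p + total), seq_len - p
                    sox_g = (seq_len - sox_iv[1], seq_len - sox_iv[0])
                    oct_g = (seq_len - oct_iv[1], seq_len - oct_iv[0])
                hits.append(
                    MotifHit(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        strand=strand,
                        spacer=spacer,
                        order=order,
                        matched_text=m.group(1),
                        sox_site=sox_g,
                        oct_site=oct_g,
                    )
                )
    return hits


def scan_sequence(
    seq: str, spec: CompositeMotifSpec, seq_id: str = "seq"
) -> List[MotifHit]:
    """All composite-motif hits in a sequence, sorted by (start, strand).

    Overlapping hits are all reported.  Minus-strand hits carry genomic
    (plus-strand) coordinates; their ``matched_text`` is the minus-strand
    sequence that matches the pattern.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"sequence contains non-DNA characters: {sorted(bad)}")
    hits = _forward_hits(seq, spec, seq_id, "+", len(seq))
    if spec.strands == "both":
        rc = str(Seq(seq).reverse_complement())
        hits += _forward_hits(rc, spec, seq_id, "-", len(seq))
    hits.sort(key=lambda h: (h.start, h.strand, h.end, h.order))
    return hits


def scan_fasta(path: str | Path, spec: CompositeMotifSpec) -> pd.DataFrame:
    """Scan every record of a FASTA file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    all_hits: List[MotifHit] = []
    try:
        with opener(path, "rt") as fh:
            for record in SeqIO.parse(fh, "fasta"):
                all_hits += scan_sequence(str(record.seq), spec, seq_id=record.id)
    except (OSError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot read FASTA {path}: {exc}") from exc
    except ValidationError as exc:
        raise FormatError(f"malformed record in {path}: {exc}") from exc
    return hits_to_frame(all_hits)


_FRAME_COLUMNS = [
    "seq_id", "start", "end", "strand", "spacer", "order", "matched_text",
    "sox_start", "sox_end", "oct_start", "oct_end",
]


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": h.seq_id, "start": h.start, "end": h.end, "strand": h.strand,
            "spacer": h.spacer, "order": h.order, "matched_text": h.matched_text,
            "sox_start": h.sox_site[0], "sox_end": h.sox_site[1],
            "oct_start": h.oct_site[0], "oct_end": h.oct_site[1],
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def _half_site_identity(text: str, pattern: str) -> float:
    """Fraction of positions where the base is allowed by the pattern symbol."""
    ok = sum(1 for b, s in zip(text, pattern) if b in IUPAC[s])
    return ok / len(pattern)


def hits_to_bed(hits: Sequence[MotifHit], spec: CompositeMotifSpec) -> List[str]:
    """BED6 lines: name encodes order and spacer, score = 1000 * min half-site identity."""
    lines = []
    for h in hits:
        lsox = len(spec.sox_pattern)
        if h.order == "sox_first":
            sox_txt = h.matched_text[:lsox]
            oct_txt = h.matched_text[lsox + h.spacer:]
        else:
            loct = len(spec.oct_pattern)
            oct_txt = h.matched_text[:loct]
            sox_txt = h.matched_text[loct + h.spacer:]
        score = int(
            1000
            * min(
                _half_site_identity(sox_txt, spec.sox_pattern),
                _half_site_identity(oct_txt, spec.oct_pattern),
            )
        )
        name = f"{h.order}:s{h.spacer}"
        lines.append(
            f"{h.seq_id}\t{h.start}\t{h.end}\t{name}\t{score}\t{h.strand}"
        )
    return lines


@dataclass
class ConservationProfile:
    """Per-position identity fractions over an ungapped motif alignment."""

    identity: np.ndarray
    consensus: str


def conservation_profile(instances: Sequence[str]) -> ConservationProfile:
    """Per-position fraction of instances matching the modal base.

    Ties in the modal base are broken alphabetically for the consensus
    display.  Requires >= 2 equal-length ungapped instances.
    """
    if len(instances) < 2:
        raise ValidationError("need at least 2 motif instances")
    instances = [s.upper() for s in instances]
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValidationError("motif instances must all have equal length")
    for s in instances:
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValidationError(f"non-DNA characters in instance: {sorted(bad)}")
    arr = np.array([list(s) for s in instances])
    identity = np.empty(length)
    consensus = []
    for j in range(length):
        col = arr[:, j]
        bases, counts = np.unique(col, return_counts=True)
        best = counts.max()
        identity[j] = best / len(instances)
        # np.unique sorts lexically, so argmax already breaks ties alphabetically
        consensus.append(str(bases[np.argmax(counts)]))
    return ConservationProfile(identity=identity, consensus="".join(consensus))
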