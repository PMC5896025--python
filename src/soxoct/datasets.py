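"""Published apparent-Kd measurements for Sox2/Oct4 on composite motifs.

Apparent dissociation constants (aKd, nM) from FCS titration assays at a
constant 5 nM DNA concentration in unpurified CHO nuclear lysate, for the
Nanog, Fgf4 and Utf1 composite Sox/Oct elements.  Each entry gives the aKd
of the titrated protein alone or in the presence of a fixed concentration of
the partner protein; the parenthetical cooperativity factors printed next to
the with-cofactor entries are the ratios aKd(alone)/aKd(with), which this
package recomputes rather than storing.

These measured values are inputs to downstream analysis (they derive from
raw fluorescence data that is not reproducible in silico).
"""

from __future__ import annotations

from typing import Optional, Tuple

from .titration import KdEstimate

__all__ = [
    "AKD_TABLE",
    "FGFR2_SOX_AKD",
    "NANOG_SOX_OCT_OLIGO",
    "SOX_HALF_SITES",
    "SOX2_COFACTOR_LEVELS_NM",
    "OCT4_COFACTOR_LEVEL_NM",
    "DNA_TOTAL_NM",
]

#: DNA concentration held constant in every titration (nM).
DNA_TOTAL_NM = 5.0
#: Sox2 cofactor levels used in the Oct4 titrations (nM).
SOX2_COFACTOR_LEVELS_NM = (37.0, 72.0)
#: Oct4 cofactor level used in the Sox2 titrations (nM).
OCT4_COFACTOR_LEVEL_NM = 40.0

#: (element, titrant, cofactor or None) -> KdEstimate(akd, se) in nM.
AKD_TABLE: dict[Tuple[str, str, Optional[Tuple[str, float]]], KdEstimate] = {
    # Oct4 titrations
    ("Nanog", "oct4", None): KdEstimate(28.2, 4.9),
    ("Nanog", "oct4", ("sox2", 37.0)): KdEstimate(13.8, 3.0),
    ("Nanog", "oct4", ("sox2", 72.0)): KdEstimate(11.6, 2.4),
    ("Fgf4", "oct4", None): KdEstimate(42.5, 5.5),
    ("Fgf4", "oct4", ("sox2", 37.0)): KdEstimate(49.1, 5.0),
    ("Fgf4", "oct4", ("sox2", 72.0)): KdEstimate(25.2, 4.1),
    ("Utf1", "oct4", None): KdEstimate(32.0, 5.5),
    ("Utf1", "oct4", ("sox2", 37.0)): KdEstimate(19.8, 7.3),
    ("Utf1", "oct4", ("sox2", 72.0)): KdEstimate(15.5, 6.0),
    # Sox2 titrations
    ("Nanog", "sox2", None): KdEstimate(31.7, 4.6),
    ("Nanog", "sox2", ("oct4", 40.0)): KdEstimate(13.2, 6.5),
    ("Fgf4", "sox2", None): KdEstimate(70.2, 19.1),
    ("Fgf4", "sox2", ("oct4", 40.0)): KdEstimate(23.3, 1.2),
    ("Utf1", "sox2", None): KdEstimate(44.0, 9.8),
    ("Utf1", "sox2", ("oct4", 40.0)): KdEstimate(43.4, 1.5),
}

#: Sox2-only aKd on the intronic Fgfr2 Sox motif (no adjacent octamer site).
FGFR2_SOX_AKD = KdEstimate(81.2, 15.1)

#: Wild-type Nanog composite Sox/Oct oligo (Sox half-site + octamer, 0 bp spacer).
NANOG_SOX_OCT_OLIGO = "CATTGTAATGCAAAA"

#: Sox half-site variants of the characterized elements.
SOX_HALF_SITES = {
    "Nanog": "CATTGTA",
    "Utf1": "CATTGTT",
    "Sox2": "CATTGTG",
    "Fgf4": "CTTTGTT",
}
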