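"""Ballesteros-Weinstein identifiers and topological region labels.

The Ballesteros-Weinstein (BW) scheme gives every transmembrane (TM)
residue of a GPCR a universal identifier X.YY: X is the TM helix number
(1-7) and YY counts relative to the most conserved position of that
helix, which is defined to be X.50. A residue two positions before the
TM6 anchor is therefore 6.48 in any receptor. Residues outside the seven
TM helices carry a region label instead (N-term, EL1-3, IL1-3, H8,
C-term).

TM boundaries are configuration, not computation: the shipped default
scheme encodes beta-2 adrenergic receptor boundaries built around the
canonical anchors (1.50 Asn 51, 2.50 Asp 79, 3.50 Arg 131, 4.50 Trp 158,
5.50 Pro 211, 6.50 Pro 288, 7.50 Pro 323) with standard helix spans, and
is clearly editable for other receptors or boundary choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


@dataclass
class BWScheme:
    """Anchors, TM ranges and non-TM region labels for one receptor.

    anchors : TM index (1-7) -> author seq number of the X.50 residue.
    tm_ranges : TM index -> (start, end), author numbering, inclusive.
    regions : ordered (label, (start, end)) for non-TM stretches.
    """

    anchors: dict[int, int]
    tm_ranges: dict[int, tuple[int, int]]
    regions: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self):
        for tm, anchor in self.anchors.items():
            lo, hi = self.tm_ranges[tm]
            if not lo <= anchor <= hi:
                raise ValueError(f"anchor {anchor} for TM{tm} outside its range ({lo}, {hi})")
        spans = sorted(self.tm_ranges.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise ValueError("TM ranges must be disjoint and ordered")


def beta2ar_scheme() -> BWScheme:
    """The shipped beta-2 adrenergic receptor numbering scheme."""
    return BWScheme(
        anchors={1: 51, 2: 79, 3: 131, 4: 158, 5: 211, 6: 288, 7: 323},
        tm_ranges={
            1: (29, 60), 2: (67, 96), 3: (103, 136), 4: (147, 171),
            5: (197, 229), 6: (267, 298), 7: (305, 328),
        },
        regions=[
            ("N-term", (1, 28)), ("IL1", (61, 66)), ("EL1", (97, 102)),
            ("IL2", (137, 146)), ("EL2", (172, 196)), ("IL3", (230, 266)),
            ("EL3", (299, 304)), ("H8", (329, 342)), ("C-term", (343, 413)),
        ],
    )


def assign_bw(res_seq: int, scheme: BWScheme) -> str:
    """BW identifier ("6.48") for TM residues, region label otherwise.

    A residue inside TM X gets "X." followed by 50 + (res_seq - anchor_X);
    outside every declared range the label is "unassigned" (logged).
    """
    for tm, (lo, hi) in scheme.tm_ranges.items():
        if lo <= res_seq <= hi:
            return f"{tm}.{50 + (res_seq - scheme.anchors[tm])}"
    for label, (lo, hi) in scheme.regions:
        if lo <= res_seq <= hi:
            return label
    logger.info("residue %d outside every declared range", res_seq)
    return "unassigned"
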