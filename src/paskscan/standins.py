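"""Synthetic stand-in sequences emulating published compositional statistics.

Every sequence in this module is SYNTHETIC — constructed residue by residue
to reproduce the printed compositional statistics of real proteins (lengths,
per-region lysine counts, and which composition thresholds their lysine-rich
regions pass), not their actual residues.  They make region arithmetic and
threshold-sweep behaviour demonstrable and testable offline; none of them
should be mistaken for a database sequence.

The emulated facts:

* A GTPase-activating protein of 169 residues whose C-terminus carries a
  canonical PASK motif (passes the 75% D/E/S/K test, two lysines) and whose
  N-terminal 45 residues carry a "PASK-like" region that only passes at the
  relaxed 50% threshold and contains exactly seven lysines.
* An exoribonuclease of 813 residues with domain boundaries 1-216 (cold
  shock), 217-643 (nuclease), 644-730 (S1) and 731-813 (basic), carrying 27
  lysines across residues 644-813, whose basic domain passes only the 50%
  threshold.
* A seven-protein polyP-binding screen-hit panel in which exactly one
  protein passes the 75% test, three pass at 60%, and all seven at 50%.
"""

from __future__ import annotations

from itertools import cycle, islice

from .motif import ProteinSequence
from .proteome import ProteomeRecordSet

__all__ = [
    "synthetic_yihi",
    "synthetic_rnr",
    "synthetic_screen_hits",
    "YIHI_LENGTH",
    "YIHI_NTERM_TRUNCATION",
    "RNR_LENGTH",
    "RNR_DOMAINS",
]

#: Published lengths and boundaries the stand-ins reproduce.
YIHI_LENGTH = 169
YIHI_NTERM_TRUNCATION = (1, 45)  # N-terminal truncation studied for the GAP
RNR_LENGTH = 813
RNR_DOMAINS = {
    "cold_shock": (1, 216),
    "nuclease": (217, 643),
    "S1": (644, 730),
    "basic": (731, 813),
}

_FILLER = "ALGVPT"  # residues outside the D/E/S/K class


def _filler(n: int, phase: int = 0) -> str:
    return "".join(islice(cycle(_FILLER), phase, phase + n))


def _alternating(counted: str) -> str:
    """Interleave counted residues with non-counted filler: c f c f ... c.

    Every 20-residue window of the result contains exactly 10 counted
    residues, so the segment passes a 50% composition test everywhere but
    can never reach 60%.
    """
    out = []
    fill = cycle(_FILLER)
    for i, aa in enumerate(counted):
        out.append(aa)
        if i < len(counted) - 1:
            out.append(next(fill))
    return "".join(out)


def synthetic_yihi() -> ProteinSequence:
    """Synthetic 169-residue stand-in for the Der-activating GAP.

    Layout (1-based): residues 6-35 hold an alternating lysine/acidic
    segment with exactly seven lysines (the 50%-only "PASK-like" region,
    inside the 1-45 N-terminal truncation); residues 148-167 hold a
    canonical PASK window (15/20 D/E/S/K, two lysines, passes 75%).
    Everything else is non-D/E/S/K filler.
    """
    # 15 counted residues, K at odd indices 1,3,5,... of this list -> segment
    # positions 1,5,9,...,25: max inter-lysine gap 4, so every window has a K.
    nterm_counted = "KDKEKSKDKEKSKDE"
    nterm = _alternating(nterm_counted)  # 29 residues
    assert nterm.count("K") == 7
    cterm = "DESDESDESDESD" + "KK" + "AGLVA"  # 20 residues, 15 counted, 2 K

    seq = _filler(5) + nterm + _filler(147 - (5 + len(nterm))) + cterm + _filler(2)
    assert len(seq) == YIHI_LENGTH
    return ProteinSequence(
        identifier="SYNTH_YIHI",
        residues=seq,
        description="synthetic stand-in: 169 aa, 7 N-terminal lysines in a "
        "50%-threshold PASK-like region, C-terminal 75% PASK motif",
    )


def synthetic_rnr() -> ProteinSequence:
    """Synthetic 813-residue stand-in for the exoribonuclease.

    The S1 region (644-730) carries ten isolated lysines in a non-acidic
    context (no window qualifies at any threshold); the basic domain
    (731-813) is an alternating lysine/acidic segment with seventeen
    lysines that qualifies only at the 50% threshold.  Residues 644-813
    therefore contain exactly 27 lysines.
    """
    body = _filler(643)

    # S1: 10 lysines spaced 9 apart in filler; max 3 per window, never 10 counted.
    s1 = []
    fill = cycle(_FILLER)
    for i in range(87):
        s1.append("K" if i % 9 == 0 and i // 9 < 10 else next(fill))
    s1 = "".join(s1)
    assert len(s1) == 87 and s1.count("K") == 10

    # basic: alternating segment, 42 counted residues, K at the first 17 odd
    # slots (positions 1,5,...,65), D/E/S elsewhere.
    counted = []
    des = cycle("DES")
    for j in range(42):
        counted.append("K" if j % 2 == 0 and j // 2 < 17 else next(des))
    basic = _alternating("".join(counted))  # 83 residues
    assert len(basic) == 83 and basic.count("K") == 17

    seq = body + s1 + basic
    assert len(seq) == RNR_LENGTH
    return ProteinSequence(
        identifier="SYNTH_RNR",
        residues=seq,
        description="synthetic stand-in: 813 aa, 27 lysines in residues "
        "644-813, basic domain qualifies only at the 50% threshold",
    )


def _planted_protein(
    identifier: str, length: int, plant: str, at: int, note: str
) -> ProteinSequence:
    before = _filler(at - 1)
    after = _filler(length - (at - 1) - len(plant), phase=3)
    seq = before + plant + after
    assert len(seq) == length
    return ProteinSequence(identifier=identifier, residues=seq, description=note)


def synthetic_screen_hits() -> ProteomeRecordSet:
    """Seven synthetic stand-ins for the polyP-binding screen hits.

    Threshold profile by construction: one protein (the GAP stand-in)
    passes at 75%; it plus two more pass at 60%; all seven pass at 50%.
    """
    note60 = "synthetic stand-in: 60%-threshold region (13/20 D/E/S/K)"
    note50 = "synthetic stand-in: 50%-only region (alternating, 10/20)"
    # 13 counted incl. 2 K -> passes 60% (needs 12), fails 75% (needs 15)
    plant60 = "DEKSDEKSDESDE" + _filler(7)
    # alternating, 4 K at positions 1,9,17,25 -> every window holds a K
    plant50 = _alternating("KDESKDESKDESKDE")  # 29 aa

    records = [
        _planted_protein("SYNTH_SRMB", 444, plant50, 200, note50),
        synthetic_yihi(),
        synthetic_rnr(),
        _planted_protein("SYNTH_RSGA", 350, plant50, 120, note50),
        _planted_protein("SYNTH_SMPB", 160, plant50, 60, note50),
        _planted_protein("SYNTH_INFB", 890, plant60, 400, note60),
        _planted_protein("SYNTH_RNE", 1061, plant60, 850, note60),
    ]
    return ProteomeRecordSet(source_label="synthetic_screen_hits", records=records)
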