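"""Core compositional motif test and single-sequence scanning.

A PASK (polyacidic serine/lysine-rich) motif is defined compositionally: a
fixed-length window of residues (default 20) in which a counted residue
class (default D, E, S, K) occupies at least a threshold fraction of the
positions (default 75%, i.e. 15 of 20) and which additionally contains a
minimum number of specific required residues (default at least one lysine).
Lysine-rich acidic stretches of this kind are the canonical binding sites of
inorganic polyphosphate (polyP) on target proteins.

The scan slides the window one residue at a time along a protein, maintaining
incremental residue counts; overlapping or abutting qualifying windows can be
merged into maximal motif regions for reporting.  All coordinates are 1-based
and inclusive at both ends, matching the residue-range convention used in
protein domain annotation (e.g. "residues 644-730").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STANDARD_AA",
    "AMBIGUOUS_AA",
    "MotifConfig",
    "ProteinSequence",
    "QualifyingWindow",
    "MotifRegion",
    "min_composition_count",
    "window_qualifies",
    "scan_sequence",
    "merge_windows",
    "has_motif",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/rare codes tolerated on ingest (counted as non-matching).
AMBIGUOUS_AA = frozenset("XBZJUO")


def _as_fraction(value: float | str | Fraction | int) -> Fraction:
    """Normalize a threshold given as Fraction, decimal string, percentage
    string ("75%"), int, or float into an exact :class:`Fraction`.

    Floats are snapped to the nearest small-denominator rational so that a
    user-supplied ``0.6`` means exactly 3/5, not the nearest binary float.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            return Fraction(s[:-1].strip()) / 100
        return Fraction(s)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**6)
    raise TypeError(f"cannot interpret threshold of type {type(value).__name__}")


@dataclass(frozen=True)
class MotifConfig:
    """Parameterization of the compositional window test.

    Parameters
    ----------
    window_length
        Number of residues per window (default 20).
    counted_residues
        The residue class whose joint fraction is thresholded
        (default ``{D, E, S, K}``).
    fraction_threshold
        Minimum fraction of window positions occupied by the counted class,
        held as an exact rational (default 3/4).  Accepts floats, decimal
        strings and percentage strings on construction.
    required_residues
        Minimum per-window counts of specific residues (default ``{"K": 1}``:
        at least one lysine).  Every required residue must belong to the
        counted class.
    """

    window_length: int = 20
    counted_residues: frozenset[str] = frozenset("DESK")
    fraction_threshold: Fraction = Fraction(3, 4)
    required_residues: Mapping[str, int] = field(
        default_factory=lambda: {"K": 1}
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counted_residues", frozenset(self.counted_residues)
        )
        object.__setattr__(
            self, "fraction_threshold", _as_fraction(self.fraction_threshold)
        )
        object.__setattr__(
            self, "required_residues", dict(self.required_residues)
        )
        if self.window_length < 1:
            raise ValueError(f"window_length must be >= 1, got {self.window_length}")
        if not (0 < self.fraction_threshold <= 1):
            raise ValueError(
                f"fraction_threshold must lie in (0, 1], got {self.fraction_threshold}"
            )
        for res, count in self.required_residues.items():
            if res not in self.counted_residues:
                raise ValueError(
                    f"required residue {res!r} is not in the counted class "
                    f"{sorted(self.counted_residues)}"
                )
            if count < 1:
                raise ValueError(
                    f"required count for {res!r} must be >= 1, got {count}"
                )

    @property
    def min_count(self) -> int:
        """Minimum number of counted-class residues per window."""
        return min_composition_count(self.fraction_threshold, self.window_length)

    def with_threshold(self, threshold: float | str | Fraction) -> "MotifConfig":
        """Return a copy with a different fraction threshold."""
        return MotifConfig(
            window_length=self.window_length,
            counted_residues=self.counted_residues,
            fraction_threshold=threshold,
            required_residues=self.required_residues,
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A normalized protein sequence: uppercase residues, no whitespace."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("protein identifier must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_raw(
        cls, identifier: str, raw: str, description: str = ""
    ) -> "ProteinSequence":
        """Normalize a raw sequence string.

        Uppercases, strips whitespace, removes one trailing stop symbol
        (``*``) with a warning, and rejects internal stops as malformed.
        Non-standard residue codes (X, B, Z, J, U, O) are retained but
        logged; they never match the counted class.
        """
        seq = "".join(raw.split()).upper()
        if seq.endswith("*"):
            logger.warning("%s: stripping trailing stop symbol", identifier)
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(
                f"{identifier}: internal stop symbol at position {seq.index('*') + 1}"
            )
        unusual = set(seq) - STANDARD_AA
        if unusual:
            unknown = unusual - AMBIGUOUS_AA
            if unknown:
                raise ValueError(
                    f"{identifier}: unrecognized residue code(s) {sorted(unknown)}"
                )
            logger.warning(
                "%s: non-standard residue(s) %s retained (never counted)",
                identifier,
                sorted(unusual),
            )
        return cls(identifier=identifier, residues=seq, description=description)


@dataclass(frozen=True)
class QualifyingWindow:
    """A window position passing the compositional test (1-based, inclusive)."""

    start: int
    end: int
    counted_count: int
    required_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_counts", dict(self.required_counts))
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid window span ({self.start}, {self.end})")


@dataclass(frozen=True)
class MotifRegion:
    """A maximal span covered by overlapping/abutting qualifying windows."""

    start: int
    end: int
    window_support: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region span ({self.start}, {self.end})")
        if self.window_support < 1:
            raise ValueError("window_support must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def min_composition_count(
    fraction_threshold: float | str | Fraction, window_length: int
) -> int:
    """Smallest integer count c with c >= fraction_threshold * window_length.

    Computed with exact rational arithmetic, so 75% of a 20-residue window is
    exactly 15 and no floating-point boundary case can shift the answer.

    >>> min_composition_count(0.75, 20)
    15
    """
    frac = _as_fraction(fraction_threshold)
    if not (0 < frac <= 1):
        raise ValueError(f"fraction_threshold must lie in (0, 1], got {frac}")
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    target = frac * window_length
    # ceil(n/d) without floats
    return -(-target.numerator // target.denominator)


def window_qualifies(window: str, config: MotifConfig) -> bool:
    """Test one window: counted-class content and required-residue minima.

    The window must have exactly ``config.window_length`` residues.
    """
    if len(window) != config.window_length:
        raise ValueError(
            f"window has {len(window)} residues, expected {config.window_length}"
        )
    counted = sum(1 for aa in window if aa in config.counted_residues)
    if counted < config.min_count:
        return False
    return all(
        window.count(res) >= minimum
        for res, minimum in config.required_residues.items()
    )


def scan_sequence(
    protein: ProteinSequence, config: MotifConfig
) -> list[QualifyingWindow]:
    """Slide the window along one protein and return every qualifying position.

    Counts are maintained incrementally (add the entering residue, drop the
    leaving one), which is outcome-identical to recounting each window from
    scratch.  Sequences shorter than the window yield an empty list.
    """
    seq = protein.residues
    w = config.window_length
    n = len(seq)
    if n < w:
        return []
    counted_set = config.counted_residues
    required = config.required_residues
    min_count = config.min_count

    counted = sum(1 for aa in seq[:w] if aa in counted_set)
    req_counts = {res: seq[:w].count(res) for res in required}

    hits: list[QualifyingWindow] = []
    for start0 in range(n - w + 1):
        if start0 > 0:
            leaving = seq[start0 - 1]
            entering = seq[start0 + w - 1]
            if leaving in counted_set:
                counted -= 1
            if entering in counted_set:
                counted += 1
            if leaving in req_counts:
                req_counts[leaving] -= 1
            if entering in req_counts:
                req_counts[entering] += 1
        if counted >= min_count and all(
            req_counts[res] >= minimum for res, minimum in required.items()
        ):
            hits.append(
                QualifyingWindow(
                    start=start0 + 1,
                    end=start0 + w,
                    counted_count=counted,
                    required_counts=dict(req_counts),
                )
            )
    return hits


def merge_windows(windows: Sequence[QualifyingWindow]) -> list[MotifRegion]:
    """Merge overlapping or abutting qualifying windows into maximal regions.

    Windows must be sorted by start (as returned by :func:`scan_sequence`).
    Two windows belong to the same region when the next one starts no later
    than one past the end of the running span.
    """
    starts = [win.start for win in windows]
    if starts != sorted(starts):
        raise ValueError("windows must be sorted by start position")
    regions: list[MotifRegion] = []
    cur_start = cur_end = support = 0
    for win in windows:
        if support and win.start <= cur_end + 1:
            cur_end = max(cur_end, win.end)
            support += 1
        else:
            if support:
                regions.append(MotifRegion(cur_start, cur_end, support))
            cur_start, cur_end, support = win.start, win.end, 1
    if support:
        regions.append(MotifRegion(cur_start, cur_end, support))
    return regions


def has_motif(protein: ProteinSequence, config: MotifConfig) -> bool:
    """True iff the protein carries at least one qualifying window.

    Short-circuits on the first hit.
    """
    seq = protein.residues
    w = config.window_length
    n = len(seq)
    if n < w:
        return False
    counted_set = config.counted_residues
    required = config.required_residues
    min_count = config.min_count
    counted = sum(1 for aa in seq[:w] if aa in counted_set)
    req_counts = {res: seq[:w].count(res) for res in required}
    for start0 in range(n - w + 1):
        if start0 > 0:
            leaving = seq[start0 - 1]
            entering = seq[start0 + w - 1]
            if leaving in counted_set:
                counted -= 1
            if entering in counted_set:
                counted += 1
            if leaving in req_counts:
                req_counts[leaving] -= 1
            if entering in req_counts:
                req_counts[entering] += 1
        if counted >= min_count and all(
            req_counts[res] >= minimum for res, minimum in required.items()
        ):
            return True
    return False
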