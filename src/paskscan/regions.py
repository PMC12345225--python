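"""Residue-range composition reports and in-silico substitution mutants.

These tools reproduce the two sequence-level analyses that accompany
compositional motif mapping: counting residues of a class inside a domain
or motif region (e.g. the 27 lysines of an S1 + basic domain pair), and
designing substitution mutants in which every residue of a source class
inside a range is replaced (e.g. all lysines to arginines, preserving
positive charge while removing polyP-binding lysines; serines to alanines;
acidic residues to their uncharged amides or to hydrophobics).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .motif import STANDARD_AA, ProteinSequence

__all__ = [
    "ResidueRange",
    "CompositionReport",
    "SubstitutionScheme",
    "VariantSequence",
    "BUILTIN_SCHEMES",
    "composition",
    "count_residue",
    "apply_scheme",
    "write_composition_table",
    "write_variant_fasta",
]


@dataclass(frozen=True)
class ResidueRange:
    """An inclusive 1-based residue range, e.g. residues 644-730."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue range ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def full(cls, protein: ProteinSequence) -> "ResidueRange":
        return cls(1, len(protein))

    def check_within(self, protein: ProteinSequence) -> None:
        if self.end > len(protein):
            raise ValueError(
                f"range {self.start}-{self.end} exceeds {protein.identifier} "
                f"length {len(protein)}"
            )

    def slice(self, protein: ProteinSequence) -> str:
        self.check_within(protein)
        return protein.residues[self.start - 1 : self.end]


@dataclass(frozen=True)
class CompositionReport:
    """Exact per-letter counts over a residue range."""

    range: ResidueRange
    counts: Mapping[str, int]
    class_count: int
    length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if sum(self.counts.values()) != self.length:
            raise ValueError("counts do not sum to range length")


@dataclass(frozen=True)
class SubstitutionScheme:
    """A residue replacement map applied uniformly over a range.

    The schemes used for polyP-binding mutagenesis swap whole residue
    classes: K-R keeps positive charge, S-A removes hydroxyls, D-N/E-Q
    neutralizes acidic charge while preserving geometry, D-A/E-L removes
    the acidic side chains outright.
    """

    name: str
    replacement_map: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "replacement_map", dict(self.replacement_map))
        for src, dst in self.replacement_map.items():
            if src not in STANDARD_AA or dst not in STANDARD_AA:
                raise ValueError(f"non-standard residues in scheme: {src}->{dst}")


BUILTIN_SCHEMES: dict[str, SubstitutionScheme] = {
    s.name: s
    for s in (
        SubstitutionScheme("K-R", {"K": "R"}),
        SubstitutionScheme("S-A", {"S": "A"}),
        SubstitutionScheme("D-N/E-Q", {"D": "N", "E": "Q"}),
        SubstitutionScheme("D-A/E-L", {"D": "A", "E": "L"}),
    )
}


@dataclass(frozen=True)
class VariantSequence:
    """A designed mutant: parent sequence with a scheme applied over a range."""

    parent_id: str
    scheme_name: str
    range: ResidueRange
    residues: str
    n_substitutions: int

    @property
    def identifier(self) -> str:
        return (
            f"{self.parent_id}|{self.scheme_name}"
            f"|{self.range.start}-{self.range.end}"
        )


def composition(
    protein: ProteinSequence,
    residue_range: ResidueRange | None = None,
    residue_class: Iterable[str] = (),
) -> CompositionReport:
    """Count every residue letter in the (inclusive) range; ``class_count``
    sums the requested class."""
    rng = residue_range or ResidueRange.full(protein)
    segment = rng.slice(protein)
    counts = Counter(segment)
    cls = set(residue_class)
    return CompositionReport(
        range=rng,
        counts=dict(counts),
        class_count=sum(counts[aa] for aa in cls),
        length=len(segment),
    )


def count_residue(
    protein: ProteinSequence,
    residue_range: ResidueRange | None = None,
    residue: str = "K",
) -> int:
    """Count one residue letter in a range (projection of composition)."""
    return composition(protein, residue_range, {residue}).class_count


def apply_scheme(
    protein: ProteinSequence,
    residue_range: ResidueRange | None,
    scheme: SubstitutionScheme,
) -> VariantSequence:
    """Replace every in-range residue that is a scheme source by its target.

    Positions outside the range, and in-range residues that are not scheme
    sources, are untouched; the sequence length never changes.
    """
    rng = residue_range or ResidueRange.full(protein)
    rng.check_within(protein)
    table = str.maketrans(scheme.replacement_map)
    before = protein.residues[rng.start - 1 : rng.end]
    after = before.translate(table)
    n_sub = sum(1 for a, b in zip(before, after) if a != b)
    mutated = protein.residues[: rng.start - 1] + after + protein.residues[rng.end :]
    return VariantSequence(
        parent_id=protein.identifier,
        scheme_name=scheme.name,
        range=rng,
        residues=mutated,
        n_substitutions=n_sub,
    )


def write_composition_table(
    reports: Mapping[str, CompositionReport], destination: "str | IO[str]"
) -> None:
    """TSV with one row per (protein, residue letter) count."""
    from pathlib import Path

    lines = ["\t".join(("id", "start", "end", "residue", "count"))]
    for pid, report in reports.items():
        for aa in sorted(report.counts):
            lines.append(
                "\t".join(
                    (pid, str(report.range.start), str(report.range.end), aa,
                     str(report.counts[aa]))
                )
            )
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, newline="\n")
    else:
        destination.write(text)


def write_variant_fasta(
    variants: Sequence[VariantSequence], destination: "str | IO[str]", width: int = 60
) -> None:
    """FASTA output of mutant sequences; the scheme name and range are
    appended to the header."""
    from pathlib import Path

    chunks: list[str] = []
    for v in variants:
        chunks.append(f">{v.identifier} n_substitutions={v.n_substitutions}")
        for i in range(0, len(v.residues), width):
            chunks.append(v.residues[i : i + width])
    text = "\n".join(chunks) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, newline="\n")
    else:
        destination.write(text)
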