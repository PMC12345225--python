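"""Synthetic proteomes with planted compositional motifs, and the exact
null probability that a random window qualifies.

The generator draws i.i.d. residues from a configurable background
distribution and overwrites chosen windows with a planted composition that
passes the motif test by construction, returning a ground-truth table so
scanner recall and false-positive behaviour can be measured exactly.  The
companion null model computes, by dynamic programming over joint residue
counts, the exact probability that a single i.i.d. window passes the
compositional test — no Monte Carlo, no approximation beyond float
arithmetic — which quantifies how rare a motif definition is under a given
background composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif import STANDARD_AA, MotifConfig, ProteinSequence, window_qualifies
from .proteome import ProteomeRecordSet

__all__ = [
    "BackgroundModel",
    "PlantSpec",
    "PlantRecord",
    "generate_proteome",
    "exact_window_rate",
    "write_plant_table",
]

#: Residues outside the default D/E/S/K counted class, for unambiguous flanks.
NON_PASK_LETTERS = "ALGVPT"


@dataclass(frozen=True)
class BackgroundModel:
    """An i.i.d. residue background: per-letter probabilities and a length."""

    probabilities: Mapping[str, float]
    length: int = 200

    def __post_init__(self) -> None:
        probs = {aa: float(p) for aa, p in self.probabilities.items() if p != 0}
        object.__setattr__(self, "probabilities", probs)
        bad = set(probs) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard letters in background: {sorted(bad)}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("background probabilities must be non-negative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"background probabilities sum to {total}, not 1")
        if self.length < 0:
            raise ValueError("length must be non-negative")

    @classmethod
    def uniform(cls, letters: Iterable[str] = STANDARD_AA, length: int = 200) -> "BackgroundModel":
        letters = sorted(set(letters))
        return cls({aa: 1.0 / len(letters) for aa in letters}, length=length)

    @classmethod
    def motif_free(cls, length: int = 200) -> "BackgroundModel":
        """Uniform background over residues outside the D/E/S/K class, so
        no window can qualify by chance under the default motif test."""
        return cls.uniform(NON_PASK_LETTERS, length=length)

    def letters_and_probs(self) -> tuple[list[str], np.ndarray]:
        letters = sorted(self.probabilities)
        p = np.array([self.probabilities[aa] for aa in letters])
        return letters, p / p.sum()


@dataclass(frozen=True)
class PlantSpec:
    """A window to plant: 1-based start position plus an exact residue
    composition (counts per letter summing to the window length)."""

    position: int
    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition", dict(self.composition))
        if self.position < 1:
            raise ValueError("plant position must be >= 1")
        if any(c < 0 for c in self.composition.values()):
            raise ValueError("composition counts must be non-negative")

    def window_length(self) -> int:
        return sum(self.composition.values())

    def validate(self, config: MotifConfig) -> None:
        """The planted composition must itself pass the window test."""
        if self.window_length() != config.window_length:
            raise ValueError(
                f"plant composition sums to {self.window_length()}, "
                f"config window is {config.window_length}"
            )
        probe = "".join(aa * c for aa, c in sorted(self.composition.items()))
        if not window_qualifies(probe, config):
            raise ValueError(
                f"planted composition {self.composition} does not satisfy "
                "the motif configuration"
            )


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted window."""

    protein_id: str
    start: int
    end: int


def generate_proteome(
    n_proteins: int,
    background: BackgroundModel,
    plants: Sequence[tuple[int, PlantSpec]] = (),
    seed: int = 0,
    config: MotifConfig | None = None,
    label: str = "synthetic",
) -> tuple[ProteomeRecordSet, list[PlantRecord]]:
    """Generate an i.i.d. proteome with planted qualifying windows.

    ``plants`` pairs a 0-based protein index with a :class:`PlantSpec`;
    the planted residues are a seeded random permutation of the specified
    composition, overwriting the background at that position.  Plants within
    one protein must not overlap.  The same seed always yields the same
    record set, byte for byte.

    Returns the record set and the ground-truth table of planted windows.
    """
    config = config or MotifConfig()
    rng = np.random.default_rng(seed)
    letters, probs = background.letters_and_probs()
    letter_arr = np.array(list(letters))

    by_protein: dict[int, list[PlantSpec]] = {}
    for idx, spec in plants:
        if not (0 <= idx < n_proteins):
            raise ValueError(f"plant protein index {idx} out of range")
        spec.validate(config)
        by_protein.setdefault(idx, []).append(spec)
    for idx, specs in by_protein.items():
        specs.sort(key=lambda s: s.position)
        for a, b in zip(specs, specs[1:]):
            if b.position <= a.position + a.window_length() - 1:
                raise ValueError(
                    f"overlapping plants in protein {idx}: "
                    f"{a.position} and {b.position}"
                )

    records: list[ProteinSequence] = []
    truth: list[PlantRecord] = []
    for i in range(n_proteins):
        seq = letter_arr[rng.choice(len(letters), size=background.length, p=probs)]
        pid = f"{label}_{i + 1:04d}"
        for spec in by_protein.get(i, []):
            end = spec.position + spec.window_length() - 1
            if end > background.length:
                raise ValueError(
                    f"plant at {spec.position} exceeds sequence length "
                    f"{background.length}"
                )
            window = np.array(
                [aa for aa, c in sorted(spec.composition.items()) for _ in range(c)]
            )
            rng.shuffle(window)
            seq[spec.position - 1 : end] = window
            truth.append(PlantRecord(pid, spec.position, end))
        records.append(ProteinSequence(identifier=pid, residues="".join(seq)))
    return ProteomeRecordSet(source_label=label, records=records), truth


def exact_window_rate(background: BackgroundModel, config: MotifConfig) -> float:
    """Exact probability that one i.i.d. window passes the compositional test.

    Dynamic programming over the joint distribution of (number of
    counted-class residues, count of each required residue) across the
    window positions.  Required-residue counts are capped at their minima,
    so the state space is tiny and the computation is exact up to float
    rounding.
    """
    letters, probs = background.letters_and_probs()
    pmap = dict(zip(letters, probs))
    required = sorted(config.required_residues)
    minima = [config.required_residues[r] for r in required]

    # per-letter category: (is_counted, which required residue or None)
    p_req = [pmap.get(r, 0.0) for r in required]
    p_counted_other = sum(
        p for aa, p in pmap.items()
        if aa in config.counted_residues and aa not in required
    )
    p_non = sum(
        p for aa, p in pmap.items() if aa not in config.counted_residues
    )

    # state: (counted_count, capped required counts...)
    start = (0,) + (0,) * len(required)
    dp: dict[tuple[int, ...], float] = {start: 1.0}
    for _ in range(config.window_length):
        nxt: dict[tuple[int, ...], float] = {}

        def add(state: tuple[int, ...], p: float) -> None:
            if p:
                nxt[state] = nxt.get(state, 0.0) + p

        for state, prob in dp.items():
            c, reqs = state[0], list(state[1:])
            add((c,) + tuple(reqs), prob * p_non)
            add((c + 1,) + tuple(reqs), prob * p_counted_other)
            for j, pr in enumerate(p_req):
                bumped = reqs.copy()
                bumped[j] = min(bumped[j] + 1, minima[j])
                add((c + 1,) + tuple(bumped), prob * pr)
        dp = nxt

    min_count = config.min_count
    return float(
        sum(
            prob
            for state, prob in dp.items()
            if state[0] >= min_count
            and all(k >= m for k, m in zip(state[1:], minima))
        )
    )


def write_plant_table(truth: Sequence[PlantRecord], destination) -> None:
    """TSV ground-truth table: protein_id, start, end."""
    from pathlib import Path

    lines = ["\t".join(("protein_id", "start", "end"))]
    for rec in truth:
        lines.append("\t".join((rec.protein_id, str(rec.start), str(rec.end))))
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, newline="\n")
    else:
        destination.write(text)
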