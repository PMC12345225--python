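"""Consensus of per-residue disorder scores from multiple predictors.

Disorder predictors disagree; averaging several (here: any number of
per-residue score tracks in [0, 1], typically three, e.g. NetSurfP-3.0,
Metapredict and IUPred3 exports) reduces algorithm-specific bias.  The
consensus profile is the per-residue arithmetic mean with a standard-error
envelope (sample standard deviation, n-1 denominator, divided by sqrt(n)),
and a binary disorder call at mean strictly greater than 0.5.

The predictors themselves are not wrapped or executed; only their exported
two-column tables (1-based position, score) are consumed, keeping this
stage deterministic and offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictorTrack",
    "ConsensusProfile",
    "read_score_table",
    "consensus",
    "write_consensus_table",
    "plot_consensus",
]

#: Disorder call threshold: a residue is called disordered at mean > 0.5.
DISORDER_CALL_THRESHOLD = 0.5


@dataclass(frozen=True)
class PredictorTrack:
    """One predictor's per-residue disorder scores (index i = residue i+1)."""

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"{self.name}: scores must be a non-empty 1-D array")
        if np.any(arr < 0) or np.any(arr > 1):
            bad = int(np.argmax((arr < 0) | (arr > 1)))
            raise ValueError(
                f"{self.name}: score {arr[bad]} at position {bad + 1} "
                "outside [0, 1]"
            )

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-residue mean, standard error, and binary disorder call."""

    mean: np.ndarray
    se: np.ndarray
    call: np.ndarray
    n_tracks: int

    def __len__(self) -> int:
        return self.mean.size


def read_score_table(source: str | Path | IO[str], name: str | None = None) -> PredictorTrack:
    """Read a two-column (position, score) table into a track.

    Positions must be exactly 1..L with no gaps or duplicates; scores must
    lie in [0, 1] (out-of-range values are errors, never clamped).  A header
    row is tolerated.  Column separators may be tabs, commas or whitespace.
    """
    if isinstance(source, (str, Path)):
        name = name or Path(source).stem
        text = Path(source).read_text()
    else:
        name = name or getattr(source, "name", "track")
        text = source.read()

    rows: list[tuple[int, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ValueError(f"{name}: row {lineno} has fewer than two columns")
        try:
            pos = int(parts[0])
            score = float(parts[1])
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ValueError(f"{name}: unparseable row {lineno}: {line!r}")
        if not (0.0 <= score <= 1.0):
            raise ValueError(
                f"{name}: score {score} at row {lineno} outside [0, 1]"
            )
        rows.append((pos, score))
    if not rows:
        raise ValueError(f"{name}: no score rows found")

    positions = [p for p, _ in rows]
    expected = list(range(1, len(rows) + 1))
    if positions != expected:
        seen = set()
        for p in positions:
            if p in seen:
                raise ValueError(f"{name}: duplicate position {p}")
            seen.add(p)
        missing = sorted(set(expected) - seen)
        if missing:
            raise ValueError(f"{name}: gap at position {missing[0]}")
        raise ValueError(f"{name}: positions not contiguous from 1")
    return PredictorTrack(name=name, scores=np.array([s for _, s in rows]))


def consensus(tracks: Sequence[PredictorTrack]) -> ConsensusProfile:
    """Average tracks per residue with a standard-error envelope.

    SE uses the sample standard deviation (n-1 denominator) over sqrt(n);
    a single track yields SE = 0 everywhere.  Tracks of unequal length are
    an error — profiles are never silently truncated.
    """
    if not tracks:
        raise ValueError("at least one predictor track is required")
    lengths = {len(t) for t in tracks}
    if len(lengths) > 1:
        detail = ", ".join(f"{t.name}={len(t)}" for t in tracks)
        raise ValueError(f"track length mismatch: {detail}")
    stacked = np.vstack([t.scores for t in tracks])
    n = stacked.shape[0]
    mean = stacked.mean(axis=0)
    if n > 1:
        se = stacked.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.zeros_like(mean)
    return ConsensusProfile(
        mean=mean, se=se, call=mean > DISORDER_CALL_THRESHOLD, n_tracks=n
    )


def write_consensus_table(
    profile: ConsensusProfile, destination: str | Path | IO[str]
) -> None:
    """TSV output: position, mean, se, call."""
    df = pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "mean": profile.mean,
            "se": profile.se,
            "call": profile.call.astype(int),
        }
    )
    text = df.to_csv(sep="\t", index=False, float_format="%.6g")
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, newline="\n")
    else:
        destination.write(text)


def plot_consensus(
    profile: ConsensusProfile,
    destination: str | Path,
    title: str = "Disorder consensus",
) -> None:
    """Render the mean profile with its SE envelope and the call threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, len(profile) + 1)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(
        x, profile.mean - profile.se, profile.mean + profile.se,
        alpha=0.3, linewidth=0, label="±SE",
    )
    ax.plot(x, profile.mean, lw=1.2, label=f"mean of {profile.n_tracks} predictors")
    ax.axhline(DISORDER_CALL_THRESHOLD, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("Residue")
    ax.set_ylabel("Disorder propensity (A.U.)")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(destination, dpi=150)
    plt.close(fig)
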