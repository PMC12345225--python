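"""Proteome-level scanning: FASTA ingest, per-proteome summaries, threshold
sweeps, and tabular/GFF3 output.

The statistic of interest at this level is the fraction of proteins in a
proteome carrying one or more PASK motifs, normalized by the number of
entries in the supplied FASTA (the cross-species comparison divides by the
number of reviewed UniProt entries; which FASTA — reviewed or unreviewed —
is the caller's choice and is recorded in ``source_label``).
"""

from __future__ import annotations

import io
import logging
import re
import urllib.request
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO

from .motif import (
    MotifConfig,
    MotifRegion,
    ProteinSequence,
    merge_windows,
    scan_sequence,
)

__all__ = [
    "ProteomeRecordSet",
    "ProteomeSummary",
    "ThresholdSweepResult",
    "read_fasta",
    "fetch_uniprot_proteome",
    "scan_proteome",
    "summarize",
    "sweep_thresholds",
    "write_motif_table",
    "read_motif_table",
    "write_motif_gff",
    "write_summary_table",
]

logger = logging.getLogger(__name__)

# UniProt FASTA header: db|ACCESSION|ENTRY_NAME Description OS=... OX=...
_UNIPROT_ID = re.compile(r"^(sp|tr)\|(?P<accession>[^|]+)\|(?P<entry_name>\S+)$")
_OS_FIELD = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")
_OX_FIELD = re.compile(r"\bOX=(\d+)")


@dataclass
class ProteomeRecordSet:
    """An ordered set of protein sequences read from one FASTA source."""

    source_label: str
    records: list[ProteinSequence]
    header_metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, identifier: str) -> ProteinSequence:
        for rec in self.records:
            if rec.identifier == identifier:
                return rec
        raise KeyError(identifier)


@dataclass(frozen=True)
class ProteomeSummary:
    """Per-proteome motif statistics.

    ``normalized_fraction`` is the number of motif-positive proteins divided
    by the total number of entries in the file.
    """

    source_label: str
    n_entries: int
    n_with_motif: int
    normalized_fraction: float
    config_echo: MotifConfig

    def __post_init__(self) -> None:
        if not (0 <= self.n_with_motif <= self.n_entries):
            raise ValueError(
                f"inconsistent counts: {self.n_with_motif} positive of "
                f"{self.n_entries} entries"
            )


@dataclass
class ThresholdSweepResult:
    """Scans of one proteome at several composition thresholds.

    ``per_threshold`` maps each threshold to the set of motif-positive
    protein identifiers and the corresponding summary.  Positive sets are
    nested: lowering the threshold can only add proteins.
    """

    thresholds: list[Fraction]
    per_threshold: dict[Fraction, tuple[set[str], ProteomeSummary]]

    def positives(self, threshold) -> set[str]:
        from .motif import _as_fraction

        return self.per_threshold[_as_fraction(threshold)][0]


def _parse_header_metadata(identifier: str, description: str) -> dict[str, str] | None:
    m = _UNIPROT_ID.match(identifier)
    if not m:
        return None
    meta = {
        "accession": m.group("accession"),
        "entry_name": m.group("entry_name"),
    }
    os_m = _OS_FIELD.search(description)
    if os_m:
        meta["organism_name"] = os_m.group(1).strip()
    ox_m = _OX_FIELD.search(description)
    if ox_m:
        meta["taxon_id"] = ox_m.group(1)
    return meta


def read_fasta(source: str | Path | IO[str], label: str | None = None) -> ProteomeRecordSet:
    """Read a FASTA file (UniProt header dialect tolerated) into a record set.

    The record identifier is the first whitespace-delimited token of the
    header; the remainder is kept as the description.  Duplicate identifiers
    are retained but disambiguated with a ``.2``, ``.3``, ... suffix and a
    warning.  An empty file or a record with an empty sequence is a format
    error.
    """
    if isinstance(source, (str, Path)):
        label = label or str(source)
        handle: IO[str] = open(source)
        close = True
    else:
        label = label or getattr(source, "name", "<stream>")
        handle = source
        close = False
    try:
        records: list[ProteinSequence] = []
        metadata: dict[str, dict[str, str]] = {}
        seen: dict[str, int] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if len(rec.seq) == 0:
                raise ValueError(f"record {rec.id!r} has an empty sequence")
            identifier = rec.id
            description = rec.description[len(rec.id):].strip()
            if identifier in seen:
                seen[identifier] += 1
                new_id = f"{identifier}.{seen[identifier]}"
                logger.warning(
                    "duplicate identifier %r renamed to %r", identifier, new_id
                )
                identifier = new_id
            else:
                seen[identifier] = 1
            protein = ProteinSequence.from_raw(identifier, str(rec.seq), description)
            records.append(protein)
            meta = _parse_header_metadata(rec.id, description)
            if meta:
                metadata[identifier] = meta
        if not records:
            raise ValueError(f"no FASTA records found in {label}")
        return ProteomeRecordSet(
            source_label=label, records=records, header_metadata=metadata
        )
    finally:
        if close:
            handle.close()


#: UniProt REST endpoint for reference-proteome FASTA downloads.
UNIPROT_STREAM_URL = (
    "https://rest.uniprot.org/uniprotkb/stream?format=fasta&query="
    "proteome:{proteome_id}+AND+reviewed:{reviewed}"
)


def fetch_uniprot_proteome(
    proteome_id: str, destination: str | Path, reviewed: bool = True
) -> Path:
    """Download a UniProt proteome FASTA (network convenience; every
    computation in this package accepts a local file instead)."""
    url = UNIPROT_STREAM_URL.format(
        proteome_id=proteome_id, reviewed=str(reviewed).lower()
    )
    destination = Path(destination)
    logger.info("fetching %s -> %s", url, destination)
    with urllib.request.urlopen(url, timeout=120) as resp:
        destination.write_bytes(resp.read())
    return destination


def scan_proteome(
    proteome: ProteomeRecordSet, config: MotifConfig
) -> dict[str, list[MotifRegion]]:
    """Scan every protein; motif-free proteins map to an empty list so that
    "scanned, none found" is distinguishable from "absent"."""
    return {
        rec.identifier: merge_windows(scan_sequence(rec, config))
        for rec in proteome.records
    }


def summarize(
    proteome: ProteomeRecordSet,
    scan_result: Mapping[str, Sequence[MotifRegion]],
    config: MotifConfig,
) -> ProteomeSummary:
    """Protein-level summary: each protein counts at most once however many
    regions it carries."""
    ids = {rec.identifier for rec in proteome.records}
    if set(scan_result) != ids:
        missing = ids - set(scan_result)
        extra = set(scan_result) - ids
        raise ValueError(
            f"scan result does not match record set "
            f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
        )
    n_with = sum(1 for regions in scan_result.values() if regions)
    n = len(proteome.records)
    return ProteomeSummary(
        source_label=proteome.source_label,
        n_entries=n,
        n_with_motif=n_with,
        normalized_fraction=n_with / n,
        config_echo=config,
    )


def sweep_thresholds(
    proteome: ProteomeRecordSet,
    base_config: MotifConfig,
    thresholds: Iterable[float | str | Fraction],
) -> ThresholdSweepResult:
    """Scan the proteome once per threshold, holding every other parameter
    fixed, and verify that positive sets nest (lower threshold is a superset).

    A nesting violation raises: it can only arise from a scanner defect.
    """
    from .motif import _as_fraction

    fracs = [_as_fraction(t) for t in thresholds]
    if not fracs:
        raise ValueError("thresholds must be non-empty")
    per: dict[Fraction, tuple[set[str], ProteomeSummary]] = {}
    for frac in fracs:
        cfg = base_config.with_threshold(frac)
        result = scan_proteome(proteome, cfg)
        positives = {pid for pid, regions in result.items() if regions}
        per[frac] = (positives, summarize(proteome, result, cfg))
    ordered = sorted(per)
    for lo, hi in zip(ordered, ordered[1:]):
        if not per[hi][0] <= per[lo][0]:
            raise RuntimeError(
                f"threshold nesting violated: positives at {hi} not a subset "
                f"of positives at {lo}"
            )
    return ThresholdSweepResult(thresholds=fracs, per_threshold=per)


_TABLE_COLUMNS = (
    "protein_id",
    "start",
    "end",
    "length",
    "window_support",
    "threshold",
    "window_length",
)


def write_motif_table(
    scan_result: Mapping[str, Sequence[MotifRegion]],
    destination: str | Path | IO[str],
    config: MotifConfig,
) -> None:
    """Write merged motif regions as a TSV table (byte-stable output)."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for pid in scan_result:
        for region in scan_result[pid]:
            lines.append(
                "\t".join(
                    (
                        pid,
                        str(region.start),
                        str(region.end),
                        str(region.length),
                        str(region.window_support),
                        str(config.fraction_threshold),
                        str(config.window_length),
                    )
                )
            )
    _write_text(destination, "\n".join(lines) + "\n")


def read_motif_table(source: str | Path | IO[str]) -> dict[str, list[MotifRegion]]:
    """Parse a motif TSV back into per-protein region lists (round-trip of
    :func:`write_motif_table`; proteins without regions are absent)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    if tuple(header) != _TABLE_COLUMNS:
        raise ValueError(f"unexpected motif-table header: {header}")
    out: dict[str, list[MotifRegion]] = {}
    for line in lines[1:]:
        pid, start, end, _length, support, _thr, _w = line.split("\t")
        out.setdefault(pid, []).append(
            MotifRegion(int(start), int(end), int(support))
        )
    return out


def write_motif_gff(
    scan_result: Mapping[str, Sequence[MotifRegion]],
    destination: str | Path | IO[str],
    config: MotifConfig,
) -> None:
    """Write motif regions as GFF3 against protein coordinate space.

    The protein identifier is the seqid; features are typed
    ``compositional_bias`` with 1-based inclusive coordinates and a ``Note``
    attribute carrying the counted residue class.
    """
    note = "".join(sorted(config.counted_residues))
    lines = ["##gff-version 3"]
    for pid in scan_result:
        for i, region in enumerate(scan_result[pid], start=1):
            attrs = (
                f"ID={pid}:pask:{i};Note=composition class {note} "
                f">= {config.fraction_threshold} over {config.window_length}aa windows"
            )
            lines.append(
                "\t".join(
                    (
                        pid,
                        "paskscan",
                        "compositional_bias",
                        str(region.start),
                        str(region.end),
                        ".",
                        ".",
                        ".",
                        attrs,
                    )
                )
            )
    _write_text(destination, "\n".join(lines) + "\n")


def write_summary_table(
    summaries: Sequence[ProteomeSummary], destination: str | Path | IO[str]
) -> None:
    """Write one TSV row per proteome summary."""
    lines = ["\t".join(("source", "n_entries", "n_with_motif", "fraction", "threshold"))]
    for s in summaries:
        lines.append(
            "\t".join(
                (
                    s.source_label,
                    str(s.n_entries),
                    str(s.n_with_motif),
                    f"{s.normalized_fraction:.6g}",
                    str(s.config_echo.fraction_threshold),
                )
            )
        )
    _write_text(destination, "\n".join(lines) + "\n")


def _write_text(destination: str | Path | IO[str], text: str) -> None:
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, newline="\n")
    else:
        destination.write(text)
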