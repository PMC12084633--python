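"""Alternative-splicing event model and table I/O.

An event is a genomic locus where competing splice junctions produce distinct
mature transcripts.  Six categories are supported, following the standard
junction-based taxonomy:

* ``cassette`` -- an exon included or skipped as a unit,
* ``A5S`` / ``A3S`` -- alternative 5' (donor) / 3' (acceptor) splice-site
  choice between exactly two competing sites,
* ``IR`` -- intron retention,
* ``MXE`` -- mutually exclusive exons,
* ``composite`` -- several intertwined choices at one locus.

Coordinates are 0-based half-open genomic intervals (BED convention)
throughout the library; the GFF3 writer converts to 1-based inclusive on
output.  Junctions are stored sorted by genomic start so that "the
genomically-first alternative" is always junction index 0 for binary-choice
events.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import CountTableError, EventDefinitionError, UnknownEventTypeError

EVENT_TYPES = ("cassette", "A5S", "A3S", "IR", "MXE", "composite")

#: stable integer code per type, used for vectorized grouping
EVENT_TYPE_CODES = {t: i for i, t in enumerate(EVENT_TYPES)}


@dataclass(frozen=True)
class SplicingEvent:
    """One alternative-splicing locus.

    Parameters
    ----------
    event_id:
        Unique identifier.
    gene_id:
        Gene the locus belongs to.
    chrom, strand:
        Genomic location; strand is ``+`` or ``-``.
    event_type:
        One of :data:`EVENT_TYPES`.
    junctions:
        Ordered ``(donor_coord, acceptor_coord)`` pairs, 0-based half-open,
        sorted by genomic start.  For intron retention the two "boundary"
        pseudo-junctions represent reads spanning the exon--intron borders.
    inclusion_junction_index:
        Indices of the junctions that define the inclusion choice
        (cassette/IR) or the genomically-first choice (A5S/A3S/MXE).
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    event_type: str
    junctions: tuple[tuple[int, int], ...]
    inclusion_junction_index: tuple[int, ...] = field(default=(0,))

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise UnknownEventTypeError(
                f"{self.event_id}: unknown event type {self.event_type!r}"
            )
        if self.strand not in ("+", "-"):
            raise EventDefinitionError(
                f"{self.event_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if len(self.junctions) < 2:
            raise EventDefinitionError(
                f"{self.event_id}: events need at least two junctions"
            )
        for start, end in self.junctions:
            if start < 0 or end < 0:
                raise EventDefinitionError(
                    f"{self.event_id}: negative junction coordinate"
                )
            if start == end:
                raise EventDefinitionError(
                    f"{self.event_id}: donor and acceptor coordinates coincide"
                )
        if list(self.junctions) != sorted(self.junctions):
            raise EventDefinitionError(
                f"{self.event_id}: junctions must be sorted by genomic start"
            )
        if self.event_type in ("A5S", "A3S"):
            # more than two alternative coordinates are rejected
            if len(self.junctions) != 2:
                raise EventDefinitionError(
                    f"{self.event_id}: {self.event_type} events must have exactly "
                    f"2 alternative junctions, got {len(self.junctions)}"
                )
            (s1, e1), (s2, e2) = self.junctions
            if self.event_type == "A3S" and s1 != s2:
                raise EventDefinitionError(
                    f"{self.event_id}: A3S junctions must share the donor coordinate"
                )
            if self.event_type == "A5S" and e1 != e2:
                raise EventDefinitionError(
                    f"{self.event_id}: A5S junctions must share the acceptor coordinate"
                )
        inc = self.inclusion_junction_index
        if len(inc) == 0 or len(set(inc)) != len(inc):
            raise EventDefinitionError(
                f"{self.event_id}: inclusion junction indices empty or duplicated"
            )
        if any(i < 0 or i >= len(self.junctions) for i in inc):
            raise EventDefinitionError(
                f"{self.event_id}: inclusion junction index out of range"
            )
        if len(inc) >= len(self.junctions):
            raise EventDefinitionError(
                f"{self.event_id}: at least one junction must be an exclusion junction"
            )

    @property
    def exclusion_junction_index(self) -> tuple[int, ...]:
        inc = set(self.inclusion_junction_index)
        return tuple(i for i in range(len(self.junctions)) if i not in inc)


def events_to_frame(events: Iterable[SplicingEvent]) -> pd.DataFrame:
    """Flatten events into a metadata frame (one row per event)."""
    rows = [
        {
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "chrom": e.chrom,
            "strand": e.strand,
            "event_type": e.event_type,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "chrom", "strand", "event_type"])


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "event_id",
    "gene_id",
    "chrom",
    "strand",
    "event_type",
    "junctions",
    "inclusion_junctions",
]


def write_event_table(events: Sequence[SplicingEvent], path: str | Path) -> None:
    """Write events as TSV; junctions serialized as ``start-end;start-end``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [
                    e.event_id,
                    e.gene_id,
                    e.chrom,
                    e.strand,
                    e.event_type,
                    ";".join(f"{s}-{t}" for s, t in e.junctions),
                    ",".join(str(i) for i in e.inclusion_junction_index),
                ]
            )


def read_event_table(path: str | Path) -> list[SplicingEvent]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(_EVENT_COLUMNS) - set(reader.fieldnames):
            raise EventDefinitionError(f"{path}: missing event table columns")
        events = []
        for row in reader:
            junctions = tuple(
                tuple(int(x) for x in pair.split("-"))
                for pair in row["junctions"].split(";")
            )
            events.append(
                SplicingEvent(
                    event_id=row["event_id"],
                    gene_id=row["gene_id"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    event_type=row["event_type"],
                    junctions=junctions,  # type: ignore[arg-type]
                    inclusion_junction_index=tuple(
                        int(i) for i in row["inclusion_junctions"].split(",")
                    ),
                )
            )
    return events


def write_gff3(events: Sequence[SplicingEvent], path: str | Path) -> None:
    """Export one GFF3 line per junction (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in events:
            for j, (start, end) in enumerate(e.junctions):
                role = "inclusion" if j in e.inclusion_junction_index else "exclusion"
                attrs = (
                    f"ID={e.event_id}.j{j};Parent={e.gene_id};"
                    f"event_type={e.event_type};role={role}"
                )
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            "neurosplice",
                            "splice_junction",
                            str(start + 1),
                            str(end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


COUNT_COLUMNS = ["event_id", "cell_type", "replicate", "junction_index", "count"]


def write_junction_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format junction-count table."""
    counts.loc[:, COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "cell_type": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise CountTableError(f"{path}: missing columns {sorted(missing)}")
    return df
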