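"""Coding consequences of retained introns and splice-site choices.

A retained intron (or the sequence between two alternative splice sites)
inserts nucleotides into the mature transcript.  The classifier assigns
exactly one of three mutually exclusive categories, in order of
precedence:

* ``frameshift`` -- inserted length is not a multiple of 3,
* ``stop`` -- frame is preserved but the phase-adjusted reading of the
  insertion contains at least one stop codon (TAA/TAG/TGA), including the
  codon straddling the upstream exon boundary (which needs up to two
  flanking exonic bases when the insertion does not start on a codon
  boundary),
* ``neither`` -- frame preserved, no stop introduced.

Only the inserted sequence itself is scanned; downstream read-through
after a frameshift is not evaluated.  Both boolean flags are retained so
alternative tabulations stay possible.

Splice-site spacing for binary alternative donor/acceptor choices is the
absolute coordinate difference; a spacing divisible by 3 is
frame-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import AnalysisError, EventDefinitionError, SequenceError
from .events import SplicingEvent

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class ConsequenceCall:
    event_id: str | None
    frame_shift: bool
    in_frame_stop: bool
    category: str
    inserted_length: int
    phase: int


@dataclass(frozen=True)
class SpliceSiteSpacing:
    event_id: str
    distance_nt: int
    frame_preserving: bool


def classify_inserted_sequence(
    seq: str,
    phase: int,
    upstream_flank: str = "",
    event_id: str | None = None,
) -> ConsequenceCall:
    """Classify one inserted sequence.

    ``phase`` is the reading-frame offset of the first inserted base
    (0 = insertion starts a codon); for phase 1/2 the last 1/2 bases of
    ``upstream_flank`` complete the straddling codon.
    """
    seq = seq.upper()
    if not seq:
        raise SequenceError("inserted sequence is empty")
    if set(seq) - _VALID:
        raise SequenceError(f"non-ACGT character in sequence {seq!r}")
    if phase not in (0, 1, 2):
        raise SequenceError(f"phase must be 0, 1 or 2, got {phase!r}")
    flank_needed = phase
    flank = upstream_flank.upper()
    if len(flank) < flank_needed:
        raise SequenceError(
            f"phase {phase} requires {flank_needed} upstream flanking bases"
        )
    if flank_needed and set(flank[-flank_needed:]) - _VALID:
        raise SequenceError("non-ACGT character in upstream flank")

    frame_shift = len(seq) % 3 != 0
    reading = (flank[-flank_needed:] if flank_needed else "") + seq
    in_frame_stop = any(
        reading[i : i + 3] in STOP_CODONS for i in range(0, len(reading) - 2, 3)
    )
    if frame_shift:
        category = "frameshift"
    elif in_frame_stop:
        category = "stop"
    else:
        category = "neither"
    return ConsequenceCall(
        event_id=event_id,
        frame_shift=frame_shift,
        in_frame_stop=in_frame_stop,
        category=category,
        inserted_length=len(seq),
        phase=phase,
    )


def splice_site_distance(event: SplicingEvent) -> SpliceSiteSpacing:
    """Distance between the two alternative splice-site coordinates."""
    if event.event_type not in ("A3S", "A5S"):
        raise EventDefinitionError(
            f"{event.event_id}: splice-site spacing applies to A3S/A5S events only"
        )
    (s1, e1), (s2, e2) = event.junctions
    distance = abs(e1 - e2) if s1 == s2 else abs(s1 - s2)
    return SpliceSiteSpacing(
        event_id=event.event_id,
        distance_nt=distance,
        frame_preserving=distance % 3 == 0,
    )


def upstream_bias_fraction(
    records: pd.DataFrame, cell: str, event_type: str = "A3S"
) -> float:
    """Fraction of nonzero-index events with positive (upstream) index.

    ``records`` is a uniqueness table with ``cell_type``, ``event_type``
    and ``index`` columns.
    """
    sub = records[
        (records["cell_type"] == cell)
        & (records["event_type"] == event_type)
        & (records["index"] != 0)
    ]
    if sub.empty:
        raise AnalysisError(
            f"no nonzero-index {event_type} records for cell {cell!r}"
        )
    return float((sub["index"] > 0).mean())


def classify_fasta(
    fasta_path: str | Path,
    phases: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every record of a FASTA keyed by event id.

    ``phases`` carries ``event_id``, ``phase`` and optional
    ``upstream_flank`` columns; events missing from it default to phase 0.
    """
    phase_of = phases.set_index("event_id") if len(phases) else pd.DataFrame()
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        phase, flank = 0, ""
        if rec.id in getattr(phase_of, "index", []):
            phase = int(phase_of.loc[rec.id, "phase"])
            if "upstream_flank" in phase_of.columns:
                val = phase_of.loc[rec.id, "upstream_flank"]
                flank = "" if pd.isna(val) else str(val)
        call = classify_inserted_sequence(str(rec.seq), phase, flank, event_id=rec.id)
        rows.append(
            {
                "event_id": call.event_id,
                "inserted_length": call.inserted_length,
                "phase": call.phase,
                "frame_shift": call.frame_shift,
                "in_frame_stop": call.in_frame_stop,
                "category": call.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "inserted_length", "phase", "frame_shift", "in_frame_stop", "category"],
    )
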