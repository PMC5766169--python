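"""Transcript-coordinate SAM input: mate re-pairing and stop assignment.

Forward and reverse mates are mapped independently (sense-only and
antisense-only respectively) and re-joined here by read name.  Each
surviving pair is converted into the two coordinates the method needs:

* the polymerase position = the reverse mate's 3'-most aligned
  transcript coordinate (the ligated adapter marks the nascent RNA 3'
  end, so the mate's far coordinate — not its POS — is the one that
  matters, computed through reference-consuming CIGAR operations);
* the RT-stop-inferred modified base = the forward mate's 5'-most
  aligned position minus one (the modified base is the nucleotide
  immediately downstream, in RNA orientation, of the cDNA 5' terminus).

Coordinates are 1-based closed throughout, matching SAM convention.
Multi-mapped pairs (both mates consistently mapping to k transcripts)
are emitted k times at weight 1/k so that total signal is conserved
across repeated genes such as rRNA operons; a ``drop`` policy is also
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "TranscriptAnnotation",
    "RawPair",
    "PairedAssignment",
    "PairingStats",
    "load_transcripts",
    "repair_mates",
    "assign_intermediate",
    "collapse_duplicates",
    "assignments_from_sam",
    "write_pair_table",
    "read_pair_table",
]

_IUPAC = frozenset("ACGTUNRYSWKMBDHV")


@dataclass(eq=False)
class TranscriptAnnotation:
    """A transcript sequence with its precomputed A/C positions (1-based)."""

    id: str
    sequence: str
    ac_positions: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


def annotate_transcript(name: str, sequence: str) -> TranscriptAnnotation:
    seq = sequence.upper().replace("U", "T")
    for off, ch in enumerate(seq, start=1):
        if ch not in _IUPAC:
            raise ValueError(f"record {name!r}: non-IUPAC character {ch!r} at offset {off}")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    ac = np.flatnonzero((arr == b"A") | (arr == b"C")) + 1
    return TranscriptAnnotation(id=name, sequence=seq, ac_positions=ac)


def load_transcripts(fasta_path) -> dict[str, TranscriptAnnotation]:
    """Load a FASTA file into annotations keyed by record id.

    Raises on duplicate ids or non-IUPAC characters (naming the record
    and offset).
    """
    out: dict[str, TranscriptAnnotation] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {fasta_path}")
        out[rec.id] = annotate_transcript(rec.id, str(rec.seq))
    return out


@dataclass(frozen=True)
class RawPair:
    """A re-paired forward/reverse mate couple on one transcript."""

    name: str
    transcript_id: str
    weight: float
    fwd_start5: int       # forward mate 5'-most aligned position (1-based)
    fwd_softclip5: bool   # soft-clip at the forward mate's 5' end
    fwd_is_reverse: bool
    rev_end3: int         # reverse mate 3'-most aligned position (1-based)
    rev_is_reverse: bool


@dataclass
class PairingStats:
    """Exact accounting over the pairing and assignment stages.

    Name-level: ``names_total = names_paired + orphans + cross_transcript``.
    Pair-level: ``pairs_in = assigned + coverage_only + rejected_strand +
    rejected_out_of_range + rejected_inconsistent``.
    """

    names_total: int = 0
    names_paired: int = 0
    orphans: int = 0
    cross_transcript: int = 0
    pairs_in: int = 0
    assigned: int = 0
    coverage_only: int = 0
    rejected_strand: int = 0
    rejected_out_of_range: int = 0
    rejected_inconsistent: int = 0
    duplicates_removed: int = 0

    def names_conserved(self) -> bool:
        return self.names_total == self.names_paired + self.orphans + self.cross_transcript

    def pairs_conserved(self) -> bool:
        return self.pairs_in == (self.assigned + self.coverage_only + self.rejected_strand
                                 + self.rejected_out_of_range + self.rejected_inconsistent)


def _collect_alignments(source) -> dict[str, dict[str, pysam.AlignedSegment]]:
    """Read name -> reference -> first mapped alignment."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle = pysam.AlignmentFile(str(source), "r", check_sq=False)
        segments: Iterable[pysam.AlignedSegment] = handle
    else:
        handle = None
        segments = source
    out: dict[str, dict[str, pysam.AlignedSegment]] = {}
    try:
        for seg in segments:
            if seg.is_unmapped or seg.reference_name is None:
                out.setdefault(seg.query_name, {})
                continue
            out.setdefault(seg.query_name, {}).setdefault(seg.reference_name, seg)
    finally:
        if handle is not None:
            handle.close()
    return out


def repair_mates(fwd_source, rev_source,
                 stats: PairingStats | None = None,
                 multimap_policy: str = "weight") -> tuple[list[RawPair], PairingStats]:
    """Re-pair independently mapped forward and reverse mates by read name.

    A read name whose mates both map to k >= 1 common transcripts yields
    k pairs of weight 1/k each (``multimap_policy='weight'``) or is
    dropped for k > 1 (``'drop'``).  Reads with only one mapped mate are
    counted as orphans; mates mapping to disjoint transcript sets are
    counted as cross-transcript drops.
    """
    if multimap_policy not in ("weight", "drop"):
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    stats = stats or PairingStats()
    fwd = _collect_alignments(fwd_source)
    rev = _collect_alignments(rev_source)
    pairs: list[RawPair] = []
    names = sorted(set(fwd) | set(rev))
    for name in names:
        stats.names_total += 1
        f_map = fwd.get(name, {})
        r_map = rev.get(name, {})
        if not f_map or not r_map:
            stats.orphans += 1
            continue
        common = sorted(set(f_map) & set(r_map))
        if not common:
            stats.cross_transcript += 1
            continue
        k = len(common)
        if k > 1 and multimap_policy == "drop":
            stats.cross_transcript += 1
            continue
        stats.names_paired += 1
        for ref in common:
            fseg, rseg = f_map[ref], r_map[ref]
            cig = fseg.cigartuples or ()
            softclip5 = bool(cig) and cig[0][0] == pysam.CSOFT_CLIP
            pairs.append(RawPair(
                name=name,
                transcript_id=ref,
                weight=1.0 / k,
                fwd_start5=fseg.reference_start + 1,
                fwd_softclip5=softclip5,
                fwd_is_reverse=fseg.is_reverse,
                rev_end3=int(rseg.reference_end),
                rev_is_reverse=rseg.is_reverse,
            ))
    return pairs, stats


@dataclass(frozen=True)
class PairedAssignment:
    """One read pair reduced to (intermediate length, stop position).

    ``stop_pos`` is the inferred modified base; None with
    ``full_length=True`` means the cDNA reached the transcript 5' end,
    and None with ``full_length=False`` marks a coverage-only pair whose
    stop call was disqualified (5' soft-clip).  ``cdna_start`` is the
    5'-most transcript position covered by the cDNA.
    """

    transcript_id: str
    intermediate_len: int
    stop_pos: int | None
    full_length: bool
    cdna_start: int
    weight: float = 1.0

    @property
    def duplicate_key(self) -> tuple[str, int, int | None]:
        return (self.transcript_id, self.intermediate_len, self.stop_pos)


def assign_intermediate(pair: RawPair,
                        transcript_length: int,
                        stats: PairingStats | None = None) -> PairedAssignment | None:
    """Convert a raw mate pair into a :class:`PairedAssignment`.

    Returns None for rejected pairs (wrong strand, reverse 3' end beyond
    the transcript, or stop at/after the polymerase position), updating
    the counters.
    """
    if stats is not None:
        stats.pairs_in += 1
    if pair.fwd_is_reverse or not pair.rev_is_reverse:
        if stats is not None:
            stats.rejected_strand += 1
        return None
    L = pair.rev_end3
    if L is None or L > transcript_length or L < 1:
        if stats is not None:
            stats.rejected_out_of_range += 1
        return None
    if pair.fwd_softclip5:
        # clipped bases hide the true stop; keep the pair for coverage only
        if stats is not None:
            stats.coverage_only += 1
        return PairedAssignment(
            transcript_id=pair.transcript_id, intermediate_len=L, stop_pos=None,
            full_length=False, cdna_start=pair.fwd_start5, weight=pair.weight,
        )
    if pair.fwd_start5 == 1:
        if stats is not None:
            stats.assigned += 1
        return PairedAssignment(
            transcript_id=pair.transcript_id, intermediate_len=L, stop_pos=None,
            full_length=True, cdna_start=1, weight=pair.weight,
        )
    stop = pair.fwd_start5 - 1
    if stop >= L:
        if stats is not None:
            stats.rejected_inconsistent += 1
        return None
    if stats is not None:
        stats.assigned += 1
    return PairedAssignment(
        transcript_id=pair.transcript_id, intermediate_len=L, stop_pos=stop,
        full_length=False, cdna_start=stop + 1, weight=pair.weight,
    )


def collapse_duplicates(assignments: Iterable[PairedAssignment],
                        stats: PairingStats | None = None) -> Iterator[PairedAssignment]:
    """Keep the first assignment per (transcript, intermediate, stop) key."""
    seen: set[tuple[str, int, int | None]] = set()
    for a in assignments:
        key = a.duplicate_key
        if key in seen:
            if stats is not None:
                stats.duplicates_removed += 1
            continue
        seen.add(key)
        yield a


def assignments_from_sam(fwd_source, rev_source,
                         transcripts: dict[str, TranscriptAnnotation],
                         multimap_policy: str = "weight"
                         ) -> tuple[list[PairedAssignment], PairingStats]:
    """Full pairing stage: re-pair mates and assign intermediates."""
    stats = PairingStats()
    pairs, stats = repair_mates(fwd_source, rev_source, stats, multimap_policy)
    out: list[PairedAssignment] = []
    for pair in pairs:
        ann = transcripts.get(pair.transcript_id)
        if ann is None:
            stats.pairs_in += 1
            stats.rejected_out_of_range += 1
            continue
        a = assign_intermediate(pair, ann.length, stats)
        if a is not None:
            out.append(a)
    return out, stats


_PAIR_TABLE_COLUMNS = ["transcript", "intermediate_len", "stop_pos", "full_length", "cdna_start", "weight"]


def write_pair_table(assignments: Iterable[PairedAssignment], path) -> None:
    """Write assignments as the pipeline's TSV interchange format."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PAIR_TABLE_COLUMNS)
        for a in assignments:
            writer.writerow([
                a.transcript_id, a.intermediate_len,
                "FULL" if a.stop_pos is None and a.full_length
                else ("NA" if a.stop_pos is None else a.stop_pos),
                int(a.full_length), a.cdna_start, repr(a.weight),
            ])


def read_pair_table(path) -> list[PairedAssignment]:
    import csv

    out: list[PairedAssignment] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _PAIR_TABLE_COLUMNS:
            raise ValueError(f"{path}: unrecognized pair-table header {header}")
        for ln, row in enumerate(reader, start=2):
            try:
                tx, L, stop, full, cstart, w = row
                stop_val = None if stop in ("FULL", "NA") else int(stop)
                out.append(PairedAssignment(
                    transcript_id=tx, intermediate_len=int(L), stop_pos=stop_val,
                    full_length=bool(int(full)), cdna_start=int(cstart), weight=float(w),
                ))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed pair-table line {ln}: {exc}") from exc
    return out
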