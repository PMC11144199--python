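"""Parse aligner SAM output into per-read groups of genomic segments.

The aligner contract: any local aligner emitting name-grouped SAM in which
split reads appear as supplementary (0x800) records, mates are aligned
independently (no mate rescue), and alternative mappings are secondary
(0x100).  BWA-MEM invoked with ``-S -P -5`` satisfies this; STAR output
reduces to the same contract once its MAPQ 255 ("unique") is remapped to 60.

Coordinates are SAM 1-based inclusive throughout.  Query intervals are
expressed on the ORIGINAL read (minus-strand alignments are mirrored), so
clip accounting is strand-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

# CIGAR operation codes that consume query bases within the aligned region
_QUERY_ALIGNED_OPS = {0, 1, 7, 8}  # M, I, =, X
_CLIP_OPS = {4, 5}  # S, H

SOURCES = ("stitched", "mate1", "mate2")


@dataclass
class AlnRecord:
    """One alignment line, decomposed for filtering and pair extraction."""

    read_id: str
    source: str  # stitched | mate1 | mate2
    chrom: str
    ref_start: int  # 1-based inclusive
    ref_end: int
    strand: str  # '+' | '-'
    mapq: int
    query_start: int  # 1-based inclusive, on the original read
    query_end: int
    clipped_bases: int
    read_length: int  # original read length incl. hard clips
    is_supplementary: bool = False

    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)


@dataclass
class ReadGroup:
    """All kept alignment records of one read (pair), partitioned by source."""

    read_id: str
    records: dict[str, list[AlnRecord]] = field(default_factory=dict)
    read_lengths: dict[str, int] = field(default_factory=dict)

    def add(self, rec: AlnRecord) -> None:
        self.records.setdefault(rec.source, []).append(rec)
        self.read_lengths.setdefault(rec.source, rec.read_length)

    def sources(self) -> list[str]:
        return [s for s in SOURCES if s in self.records]

    def n_records(self) -> int:
        return sum(len(v) for v in self.records.values())


def parse_record(aln: pysam.AlignedSegment) -> AlnRecord | None:
    """Decompose one SAM record; returns None for unmapped/secondary lines."""
    if aln.is_unmapped or aln.is_secondary:
        return None
    cig = aln.cigartuples
    if not cig:
        raise ValueError(f"alignment for read {aln.query_name!r} has no CIGAR")
    # leading / trailing clips in alignment orientation
    lead = cig[0][1] if cig[0][0] in _CLIP_OPS else 0
    trail = cig[-1][1] if cig[-1][0] in _CLIP_OPS else 0
    aligned = sum(n for op, n in cig if op in _QUERY_ALIGNED_OPS)
    if aligned == 0:
        raise ValueError(f"alignment for read {aln.query_name!r} consumes no query bases")
    read_len = lead + aligned + trail
    if aln.is_reverse:
        query_start, query_end = trail + 1, trail + aligned
        strand = "-"
    else:
        query_start, query_end = lead + 1, lead + aligned
        strand = "+"
    if aln.is_paired:
        source = "mate1" if aln.is_read1 else "mate2"
    else:
        source = "stitched"
    mapq = aln.mapping_quality
    if mapq == 255:  # STAR's "unique" convention
        mapq = 60
    return AlnRecord(
        read_id=aln.query_name,
        source=source,
        chrom=aln.reference_name,
        ref_start=aln.reference_start + 1,
        ref_end=aln.reference_end,  # pysam end is 0-based exclusive == 1-based inclusive
        strand=strand,
        mapq=mapq,
        query_start=query_start,
        query_end=query_end,
        clipped_bases=lead + trail,
        read_length=read_len,
        is_supplementary=aln.is_supplementary,
    )


def parse_sam(path: str | Path) -> Iterator[AlnRecord]:
    """Stream kept AlnRecords from a SAM text file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            rec = parse_record(aln)
            if rec is not None:
                yield rec


def group_by_read(records: Iterable[AlnRecord]) -> Iterator[ReadGroup]:
    """Collect name-grouped records into ReadGroups, preserving input order.

    The aligner invocation guarantees grouped output; a read id recurring
    after the group closed indicates unsorted input and raises.
    """
    seen: set[str] = set()
    group: ReadGroup | None = None
    for rec in records:
        if group is None or rec.read_id != group.read_id:
            if rec.read_id in seen:
                raise ValueError(f"input not grouped by read id: {rec.read_id!r} reappears")
            if group is not None:
                yield group
                seen.add(group.read_id)
            group = ReadGroup(rec.read_id)
        group.add(rec)
    if group is not None:
        yield group


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end > last_end:
            total += end - start + 1
            last_end = end
    return total


def clip_fraction(group: ReadGroup, source: str) -> float:
    """Fraction of a source read's cycles covered by no kept alignment.

    The union (not the sum) of query intervals is used so overlapping split
    alignments are not double-counted.  A source with no records is fully
    clipped (fraction 1).
    """
    recs = group.records.get(source, [])
    if not recs:
        return 1.0
    read_len = group.read_lengths[source]
    covered = _interval_union([r.query_interval() for r in recs])
    return (read_len - covered) / read_len
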