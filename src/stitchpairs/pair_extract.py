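"""Alignment filtering, chimeric classification and outermost-end pairing.

The filtering cascade for each read group:

1. drop alignment records with MAPQ below 10;
2. classify by segment count — stitched fragments mapping to one region
   (non-chimeric) or two regions (split across the ligation junction) are
   kept; unstitched pairs are kept when each mate maps to one region, or when
   one mate splits into two segments one of which pairs face-to-face with the
   other mate on the same fragment (three records, two loci);
3. drop reads with more than half of their cycles clipped;
4. report the two outermost ends — the junction-distal mapped coordinate of
   each locus — as the contact pair, in upper-triangle order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator

from .sam_ingest import AlnRecord, ReadGroup, clip_fraction

if TYPE_CHECKING:  # avoids a circular import; pairs_io re-exports ContactPair
    from .pairs_io import ChromOrder

CATEGORIES = ("stitched_1seg", "stitched_2seg", "unstitched_2loci", "unstitched_3rec")


@dataclass
class ExtractConfig:
    min_mapq: int = 10
    max_clip_frac: float = 0.5
    # maximum implied fragment span for calling a split segment and the other
    # mate products of the same fragment (3-record case)
    mate_join_max_span: int = 1000
    # reciprocal query-overlap above which two records count as one region
    region_merge_overlap: float = 0.5
    min_span: int = 0  # optional post-hoc cis-span filter, off by default

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if not 0.0 <= self.max_clip_frac <= 1.0:
            raise ValueError("max_clip_frac outside [0, 1]")


@dataclass
class ContactPair:
    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    category: str


@dataclass
class Classification:
    category: str | None  # None when rejected
    reason: str | None = None  # rejection reason
    # records in role order: for 2-locus categories, [locus1, locus2] by query
    # or mate order; for unstitched_3rec, [distal split segment, lone mate]
    loci: list[AlnRecord] = field(default_factory=list)
    # outer side per locus: "query_start" or "query_end"
    outer_sides: list[str] = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return self.category is None


# ------------------------------------------------------------------ filtering


def filter_mapq(group: ReadGroup, config: ExtractConfig) -> ReadGroup:
    """Remove records with mapping quality below the threshold."""
    out = ReadGroup(group.read_id)
    out.read_lengths = dict(group.read_lengths)
    for recs in group.records.values():
        for rec in recs:
            if rec.mapq >= config.min_mapq:
                out.add(rec)
    return out


def _reciprocal_overlap(a: AlnRecord, b: AlnRecord) -> float:
    lo = max(a.query_start, b.query_start)
    hi = min(a.query_end, b.query_end)
    if hi < lo:
        return 0.0
    ov = hi - lo + 1
    return min(ov / (a.query_end - a.query_start + 1), ov / (b.query_end - b.query_start + 1))


def merge_regions(records: list[AlnRecord], config: ExtractConfig) -> list[AlnRecord]:
    """Collapse records whose query intervals reciprocally overlap > 50 %.

    Such records describe the same stretch of the read (e.g. an ambiguous
    re-alignment of one segment) and must count as one region; the
    highest-MAPQ record represents the region (primary wins ties).
    """
    kept: list[AlnRecord] = []
    for rec in sorted(records, key=lambda r: (-r.mapq, r.is_supplementary)):
        if any(_reciprocal_overlap(rec, k) > config.region_merge_overlap for k in kept):
            continue
        kept.append(rec)
    kept.sort(key=lambda r: r.query_start)
    return kept


# -------------------------------------------------------------- classification


def _faces_and_span(a: AlnRecord, b: AlnRecord) -> int | None:
    """Implied fragment span if a and b look like two ends of one fragment.

    Requires same chromosome, opposite strands and face-to-face orientation
    (the plus-strand record upstream of the minus-strand one).  Returns the
    outermost-to-outermost span in bp, or None when the configuration does
    not qualify.
    """
    if a.chrom != b.chrom or a.strand == b.strand:
        return None
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    if plus.ref_start > minus.ref_end:
        return None
    return minus.ref_end - plus.ref_start + 1


def classify_group(group: ReadGroup, config: ExtractConfig) -> Classification:
    """Segment-count classification of a MAPQ-filtered read group."""
    if "stitched" in group.records:
        segs = merge_regions(group.records["stitched"], config)
        if len(segs) == 0:
            return Classification(None, "unmapped")
        if len(segs) == 1:
            cls = Classification("stitched_1seg", loci=[segs[0], segs[0]],
                                 outer_sides=["query_start", "query_end"])
        elif len(segs) == 2:
            cls = Classification("stitched_2seg", loci=segs,
                                 outer_sides=["query_start", "query_end"])
        else:
            return Classification(None, "multi_segment")
        return _apply_clip_filter(group, cls, config)

    m1 = merge_regions(group.records.get("mate1", []), config)
    m2 = merge_regions(group.records.get("mate2", []), config)
    if not m1 or not m2:
        return Classification(None, "singleton" if (m1 or m2) else "unmapped")
    if len(m1) == 1 and len(m2) == 1:
        cls = Classification("unstitched_2loci", loci=[m1[0], m2[0]],
                             outer_sides=["query_start", "query_start"])
        return _apply_clip_filter(group, cls, config)
    if {len(m1), len(m2)} == {1, 2}:
        split, lone = (m1, m2[0]) if len(m1) == 2 else (m2, m1[0])
        joined = [(span, i) for i, s in enumerate(split)
                  if (span := _faces_and_span(s, lone)) is not None
                  and span <= config.mate_join_max_span]
        if joined:  # ambiguity (both qualify) resolved toward the smaller span
            paired = split[min(joined)[1]]
            distal = split[0] if paired is split[1] else split[1]
            outer = "query_start" if distal is split[0] else "query_end"
            cls = Classification("unstitched_3rec", loci=[distal, lone],
                                 outer_sides=[outer, "query_start"])
            return _apply_clip_filter(group, cls, config)
        return Classification(None, "unpaired_split")
    return Classification(None, "multi_segment")


def _apply_clip_filter(
    group: ReadGroup, cls: Classification, config: ExtractConfig
) -> Classification:
    for source in group.sources():
        if clip_fraction(group, source) > config.max_clip_frac:
            return Classification(None, "overclipped")
    return cls


# ----------------------------------------------------------------- extraction


def _outer_end(rec: AlnRecord, side: str) -> tuple[int, str]:
    """Reference coordinate and strand of a locus's junction-distal end.

    The outer end is the mapped position of the query base most distal from
    the ligation junction; its strand points from that base into the
    fragment, so a plus value means the fragment extends rightward.
    """
    at_query_start = side == "query_start"
    if (rec.strand == "+") == at_query_start:
        return rec.ref_start, "+"
    return rec.ref_end, "-"


def extract_pair(group: ReadGroup, cls: Classification, order: ChromOrder) -> ContactPair:
    """Report the two outermost ends of a classified group as a contact pair."""
    if cls.rejected:
        raise ValueError(f"cannot extract a pair from rejected group {group.read_id!r}")
    (rec_a, rec_b) = cls.loci
    pos1, strand1 = _outer_end(rec_a, cls.outer_sides[0])
    pos2, strand2 = _outer_end(rec_b, cls.outer_sides[1])
    end1 = (order.rank(rec_a.chrom), pos1, rec_a.chrom, strand1)
    end2 = (order.rank(rec_b.chrom), pos2, rec_b.chrom, strand2)
    if end1[:2] > end2[:2]:
        end1, end2 = end2, end1
    return ContactPair(
        group.read_id,
        end1[2], end1[1], end1[3],
        end2[2], end2[1], end2[3],
        cls.category,
    )


def extract_pairs(
    groups: Iterable[ReadGroup],
    order: ChromOrder,
    config: ExtractConfig | None = None,
    counts: dict[str, int] | None = None,
) -> Iterator[ContactPair]:
    """Filter, classify and extract a stream of read groups.

    ``counts`` (optional, mutated in place) accumulates per-category and
    per-rejection-reason tallies so that groups in = pairs out + rejected.
    """
    config = config or ExtractConfig()
    for group in groups:
        filtered = filter_mapq(group, config)
        cls = classify_group(filtered, config)
        if cls.rejected:
            if counts is not None:
                counts[f"rejected_{cls.reason}"] = counts.get(f"rejected_{cls.reason}", 0) + 1
            continue
        pair = extract_pair(filtered, cls, order)
        if config.min_span and pair.chrom1 == pair.chrom2 and (
            pair.pos2 - pair.pos1 < config.min_span
        ):
            if counts is not None:
                counts["rejected_min_span"] = counts.get("rejected_min_span", 0) + 1
            continue
        if counts is not None:
            counts[pair.category] = counts.get(pair.category, 0) + 1
        yield pair
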