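"""MAPQ/clip filtering, chimeric classification, outermost-end extraction."""

from __future__ import annotations

import itertools

import pytest

from stitchpairs.pair_extract import (
    Classification,
    ContactPair,
    ExtractConfig,
    classify_group,
    extract_pair,
    extract_pairs,
    filter_mapq,
)
from stitchpairs.pairs_io import ChromOrder
from stitchpairs.sam_ingest import ReadGroup

from conftest import make_aln

ORDER = ChromOrder([("chrA", 1_000_000), ("chrB", 500_000), ("chrC", 250_000)])
CFG = ExtractConfig()


def group_of(*recs) -> ReadGroup:
    g = ReadGroup(recs[0].read_id)
    for r in recs:
        g.add(r)
    return g


# ------------------------------------------------------------------- brute force


def naive_classify(group: ReadGroup, cfg: ExtractConfig) -> str | None:
    """Independent restatement of the filtering rules, for cross-checking.

    Counts kept records per source read after the MAPQ cut: stitched reads
    pass with one or two regions; unstitched pairs pass with one region per
    mate, or with a 2+1 split where one split segment lies face-to-face with
    the lone mate on the same chromosome within the joinable span; finally
    any read with more than half its cycles unaligned fails.  Returns the
    category name or None.  (Assumes non-overlapping query intervals.)
    """
    recs = {
        src: [r for r in group.records.get(src, []) if r.mapq >= cfg.min_mapq]
        for src in ("stitched", "mate1", "mate2")
    }

    def overclipped(src):
        kept = recs[src]
        if not kept:
            return False
        covered = sum(r.query_end - r.query_start + 1 for r in kept)
        return (group.read_lengths[src] - covered) / group.read_lengths[src] > cfg.max_clip_frac

    if group.records.get("stitched") or not (group.records.get("mate1") or group.records.get("mate2")):
        n = len(recs["stitched"])
        if n not in (1, 2):
            return None
        if overclipped("stitched"):
            return None
        return "stitched_1seg" if n == 1 else "stitched_2seg"

    n1, n2 = len(recs["mate1"]), len(recs["mate2"])
    if any(overclipped(s) for s in ("mate1", "mate2") if recs[s]):
        clip_ok = False
    else:
        clip_ok = True
    if n1 == 1 and n2 == 1:
        return "unstitched_2loci" if clip_ok else None
    if sorted([n1, n2]) == [1, 2]:
        split = recs["mate1"] if n1 == 2 else recs["mate2"]
        lone = (recs["mate2"] if n1 == 2 else recs["mate1"])[0]
        for seg in split:
            if seg.chrom != lone.chrom or seg.strand == lone.strand:
                continue
            plus, minus = (seg, lone) if seg.strand == "+" else (lone, seg)
            if plus.ref_start <= minus.ref_end and (
                minus.ref_end - plus.ref_start + 1 <= cfg.mate_join_max_span
            ):
                return "unstitched_3rec" if clip_ok else None
        return None
    return None


# ------------------------------------------------------------------------ tests


class TestMapqFilter:
    def test_threshold_boundary(self):
        g = group_of(
            make_aln(mapq=9, query_start=1, query_end=50),
            make_aln(mapq=10, query_start=51, query_end=100),
            make_aln(mapq=60, query_start=101, query_end=150),
        )
        kept = filter_mapq(g, CFG)
        assert sorted(r.mapq for r in kept.records["stitched"]) == [10, 60]

    def test_all_removed_gives_empty_group(self):
        g = group_of(make_aln(mapq=0))
        assert filter_mapq(g, CFG).n_records() == 0

    def test_zero_threshold_is_identity(self):
        g = group_of(make_aln(mapq=0), make_aln(mapq=5, query_start=100, query_end=150))
        assert filter_mapq(g, ExtractConfig(min_mapq=0)).n_records() == 2


class TestClassify:
    def test_stitched_single_full_segment(self):
        g = group_of(make_aln(read_length=200, query_end=200, ref_end=1199))
        cls = classify_group(g, CFG)
        assert cls.category == "stitched_1seg"

    def test_stitched_three_segments_rejected(self):
        g = group_of(
            make_aln(read_length=210, query_start=1, query_end=70),
            make_aln(read_length=210, query_start=71, query_end=140, ref_start=5000, ref_end=5069),
            make_aln(read_length=210, query_start=141, query_end=210, ref_start=9000, ref_end=9069),
        )
        cls = classify_group(g, CFG)
        assert cls.rejected and cls.reason == "multi_segment"

    def test_three_record_join_example(self):
        """mate1 split chrA+/chrB-; mate2 on chrB+, 250 bp implied span."""
        m1a = make_aln(source="mate1", chrom="chrA", ref_start=1000, ref_end=1089,
                       strand="+", query_start=1, query_end=90)
        m1b = make_aln(source="mate1", chrom="chrB", ref_start=9000, ref_end=9059,
                       strand="-", query_start=91, query_end=150)
        m2 = make_aln(source="mate2", chrom="chrB", ref_start=8810, ref_end=8959,
                      strand="+", query_start=1, query_end=150)
        cls = classify_group(group_of(m1a, m1b, m2), CFG)
        assert cls.category == "unstitched_3rec"
        assert cls.loci[0] is m1a  # distal = the unpaired split segment

    def test_three_record_span_exceeds_limit(self):
        m1a = make_aln(source="mate1", chrom="chrA", ref_start=1000, ref_end=1089,
                       strand="+", query_start=1, query_end=90)
        m1b = make_aln(source="mate1", chrom="chrB", ref_start=9000, ref_end=9059,
                       strand="-", query_start=91, query_end=150)
        m2 = make_aln(source="mate2", chrom="chrB", ref_start=5000, ref_end=5149,
                      strand="+", query_start=1, query_end=150)
        cls = classify_group(group_of(m1a, m1b, m2), CFG)
        assert cls.rejected and cls.reason == "unpaired_split"

    def test_overclip_boundary(self):
        half = make_aln(read_length=150, query_start=1, query_end=75)  # exactly 50 %
        assert classify_group(group_of(half), CFG).category == "stitched_1seg"
        over = make_aln(read_length=150, query_start=1, query_end=74)  # > 50 %
        cls = classify_group(group_of(over), CFG)
        assert cls.rejected and cls.reason == "overclipped"

    def test_permutation_invariance(self):
        recs = [
            make_aln(source="mate1", chrom="chrA", ref_start=1000, ref_end=1089,
                     strand="+", query_start=1, query_end=90),
            make_aln(source="mate1", chrom="chrB", ref_start=9000, ref_end=9059,
                     strand="-", query_start=91, query_end=150),
            make_aln(source="mate2", chrom="chrB", ref_start=8810, ref_end=8959,
                     strand="+", query_start=1, query_end=150),
        ]
        results = set()
        for perm in itertools.permutations(recs):
            cls = classify_group(group_of(*perm), CFG)
            results.add((cls.category, tuple(id(l) for l in cls.loci)))
        assert len(results) == 1

    def test_matches_brute_force_over_enumerated_configurations(self):
        """Exhaustive small-configuration truth table vs naive_classify."""
        chroms = ["chrA", "chrB"]
        strands = ["+", "-"]
        positions = [1000, 1500, 50_000]
        checked = 0

        def seg(source, i, n, chrom, strand, pos, mapq=60):
            width = 150 // n
            qs = i * width + 1
            qe = (i + 1) * width if i < n - 1 else 150
            return make_aln(
                source=source, chrom=chrom, strand=strand, mapq=mapq,
                ref_start=pos, ref_end=pos + (qe - qs), query_start=qs, query_end=qe,
            )

        # stitched groups: 1-3 segments over chrom/strand combinations
        for n in (1, 2, 3):
            for combo in itertools.product(zip(chroms * 2, strands, positions), repeat=n):
                g = ReadGroup("r")
                for i, (chrom, strand, pos) in enumerate(combo):
                    g.add(seg("stitched", i, n, chrom, strand, pos + 10_000 * i))
                cls = classify_group(filter_mapq(g, CFG), CFG)
                assert cls.category == naive_classify(g, CFG)
                checked += 1

        # unstitched groups: (n1, n2) in {1,2}^2 over chrom/strand/pos combos
        for n1, n2 in itertools.product((1, 2), repeat=2):
            specs1 = itertools.product(chroms, strands, positions[:2])
            for c1 in itertools.product(list(specs1), repeat=n1):
                for c2 in itertools.product(
                    itertools.product(chroms, strands, positions), repeat=n2
                ):
                    g = ReadGroup("r")
                    for i, (chrom, strand, pos) in enumerate(c1):
                        g.add(seg("mate1", i, n1, chrom, strand, pos))
                    for i, (chrom, strand, pos) in enumerate(c2):
                        g.add(seg("mate2", i, n2, chrom, strand, pos))
                    cls = classify_group(filter_mapq(g, CFG), CFG)
                    assert cls.category == naive_classify(g, CFG), (c1, c2)
                    checked += 1
        assert checked > 2_000

    def test_mapq_filtered_singleton(self):
        m1 = make_aln(source="mate1", mapq=5)
        m2 = make_aln(source="mate2", mapq=60)
        cls = classify_group(filter_mapq(group_of(m1, m2), CFG), CFG)
        assert cls.rejected and cls.reason == "singleton"


class TestExtract:
    def test_stitched_single_segment_reports_fragment_ends(self):
        rec = make_aln(chrom="chrC", ref_start=5001, ref_end=5200,
                       read_length=200, query_end=200)
        cls = classify_group(group_of(rec), CFG)
        pair = extract_pair(group_of(rec), cls, ORDER)
        assert (pair.chrom1, pair.pos1, pair.strand1) == ("chrC", 5001, "+")
        assert (pair.chrom2, pair.pos2, pair.strand2) == ("chrC", 5200, "-")

    def test_unstitched_five_prime_ends_and_upper_triangle_flip(self):
        m1 = make_aln(source="mate1", chrom="chrB", ref_start=800, ref_end=949, strand="-")
        m2 = make_aln(source="mate2", chrom="chrA", ref_start=100, ref_end=249, strand="+")
        g = group_of(m1, m2)
        pair = extract_pair(g, classify_group(g, CFG), ORDER)
        assert (pair.chrom1, pair.pos1, pair.strand1) == ("chrA", 100, "+")
        assert (pair.chrom2, pair.pos2, pair.strand2) == ("chrB", 949, "-")

    def test_stitched_two_segment_outer_ends(self):
        s1 = make_aln(chrom="chrA", ref_start=10_000, ref_end=10_099, strand="+",
                      query_start=1, query_end=100, read_length=250)
        s2 = make_aln(chrom="chrB", ref_start=20_000, ref_end=20_149, strand="-",
                      query_start=101, query_end=250, read_length=250)
        g = group_of(s1, s2)
        pair = extract_pair(g, classify_group(g, CFG), ORDER)
        # first segment's outer end = coordinate of query base 1 (+ -> ref_start)
        assert (pair.chrom1, pair.pos1, pair.strand1) == ("chrA", 10_000, "+")
        # second segment on '-': last query base maps to ref_start, facing '+'
        assert (pair.chrom2, pair.pos2, pair.strand2) == ("chrB", 20_000, "+")

    def test_rejected_group_raises(self):
        g = group_of(make_aln(mapq=0))
        with pytest.raises(ValueError):
            extract_pair(g, Classification(None, "unmapped"), ORDER)

    def test_stream_accounting_and_upper_triangle(self):
        groups = []
        for i, (chrom, start) in enumerate(
            [("chrB", 700), ("chrA", 100), ("chrC", 900), ("chrA", 50)]
        ):
            groups.append(group_of(make_aln(
                read_id=f"g{i}", chrom=chrom, ref_start=start, ref_end=start + 199,
                read_length=200, query_end=200,
            )))
        groups.append(group_of(make_aln(read_id="bad", mapq=0)))
        counts: dict[str, int] = {}
        pairs = list(extract_pairs(groups, ORDER, CFG, counts))
        assert len(pairs) == 4
        assert counts == {"stitched_1seg": 4, "rejected_unmapped": 1}
        for p in pairs:
            assert (ORDER.rank(p.chrom1), p.pos1) <= (ORDER.rank(p.chrom2), p.pos2)

    def test_min_span_filter(self):
        g = group_of(make_aln(chrom="chrA", ref_start=100, ref_end=299,
                              read_length=200, query_end=200))
        cfg = ExtractConfig(min_span=1000)
        assert list(extract_pairs([g], ORDER, cfg)) == []
        assert len(list(extract_pairs([g], ORDER, CFG))) == 1
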