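"""Streaming FASTQ preprocessing: trim, prefix-dedup, overlap stitching.

Pipeline order is fixed: adapter/quality trimming, then PCR-duplicate removal
keyed on the heading 16 bp of both mates, then overlap-based stitching of
read pairs whose insert is shorter than twice the read length.  The stitch
stage can be forced on/off or decided automatically from the first 10 000
pairs of the stream (enabled when more than 10 % of them stitch).
"""

from __future__ import annotations

import gzip
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._util import deterministic_gzip_writer
from .genome import revcomp

# Illumina TruSeq adapter pair (read-through adapters at the 3' ends)
TRUSEQ_ADAPTER1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
TRUSEQ_ADAPTER2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

PHRED_OFFSET = 33


@dataclass
class RawReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch for read {self.read_id!r}")


@dataclass
class StitchOutcome:
    """Result of processing one pair: merged fragment, surviving pair, or drop."""

    kind: str  # stitched | unstitched | dropped
    read_id: str
    merged_seq: str | None = None
    merged_qual: str | None = None
    pair: RawReadPair | None = None
    drop_reason: str | None = None  # too_short | duplicate


@dataclass
class PreprocessConfig:
    adapters: tuple[str, str] = (TRUSEQ_ADAPTER1, TRUSEQ_ADAPTER2)
    quality_floor: int = 20
    min_read_len: int = 36
    dedup_prefix_len: int = 16
    stitch_min_overlap: int = 10
    stitch_max_mismatch_frac: float = 0.1
    stitch_mode: str = "auto"  # auto | on | off
    auto_probe_reads: int = 10_000
    auto_threshold: float = 0.10

    def __post_init__(self) -> None:
        for name in ("quality_floor", "min_read_len", "dedup_prefix_len", "stitch_min_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.stitch_max_mismatch_frac <= 1.0:
            raise ValueError("stitch_max_mismatch_frac outside [0, 1]")
        if self.stitch_mode not in ("auto", "on", "off"):
            raise ValueError(f"unknown stitch_mode {self.stitch_mode!r}")


# ----------------------------------------------------------------------- trim


def _find_adapter(seq: str, adapter: str) -> int:
    """Leftmost position where a suffix-anchored adapter match begins.

    A match at position p covers seq[p:] against the adapter prefix of the
    same length, allowing one mismatch per 8 matched bases; matches of fewer
    than 3 bases are not considered, and the minimal 3 bp match at the
    extreme 3' end must be exact.  Returns len(seq) when no match is found.
    """
    n = len(seq)
    for p in range(max(0, n - len(adapter)), n - 2):
        m = n - p
        allowed = 0 if m <= 3 else m // 8
        mism = 0
        for a, b in zip(seq[p:], adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return p
    return n


def _trim_one(seq: str, qual: str, adapter: str, floor: int) -> tuple[str, str]:
    cut = _find_adapter(seq, adapter)
    seq, qual = seq[:cut], qual[:cut]
    end = len(qual)
    while end > 0 and ord(qual[end - 1]) - PHRED_OFFSET < floor:
        end -= 1
    return seq[:end], qual[:end]


def trim_read_pair(pair: RawReadPair, config: PreprocessConfig) -> RawReadPair | StitchOutcome:
    """Adapter- and quality-trim both mates independently.

    Returns the trimmed pair, or a ``dropped(too_short)`` outcome when either
    mate falls below ``min_read_len``.
    """
    if not pair.seq1 or not pair.seq2:
        return StitchOutcome("dropped", pair.read_id, drop_reason="too_short")
    s1, q1 = _trim_one(pair.seq1, pair.qual1, config.adapters[0], config.quality_floor)
    s2, q2 = _trim_one(pair.seq2, pair.qual2, config.adapters[1], config.quality_floor)
    if len(s1) < config.min_read_len or len(s2) < config.min_read_len:
        return StitchOutcome("dropped", pair.read_id, drop_reason="too_short")
    return RawReadPair(pair.read_id, s1, q1, s2, q2)


# ---------------------------------------------------------------------- dedup


def dedup_stream(
    pairs: Iterable[RawReadPair], config: PreprocessConfig
) -> Iterator[RawReadPair | StitchOutcome]:
    """Drop PCR duplicates: identical heading 16 bp in both read 1 and read 2.

    The key is the (prefix1, prefix2) tuple of post-trim sequences; reads
    shorter than the prefix length contribute their full sequence, and the
    tuple representation keeps different lengths distinct.  First occurrence
    wins; order is preserved.
    """
    k = config.dedup_prefix_len
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        key = (pair.seq1[:k], pair.seq2[:k])
        if key in seen:
            yield StitchOutcome("dropped", pair.read_id, drop_reason="duplicate")
        else:
            seen.add(key)
            yield pair


# --------------------------------------------------------------------- stitch


def stitch_pair(pair: RawReadPair, config: PreprocessConfig) -> StitchOutcome:
    """Merge mates through their 3' overlap when the insert is short.

    Candidate overlaps o (from the largest possible down to the configured
    minimum) compare the last o bases of read 1 against the first o bases of
    the reverse-complemented read 2.  The candidate with the lowest mismatch
    fraction wins (ties to the larger overlap) and is accepted only if that
    fraction is within ``stitch_max_mismatch_frac``; otherwise the pair
    survives unstitched.  Overlap bases take the higher-quality call (ties to
    read 1) with the max of the two qualities.
    """
    s1, q1 = pair.seq1, pair.qual1
    rc2 = revcomp(pair.seq2)
    rq2 = pair.qual2[::-1]
    n1, n2 = len(s1), len(rc2)
    max_o = min(n1, n2)
    if max_o < config.stitch_min_overlap:
        return StitchOutcome("unstitched", pair.read_id, pair=pair)

    a1 = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode("ascii"), dtype=np.uint8)
    best: tuple[float, int] | None = None  # (mismatch_frac, overlap)
    for o in range(max_o, config.stitch_min_overlap - 1, -1):
        mism = int(np.count_nonzero(a1[n1 - o :] != a2[:o]))
        frac = mism / o
        if frac <= config.stitch_max_mismatch_frac and (
            best is None or frac < best[0] or (frac == best[0] and o > best[1])
        ):
            best = (frac, o)
    if best is None:
        return StitchOutcome("unstitched", pair.read_id, pair=pair)

    o = best[1]
    merged_seq = list(s1 + rc2[o:])
    merged_qual = list(q1 + rq2[o:])
    off = n1 - o
    for i in range(o):
        b1, b2 = s1[off + i], rc2[i]
        c1, c2 = q1[off + i], rq2[i]
        if b1 == b2 or c1 >= c2:
            merged_seq[off + i], merged_qual[off + i] = b1, max(c1, c2)
        else:
            merged_seq[off + i], merged_qual[off + i] = b2, c2
    return StitchOutcome(
        "stitched", pair.read_id, merged_seq="".join(merged_seq), merged_qual="".join(merged_qual)
    )


def decide_stitch_mode(pairs: Iterable[RawReadPair], config: PreprocessConfig) -> bool:
    """Probe the heading pairs and enable stitching if more than the
    threshold fraction of them could be stitched (strict inequality)."""
    probe = list(itertools.islice(iter(pairs), config.auto_probe_reads))
    if not probe:
        return False
    stitched = sum(1 for p in probe if stitch_pair(p, config).kind == "stitched")
    return stitched / len(probe) > config.auto_threshold


# ------------------------------------------------------------------ streaming


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        if "r" in mode:
            return gzip.open(path, "rt")
        return deterministic_gzip_writer(path)
    return open(path, mode)


def read_fastq_pairs(fq1: str | Path, fq2: str | Path) -> Iterator[RawReadPair]:
    """Stream synchronized FASTQ mates (gzip transparent).

    Read ids are taken up to the first whitespace; a ``/1`` / ``/2`` mate
    suffix is stripped.
    """
    with _open_text(Path(fq1), "rt") as h1, _open_text(Path(fq2), "rt") as h2:
        while True:
            block1 = [h1.readline() for _ in range(4)]
            block2 = [h2.readline() for _ in range(4)]
            if not block1[0] and not block2[0]:
                return
            if not block1[0] or not block2[0]:
                raise ValueError("FASTQ mate files have different numbers of records")
            id1 = block1[0].split()[0].lstrip("@")
            id2 = block2[0].split()[0].lstrip("@")
            for suffix in ("/1", "/2"):
                id1 = id1.removesuffix(suffix)
                id2 = id2.removesuffix(suffix)
            if id1 != id2:
                raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield RawReadPair(
                id1, block1[1].strip(), block1[3].strip(), block2[1].strip(), block2[3].strip()
            )


@dataclass
class PreprocessResult:
    """Run summary: output paths, per-stage counts and per-read classes."""

    stitched_fq: Path
    unstitched_fq1: Path
    unstitched_fq2: Path
    log_path: Path
    counts: dict[str, int] = field(default_factory=dict)
    read_class: dict[str, str] = field(default_factory=dict)  # read_id -> stitched|unstitched
    stitch_enabled: bool = False


def run_preprocess(
    fastq_pairs: list[tuple[str | Path, str | Path]],
    out_prefix: str | Path,
    config: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Full preprocessing of one or more FASTQ pairs (replicates concatenated
    before duplicate removal), writing stitched single-end fragments and
    surviving pairs to separate FASTQ streams for the aligner."""
    config = config or PreprocessConfig()
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    result = PreprocessResult(
        stitched_fq=prefix.with_name(prefix.name + "_stitched.fq.gz"),
        unstitched_fq1=prefix.with_name(prefix.name + "_un_R1.fq.gz"),
        unstitched_fq2=prefix.with_name(prefix.name + "_un_R2.fq.gz"),
        log_path=prefix.with_name(prefix.name + "_preprocess.json"),
    )
    counts = {
        "input": 0,
        "dropped_too_short": 0,
        "dropped_duplicate": 0,
        "stitched": 0,
        "unstitched": 0,
    }

    raw = itertools.chain.from_iterable(read_fastq_pairs(a, b) for a, b in fastq_pairs)

    def trimmed() -> Iterator[RawReadPair]:
        for pair in raw:
            counts["input"] += 1
            out = trim_read_pair(pair, config)
            if isinstance(out, StitchOutcome):
                counts["dropped_too_short"] += 1
            else:
                yield out

    def deduped() -> Iterator[RawReadPair]:
        for out in dedup_stream(trimmed(), config):
            if isinstance(out, StitchOutcome):
                counts["dropped_duplicate"] += 1
            else:
                yield out

    stream = deduped()
    if config.stitch_mode == "auto":
        probe = list(itertools.islice(stream, config.auto_probe_reads))
        do_stitch = decide_stitch_mode(probe, config)
        stream = itertools.chain(probe, stream)
    else:
        do_stitch = config.stitch_mode == "on"
    result.stitch_enabled = do_stitch

    with _open_text(result.stitched_fq, "wb") as fs, _open_text(
        result.unstitched_fq1, "wb"
    ) as f1, _open_text(result.unstitched_fq2, "wb") as f2:
        for pair in stream:
            outcome = stitch_pair(pair, config) if do_stitch else None
            if outcome is not None and outcome.kind == "stitched":
                counts["stitched"] += 1
                result.read_class[pair.read_id] = "stitched"
                fs.write(
                    f"@{pair.read_id}\n{outcome.merged_seq}\n+\n{outcome.merged_qual}\n".encode()
                )
            else:
                counts["unstitched"] += 1
                result.read_class[pair.read_id] = "unstitched"
                f1.write(f"@{pair.read_id}\n{pair.seq1}\n+\n{pair.qual1}\n".encode())
                f2.write(f"@{pair.read_id}\n{pair.seq2}\n+\n{pair.qual2}\n".encode())

    counts["kept"] = counts["stitched"] + counts["unstitched"]
    result.counts = counts
    with open(result.log_path, "w") as log:
        json.dump(
            {
                "counts": counts,
                "stitch_enabled": do_stitch,
                "read_class": result.read_class,
            },
            log,
            indent=0,
            sort_keys=True,
        )
    return result
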