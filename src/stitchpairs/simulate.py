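"""Proximity-ligation read simulator with ligation-junction truth records.

Emulates sim3C-style Hi-C / Micro-C paired-end reads: chimeric inserts are
built by joining sequence running *into* one enzymatic cut site with sequence
running *out of* a second cut site, so the ligation junction sits between the
two arms.  Every emitted read pair carries a truth record with the two
ligation coordinates, which downstream accuracy scoring joins on read id.

Two digestion modes are supported:

* ``restriction`` — fragmentation at occurrences of a restriction motif
  (default ``GATC``, MboI); sampled loci are snapped to the nearest cut site.
* ``mnase`` — Micro-C-style MNase fragmentation, where any genomic position
  is a legal breakpoint and no snapping occurs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from ._util import deterministic_gzip_writer
from .genome import Genome, revcomp

MIN_ARM = 20  # minimum bases on each side of a ligation junction
PHRED_OFFSET = 33


@dataclass
class SimConfig:
    """Knobs of the generative model.

    Defaults reflect a typical short-insert Hi-C library sequenced in
    paired-end 150 bp mode with MboI digestion: 300 bp mean insert so that a
    substantial fraction of molecules is shorter than twice the read length
    and therefore stitchable.
    """

    mode: str = "restriction"  # or "mnase"
    enzyme_site: str = "GATC"
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    n_pairs: int = 10_000
    junction_fraction: float = 0.8
    trans_fraction: float = 0.1
    cis_decay_exponent: float = 1.0
    cis_distance_range: tuple[int, int] = (1_000, 10_000_000)
    error_rate: float = 0.001
    base_quality: int = 30
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("restriction", "mnase"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("junction_fraction", "trans_fraction", "error_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.insert_mean <= 0 or self.read_length <= 0:
            raise ValueError("insert_mean and read_length must be positive")
        lo, hi = self.cis_distance_range
        if lo >= hi:
            raise ValueError("cis_distance_range min must be < max")
        if self.mode == "restriction":
            if not self.enzyme_site:
                raise ValueError("restriction mode needs a non-empty enzyme site")
            if set(self.enzyme_site) - set("ACGT"):
                raise ValueError(f"enzyme site {self.enzyme_site!r} contains non-ACGT characters")

    @property
    def insert_ceiling(self) -> int:
        """Largest insert the model will draw (truncation of the normal)."""
        return 2 * self.read_length + 400

    @property
    def insert_floor(self) -> int:
        return 2 * MIN_ARM


@dataclass
class TruthRecord:
    """Simulated ligation loci for one read pair (1-based coordinates)."""

    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    is_chimeric: bool


@dataclass
class SimReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


# --------------------------------------------------------------------- digest


def digest_reference(genome: Genome, config: SimConfig) -> dict[str, np.ndarray] | None:
    """Locate all cut sites per chromosome (1-based occurrence starts).

    Positions 1 and L+1 are included as virtual terminal cuts so every base
    lies between two cuts.  The motif is searched on the forward strand only
    (palindromic sites like MboI's GATC are their own reverse complement).

    In ``mnase`` mode there is no site list — any position is a legal cut —
    and ``None`` is returned to express that contract.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    if config.mode == "mnase":
        return None
    site = config.enzyme_site
    cuts: dict[str, np.ndarray] = {}
    for name, seq in genome:
        positions = [1]
        start = seq.find(site)
        while start != -1:
            positions.append(start + 1)  # 1-based
            start = seq.find(site, start + 1)
        positions.append(len(seq) + 1)
        cuts[name] = np.unique(np.asarray(positions, dtype=np.int64))
    return cuts


def _snap_to_cut(pos: int, cuts: np.ndarray) -> int:
    """Nearest cut site; ties broken toward the lower coordinate."""
    i = int(np.searchsorted(cuts, pos))
    if i == 0:
        return int(cuts[0])
    if i == len(cuts):
        return int(cuts[-1])
    lo, hi = int(cuts[i - 1]), int(cuts[i])
    return lo if pos - lo <= hi - pos else hi


# ------------------------------------------------------------------ simulator


class _Sampler:
    """Stateful locus/insert sampling shared by all molecules of one run."""

    def __init__(self, genome: Genome, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        usable = [(n, s) for n, s in genome if len(s) >= config.insert_ceiling]
        if not usable:
            raise ValueError(
                f"no chromosome reaches the insert ceiling of {config.insert_ceiling} bp"
            )
        self.genome = Genome(usable)
        self.names = self.genome.names
        self.lengths = np.array([len(s) for _, s in self.genome], dtype=np.int64)
        self.weights = self.lengths / self.lengths.sum()
        self.cuts = digest_reference(self.genome, config)

    def draw_insert_length(self) -> int:
        cfg = self.cfg
        while True:
            l = int(round(self.rng.normal(cfg.insert_mean, cfg.insert_sd)))
            if cfg.insert_floor <= l <= cfg.insert_ceiling:
                return l

    def pick_chrom(self, exclude: str | None = None) -> str:
        if exclude is None:
            i = self.rng.choice(len(self.names), p=self.weights)
            return self.names[int(i)]
        others = [n for n in self.names if n != exclude]
        if not others:  # single-chromosome genome: trans impossible, stay cis
            return exclude
        return others[int(self.rng.integers(len(others)))]

    def uniform_pos(self, chrom: str) -> int:
        return int(self.rng.integers(1, self.genome.length(chrom) + 1))

    def cut_near(self, chrom: str, pos: int) -> int:
        if self.cuts is None:  # mnase: every position is a cut
            return pos
        return _snap_to_cut(pos, self.cuts[chrom])

    def cis_partner(self, chrom: str, pos: int) -> int:
        """Distance from a truncated power-law density ∝ d^-a, random sign."""
        cfg = self.cfg
        lo, hi = cfg.cis_distance_range
        hi = min(hi, self.genome.length(chrom) - 1)
        lo = min(lo, hi - 1) if hi > 1 else 1
        a = cfg.cis_decay_exponent
        for _ in range(64):
            u = self.rng.random()
            if abs(a - 1.0) < 1e-9:
                d = lo * (hi / lo) ** u
            else:  # inverse CDF of d^-a on [lo, hi]
                d = (lo ** (1 - a) + u * (hi ** (1 - a) - lo ** (1 - a))) ** (1 / (1 - a))
            d = max(1, int(round(d)))
            cand = pos + d if self.rng.random() < 0.5 else pos - d
            if 1 <= cand <= self.genome.length(chrom):
                return cand
        # pathological corner (tiny chromosome): reflect into range
        return min(max(pos + lo, 1), self.genome.length(chrom))

    # -- sequence assembly ------------------------------------------------

    def arm_into_cut(self, chrom: str, cut: int, length: int, fwd: bool) -> str | None:
        """Sequence of `length` bases ending at the cut (read toward it)."""
        seq = self.genome.sequence(chrom)
        if fwd:
            if cut - length < 1:
                return None
            return seq[cut - 1 - length : cut - 1]
        if cut + length - 1 > len(seq):
            return None
        return revcomp(seq[cut - 1 : cut - 1 + length])

    def arm_out_of_cut(self, chrom: str, cut: int, length: int, fwd: bool) -> str | None:
        """Sequence of `length` bases starting at the cut (read away from it)."""
        seq = self.genome.sequence(chrom)
        if fwd:
            if cut + length - 1 > len(seq):
                return None
            return seq[cut - 1 : cut - 1 + length]
        if cut - length < 1:
            return None
        return revcomp(seq[cut - 1 - length : cut - 1])


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def simulate_read_pairs(
    genome: Genome, config: SimConfig
) -> Iterator[tuple[SimReadPair, TruthRecord]]:
    """Yield (read pair, truth) for each molecule, duplicates included.

    Chimeric molecules join an arm running into cut A with an arm running out
    of cut B; non-chimeric molecules are plain genomic fragments starting at a
    cut site, with both fragment ends recorded as truth.  Reads are the first
    ``read_length`` bases from each end of the insert (read 2 on the reverse
    strand), with independent per-base substitution errors.
    """
    sampler = _Sampler(genome, config)
    rng = sampler.rng
    cfg = config
    qual_char = chr(PHRED_OFFSET + cfg.base_quality)

    for idx in range(cfg.n_pairs):
        insert, truth = _make_molecule(sampler, rng, cfg, idx)
        n = min(cfg.read_length, len(insert))
        seq1 = _apply_errors(insert[:n], cfg.error_rate, rng)
        seq2 = _apply_errors(revcomp(insert)[:n], cfg.error_rate, rng)
        pair = SimReadPair(truth.read_id, seq1, qual_char * n, seq2, qual_char * n)
        yield pair, truth
        if cfg.duplicate_fraction > 0.0 and rng.random() < cfg.duplicate_fraction:
            dup_id = truth.read_id + "d"
            dup_truth = TruthRecord(
                dup_id, truth.chrom1, truth.pos1, truth.chrom2, truth.pos2, truth.is_chimeric
            )
            yield SimReadPair(dup_id, seq1, qual_char * n, seq2, qual_char * n), dup_truth


def _make_molecule(
    sampler: _Sampler, rng: np.random.Generator, cfg: SimConfig, idx: int
) -> tuple[str, TruthRecord]:
    read_id = f"mol{idx:08d}"
    length = sampler.draw_insert_length()

    if rng.random() < cfg.junction_fraction:
        for _ in range(64):
            chrom_a = sampler.pick_chrom()
            pos_a = sampler.uniform_pos(chrom_a)
            if rng.random() < cfg.trans_fraction and len(sampler.names) > 1:
                chrom_b = sampler.pick_chrom(exclude=chrom_a)
                pos_b = sampler.uniform_pos(chrom_b)
            else:
                chrom_b = chrom_a
                pos_b = sampler.cis_partner(chrom_a, pos_a)
            cut_a = sampler.cut_near(chrom_a, pos_a)
            cut_b = sampler.cut_near(chrom_b, pos_b)
            len_a = int(rng.integers(MIN_ARM, length - MIN_ARM + 1))
            len_b = length - len_a
            fwd_a = bool(rng.random() < 0.5)
            fwd_b = bool(rng.random() < 0.5)
            arm_a = sampler.arm_into_cut(chrom_a, cut_a, len_a, fwd_a) or sampler.arm_into_cut(
                chrom_a, cut_a, len_a, not fwd_a
            )
            arm_b = sampler.arm_out_of_cut(chrom_b, cut_b, len_b, fwd_b) or sampler.arm_out_of_cut(
                chrom_b, cut_b, len_b, not fwd_b
            )
            if arm_a is None or arm_b is None:
                continue  # both orientations fall off the chromosome end
            return arm_a + arm_b, TruthRecord(read_id, chrom_a, cut_a, chrom_b, cut_b, True)
        raise RuntimeError("failed to place a chimeric molecule after 64 attempts")

    # plain (non-chimeric) fragment anchored at a cut site
    for _ in range(64):
        chrom = sampler.pick_chrom()
        seq = sampler.genome.sequence(chrom)
        if sampler.cuts is None:
            start = int(rng.integers(1, len(seq) - length + 2))
        else:
            cuts = sampler.cuts[chrom]
            start = int(cuts[int(rng.integers(len(cuts)))])
        end = start + length - 1
        if end <= len(seq):
            insert = seq[start - 1 : end]
            return insert, TruthRecord(read_id, chrom, start, chrom, end, False)
    raise RuntimeError("failed to place a genomic fragment after 64 attempts")


# ----------------------------------------------------------------- file output


TRUTH_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "is_chimeric"]


def _gzip_writer(path: Path):
    return deterministic_gzip_writer(path)


def simulate_dataset(genome: Genome, config: SimConfig, out_prefix: str | Path) -> dict[str, Path]:
    """Run the simulator and write FASTQ pair, truth table and chrom sizes.

    Returns the paths written: ``fq1``, ``fq2`` (gzip FASTQ with identical,
    suffix-free read ids), ``truth`` (TSV) and ``chrom_sizes`` (TSV).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fq1": prefix.with_name(prefix.name + "_R1.fq.gz"),
        "fq2": prefix.with_name(prefix.name + "_R2.fq.gz"),
        "truth": prefix.with_name(prefix.name + "_truth.tsv"),
        "chrom_sizes": prefix.with_name(prefix.name + ".chrom.sizes"),
    }
    with _gzip_writer(paths["fq1"]) as f1, _gzip_writer(paths["fq2"]) as f2, open(
        paths["truth"], "w"
    ) as ft:
        ft.write("\t".join(TRUTH_COLUMNS) + "\n")
        for pair, truth in simulate_read_pairs(genome, config):
            f1.write(f"@{pair.read_id}\n{pair.seq1}\n+\n{pair.qual1}\n".encode("ascii"))
            f2.write(f"@{pair.read_id}\n{pair.seq2}\n+\n{pair.qual2}\n".encode("ascii"))
            ft.write(
                f"{truth.read_id}\t{truth.chrom1}\t{truth.pos1}\t{truth.chrom2}\t{truth.pos2}\t"
                f"{int(truth.is_chimeric)}\n"
            )
    genome.write_chrom_sizes(paths["chrom_sizes"])
    return paths


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    """Load a truth TSV into a read-id keyed dict."""
    out: dict[str, TruthRecord] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth header: {header}")
        for line in handle:
            rid, c1, p1, c2, p2, chim = line.rstrip("\n").split("\t")
            out[rid] = TruthRecord(rid, c1, int(p1), c2, int(p2), bool(int(chim)))
    return out
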