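"""4DN pairs-format reader/writer and the chromosome-order authority.

Output follows the pairs text standard v1.0: a ``## pairs format v1.0``
header, one ``#chromsize:`` line per chromosome in genome order, a
``#columns:`` declaration, then tab-separated body rows sorted by
(chrom1, chrom2, pos1, pos2) under the chrom-sizes file order (which matches
aligner-index order, not lexicographic).  Sorting is an external merge over
bounded-size runs so memory stays flat for arbitrarily large pair streams.
"""

from __future__ import annotations

import heapq
import itertools
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from ._util import open_text
from .pair_extract import ContactPair

PAIRS_VERSION_LINE = "## pairs format v1.0"
COLUMNS = ["readID", "chr1", "pos1", "chr2", "pos2", "strand1", "strand2", "category"]
# the first 7 columns are the 4DN core; `category` is this pipeline's extra


class ChromOrder:
    """Ordered (name, length) table with dense rank lookup."""

    def __init__(self, sizes: Iterable[tuple[str, int]]):
        self.sizes = list(sizes)
        names = [n for n, _ in self.sizes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in chrom-sizes table")
        self._rank = {n: i for i, n in enumerate(names)}

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromOrder":
        sizes = []
        with open(path) as handle:
            for line in handle:
                if not line.strip():
                    continue
                name, length = line.split()[:2]
                sizes.append((name, int(length)))
        return cls(sizes)

    @classmethod
    def from_genome(cls, genome) -> "ChromOrder":
        return cls(genome.chrom_sizes())

    def rank(self, name: str) -> int:
        try:
            return self._rank[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in chrom-sizes table") from None

    def __contains__(self, name: str) -> bool:
        return name in self._rank

    def __len__(self) -> int:
        return len(self.sizes)


def _open(path: Path, mode: str):
    return open_text(path, mode)


def _pair_key(pair: ContactPair, order: ChromOrder) -> tuple[int, int, int, int]:
    return (order.rank(pair.chrom1), order.rank(pair.chrom2), pair.pos1, pair.pos2)


def _format_row(pair: ContactPair) -> str:
    return (
        f"{pair.read_id}\t{pair.chrom1}\t{pair.pos1}\t{pair.chrom2}\t{pair.pos2}\t"
        f"{pair.strand1}\t{pair.strand2}\t{pair.category}\n"
    )


def write_pairs(
    pairs: Iterable[ContactPair],
    order: ChromOrder,
    path: str | Path,
    chunk_size: int = 500_000,
) -> Path:
    """Write a sorted, header-complete pairs file (gzip when path ends .gz).

    Rows are accumulated in bounded chunks, each sorted in memory and
    spilled to a temporary run file; runs are then k-way merged.  Unknown
    chromosomes raise, naming the offending read.
    """
    path = Path(path)
    runs: list[Path] = []
    chunk: list[tuple[tuple[int, int, int, int], str]] = []

    with tempfile.TemporaryDirectory(prefix="pairs_sort_") as tmpdir:

        def spill() -> None:
            chunk.sort(key=lambda kv: kv[0])
            run = Path(tmpdir) / f"run{len(runs)}.tsv"
            with open(run, "w") as out:
                for key, row in chunk:
                    out.write("%d\t%d\t%d\t%d\t%s" % (*key, row))
            runs.append(run)
            chunk.clear()

        for pair in pairs:
            for chrom in (pair.chrom1, pair.chrom2):
                if chrom not in order:
                    raise KeyError(
                        f"read {pair.read_id!r}: chromosome {chrom!r} absent from chrom order"
                    )
            chunk.append((_pair_key(pair, order), _format_row(pair)))
            if len(chunk) >= chunk_size:
                spill()
        if chunk or not runs:
            spill()

        def run_rows(run: Path) -> Iterator[tuple[tuple[int, ...], str]]:
            with open(run) as handle:
                for line in handle:
                    k1, k2, k3, k4, row = line.split("\t", 4)
                    yield (int(k1), int(k2), int(k3), int(k4)), row

        with _open(path, "w") as out:
            out.write(PAIRS_VERSION_LINE + "\n")
            out.write("#sorted: chr1-chr2-pos1-pos2\n")
            for name, length in order.sizes:
                out.write(f"#chromsize: {name} {length}\n")
            out.write("#columns: " + " ".join(COLUMNS) + "\n")
            for _, row in heapq.merge(*(run_rows(r) for r in runs), key=lambda kv: kv[0]):
                out.write(row)
    return path


@dataclass
class PairsHeader:
    version_line: str
    chrom_sizes: list[tuple[str, int]]
    columns: list[str]
    sorted_tag: str | None = None

    def chrom_order(self) -> ChromOrder:
        return ChromOrder(self.chrom_sizes)


def read_pairs(
    path: str | Path, strict: bool = False
) -> tuple[PairsHeader, Iterator[ContactPair]]:
    """Parse a pairs file; returns (header, lazy row iterator).

    Tolerant of extra columns (ignored) and of runs of spaces as the field
    separator; tab is canonical on write.  In strict mode a sortedness claim
    in the header is validated while iterating.
    """
    path = Path(path)
    handle = _open(path, "r")
    version_line = handle.readline().rstrip("\n")
    if not version_line.startswith("## pairs format"):
        handle.close()
        raise ValueError(f"{path}: missing pairs-format version line")
    chrom_sizes: list[tuple[str, int]] = []
    columns: list[str] | None = None
    sorted_tag: str | None = None
    body_first: str | None = None
    for line in handle:
        if line.startswith("#chromsize:"):
            _, name, length = line.split()
            chrom_sizes.append((name, int(length)))
        elif line.startswith("#columns:"):
            columns = line.split()[1:]
        elif line.startswith("#sorted:"):
            sorted_tag = line.split(":", 1)[1].strip()
        elif line.startswith("#"):
            continue
        else:
            body_first = line
            break
    if columns is None:
        handle.close()
        raise ValueError(f"{path}: missing #columns line in header")
    header = PairsHeader(version_line, chrom_sizes, columns, sorted_tag)

    core = ["readID", "chr1", "pos1", "chr2", "pos2", "strand1", "strand2"]
    idx = {}
    for name in core:
        if name not in columns:
            handle.close()
            raise ValueError(f"{path}: column {name!r} missing from #columns")
        idx[name] = columns.index(name)
    cat_idx = columns.index("category") if "category" in columns else None

    def rows() -> Iterator[ContactPair]:
        with handle:
            body = [body_first] if body_first is not None else []
            for lineno, line in enumerate(itertools.chain(body, handle), start=1):
                yield from _parse_row(line, lineno, idx, cat_idx, path)

    def checked_rows() -> Iterator[ContactPair]:
        order = header.chrom_order()
        last_key = None
        for pair in rows():
            key = _pair_key(pair, order)
            if last_key is not None and key < last_key:
                raise ValueError(f"{path}: body violates declared sort order at {pair.read_id}")
            last_key = key
            yield pair

    if strict and sorted_tag and chrom_sizes:
        return header, checked_rows()
    return header, rows()


def _parse_row(line, lineno, idx, cat_idx, path):
    line = line.rstrip("\n")
    if not line:
        return
    fields = line.split("\t")
    if len(fields) < len(idx):
        fields = line.split()
    if len(fields) < max(idx.values()) + 1:
        raise ValueError(f"{path}: line {lineno}: too few columns")
    try:
        pos1 = int(fields[idx["pos1"]])
        pos2 = int(fields[idx["pos2"]])
    except ValueError:
        raise ValueError(f"{path}: line {lineno}: non-integer position") from None
    yield ContactPair(
        read_id=fields[idx["readID"]],
        chrom1=fields[idx["chr1"]],
        pos1=pos1,
        strand1=fields[idx["strand1"]],
        chrom2=fields[idx["chr2"]],
        pos2=pos2,
        strand2=fields[idx["strand2"]],
        category=fields[cat_idx] if cat_idx is not None and cat_idx < len(fields) else "",
    )


def write_juicer_short(
    pairs: Iterable[ContactPair], path: str | Path
) -> Path:
    """Juicer "short format" writer for external .hic converters.

    Columns: str1 chr1 pos1 frag1 str2 chr2 pos2 frag2, with strands encoded
    0 (+) / 16 (-) and dummy fragment fields 0 and 1.
    """
    path = Path(path)
    with _open(path, "w") as out:
        for p in pairs:
            s1 = 0 if p.strand1 == "+" else 16
            s2 = 0 if p.strand2 == "+" else 16
            out.write(f"{s1}\t{p.chrom1}\t{p.pos1}\t0\t{s2}\t{p.chrom2}\t{p.pos2}\t1\n")
    return path
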