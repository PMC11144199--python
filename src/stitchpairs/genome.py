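"""Reference genome container and FASTA / chrom-sizes I/O.

The genome is an ordered list of chromosomes; the order is authoritative and
defines the genome-wide chromosome ranking used for upper-triangle pair
ordering downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

_VALID = set("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return str(Seq(seq).reverse_complement())


@dataclass
class Genome:
    """Ordered collection of named chromosome sequences (uppercase A/C/G/T)."""

    chroms: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    def sequence(self, name: str) -> str:
        for n, s in self.chroms:
            if n == name:
                return s
        raise KeyError(name)

    def length(self, name: str) -> int:
        return len(self.sequence(name))

    def chrom_sizes(self) -> list[tuple[str, int]]:
        return [(n, len(s)) for n, s in self.chroms]

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.chroms)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        """Load a (possibly gzipped, wrapped or unwrapped) multi-FASTA."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            chroms = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
        if not chroms:
            raise ValueError(f"no sequences found in {path}")
        return cls(chroms)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as out:
            for name, seq in self.chroms:
                out.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for name, size in self.chrom_sizes():
                out.write(f"{name}\t{size}\n")

    # ------------------------------------------------------------ generation

    @classmethod
    def random(cls, sizes: dict[str, int] | list[tuple[str, int]], seed: int) -> "Genome":
        """Uniform-random genome, e.g. for simulation studies.

        Random sequence is essentially repeat-free, so alignments are
        near-uniquely mappable — the regime in which mapping accuracy can be
        scored against simulated truth.
        """
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        rng = np.random.default_rng(seed)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        chroms = []
        for name, size in items:
            arr = bases[rng.integers(0, 4, size=size)]
            chroms.append((name, arr.tobytes().decode("ascii")))
        return cls(chroms)
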