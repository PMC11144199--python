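"""Shared fixtures: small synthetic genomes, simulated datasets, SAM builders."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from stitchpairs.genome import Genome
from stitchpairs.sam_ingest import AlnRecord
from stitchpairs.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """200 kb two-chromosome random genome for unit-scale simulations."""
    return Genome.random({"chrA": 120_000, "chrB": 80_000}, seed=7)


@pytest.fixture(scope="session")
def sim_genome() -> Genome:
    """3 Mb three-chromosome random genome for end-to-end runs."""
    return Genome.random({"chr1": 1_500_000, "chr2": 1_000_000, "chr3": 500_000}, seed=11)


@pytest.fixture(scope="session")
def sim_genome_dir(tmp_path_factory, sim_genome) -> Path:
    d = tmp_path_factory.mktemp("ref")
    sim_genome.to_fasta(d / "ref.fa")
    sim_genome.write_chrom_sizes(d / "ref.chrom.sizes")
    return d


@pytest.fixture(scope="session")
def e2e_dataset(tmp_path_factory, sim_genome) -> dict:
    """50 000 simulated PE150 read pairs (MboI mode, 300 bp mean insert)."""
    d = tmp_path_factory.mktemp("sim")
    config = SimConfig(n_pairs=50_000, error_rate=0.001, seed=20260927)
    paths = simulate_dataset(sim_genome, config, d / "sim")
    paths["config"] = config
    return paths


def make_aln(
    read_id="r1",
    source="stitched",
    chrom="chrA",
    ref_start=1_000,
    ref_end=1_149,
    strand="+",
    mapq=60,
    query_start=1,
    query_end=150,
    read_length=150,
    is_supplementary=False,
) -> AlnRecord:
    return AlnRecord(
        read_id=read_id, source=source, chrom=chrom, ref_start=ref_start, ref_end=ref_end,
        strand=strand, mapq=mapq, query_start=query_start, query_end=query_end,
        clipped_bases=read_length - (query_end - query_start + 1),
        read_length=read_length, is_supplementary=is_supplementary,
    )


def make_sam(records: list[dict], chrom_sizes: list[tuple[str, int]], path: Path) -> Path:
    """Write a minimal SAM text file from field dicts."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in chrom_sizes:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.get("qname", "r1"),
                    str(r.get("flag", 0)),
                    r.get("rname", "chrA"),
                    str(r.get("pos", 1)),
                    str(r.get("mapq", 60)),
                    r.get("cigar", "150M"),
                    "*", "0", "0",
                    r.get("seq", "*"),
                    r.get("qual", "*"),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
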