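"""External-aligner invocation (alignment itself is out of scope).

Any SAM-emitting local aligner honoring the split-read contract (split
alignments as supplementary records, no mate rescue, name-grouped output)
can be plugged in through a command template.  The default template drives
BWA-MEM: ``-S -P`` disable mate pairing/rescue so mates align independently,
``-5`` selects the 5'-most part of a split read as primary.  The seed and
score thresholds are lowered so that short ligation arms (down to the
simulator's 20 bp minimum) are still reported as split segments.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
from pathlib import Path

BWA_SE_TEMPLATE = "bwa mem -t {threads} -k 13 -T 15 -5 {index} {fq}"
BWA_PE_TEMPLATE = "bwa mem -t {threads} -k 13 -T 15 -S -P -5 {index} {fq1} {fq2}"


class AlignerError(RuntimeError):
    pass


def have_bwa() -> bool:
    return shutil.which("bwa") is not None


def bwa_index(fasta: str | Path) -> Path:
    """Build the BWA index next to the FASTA if not already present."""
    fasta = Path(fasta)
    if not (fasta.parent / (fasta.name + ".bwt")).exists():
        _run(["bwa", "index", str(fasta)])
    return fasta


def _run(cmd: list[str], stdout=None) -> None:
    proc = subprocess.run(cmd, stdout=stdout, stderr=subprocess.PIPE)
    if proc.returncode != 0:
        raise AlignerError(
            f"command {' '.join(cmd)!r} failed:\n{proc.stderr.decode(errors='replace')[-2000:]}"
        )


def align_single(
    index: str | Path, fq: str | Path, out_sam: str | Path,
    template: str = BWA_SE_TEMPLATE, threads: int = 1,
) -> Path:
    """Align stitched single-end fragments, writing SAM text."""
    cmd = shlex.split(template.format(index=index, fq=fq, threads=threads))
    with open(out_sam, "wb") as out:
        _run(cmd, stdout=out)
    return Path(out_sam)


def align_paired(
    index: str | Path, fq1: str | Path, fq2: str | Path, out_sam: str | Path,
    template: str = BWA_PE_TEMPLATE, threads: int = 1,
) -> Path:
    """Align surviving read pairs (each mate independently), writing SAM."""
    cmd = shlex.split(template.format(index=index, fq1=fq1, fq2=fq2, threads=threads))
    with open(out_sam, "wb") as out:
        _run(cmd, stdout=out)
    return Path(out_sam)
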