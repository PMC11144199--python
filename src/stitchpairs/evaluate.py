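"""Accuracy, concordance and stitch-yield statistics.

Two tolerance rules, both strict inequalities:

* simulation accuracy — a reported pair is *correct* when both ends match
  the simulated ligation coordinates on the same chromosomes with distances
  below 500 bp (the simulator records cut sites, while fragment ends lie
  nearby);
* cross-run concordance — two runs are *consistent* on a read when they
  report the same chromosome pair with end distances below 200 bp (aligners
  clip differently and report slightly different endpoints).

End assignment is tried both ways in each comparison, so column order never
penalizes a correct pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .pair_extract import ContactPair
from .pairs_io import read_pairs
from .simulate import TruthRecord, read_truth

ACCURACY_TOL_BP = 500
CONCORDANCE_TOL_BP = 200


@dataclass
class AccuracyReport:
    n_pairs_reported: int = 0
    n_correct: int = 0
    n_unmatched: int = 0  # read ids absent from the truth table
    n_truth: int = 0
    n_truth_matched: int = 0
    per_category: dict[str, tuple[int, int]] = field(default_factory=dict)  # cat -> (n, correct)

    @property
    def accuracy(self) -> float:
        scored = self.n_pairs_reported - self.n_unmatched
        return self.n_correct / scored if scored else 0.0

    @property
    def recall_like(self) -> float:
        return self.n_truth_matched / self.n_truth if self.n_truth else 0.0

    def as_dict(self) -> dict:
        return {
            "n_pairs_reported": self.n_pairs_reported,
            "n_correct": self.n_correct,
            "n_unmatched": self.n_unmatched,
            "accuracy": self.accuracy,
            "n_truth": self.n_truth,
            "n_truth_matched": self.n_truth_matched,
            "recall_like": self.recall_like,
            "per_category": {
                k: {"n": n, "correct": c} for k, (n, c) in sorted(self.per_category.items())
            },
        }


def _ends_match(
    chrom_a1: str, pos_a1: int, chrom_a2: str, pos_a2: int,
    chrom_b1: str, pos_b1: int, chrom_b2: str, pos_b2: int,
    tol: int,
) -> bool:
    """True when A's ends match B's ends under either end assignment."""

    def direct(c1, p1, c2, p2, d1, q1, d2, q2):
        return c1 == d1 and c2 == d2 and abs(p1 - q1) < tol and abs(p2 - q2) < tol

    return direct(chrom_a1, pos_a1, chrom_a2, pos_a2, chrom_b1, pos_b1, chrom_b2, pos_b2) or \
        direct(chrom_a1, pos_a1, chrom_a2, pos_a2, chrom_b2, pos_b2, chrom_b1, pos_b1)


def pair_matches_truth(pair: ContactPair, truth: TruthRecord, tol: int = ACCURACY_TOL_BP) -> bool:
    return _ends_match(
        pair.chrom1, pair.pos1, pair.chrom2, pair.pos2,
        truth.chrom1, truth.pos1, truth.chrom2, truth.pos2,
        tol,
    )


def accuracy_vs_truth(
    pairs: str | Path | Iterable[ContactPair],
    truth: str | Path | dict[str, TruthRecord],
    tol: int = ACCURACY_TOL_BP,
) -> AccuracyReport:
    """Score reported pairs against the simulator's truth table.

    Pairs whose read id is absent from the truth table are binned separately
    (``n_unmatched``) and excluded from the accuracy denominator.
    """
    if isinstance(pairs, (str, Path)):
        _, pairs = read_pairs(pairs)
    if isinstance(truth, (str, Path)):
        truth = read_truth(truth)
    report = AccuracyReport(n_truth=len(truth))
    matched: set[str] = set()
    for pair in pairs:
        report.n_pairs_reported += 1
        rec = truth.get(pair.read_id)
        if rec is None:
            report.n_unmatched += 1
            continue
        ok = pair_matches_truth(pair, rec, tol)
        n, c = report.per_category.get(pair.category or "", (0, 0))
        report.per_category[pair.category or ""] = (n + 1, c + int(ok))
        if ok:
            report.n_correct += 1
            matched.add(pair.read_id)
    report.n_truth_matched = len(matched)
    return report


@dataclass
class ConcordanceReport:
    n_common_read_ids: int = 0
    n_consistent: int = 0
    n_only_a: int = 0
    n_only_b: int = 0

    @property
    def consistency(self) -> float:
        return self.n_consistent / self.n_common_read_ids if self.n_common_read_ids else 0.0

    def as_dict(self) -> dict:
        return {
            "n_common_read_ids": self.n_common_read_ids,
            "n_consistent": self.n_consistent,
            "consistency": self.consistency,
            "n_only_A": self.n_only_a,
            "n_only_B": self.n_only_b,
        }


def concordance(
    pairs_a: str | Path | Iterable[ContactPair],
    pairs_b: str | Path | Iterable[ContactPair],
    tol: int = CONCORDANCE_TOL_BP,
) -> ConcordanceReport:
    """Agreement between two pairs files, joined on read id.

    A duplicated read id within one file keeps its first occurrence.
    """

    def load(pairs) -> dict[str, ContactPair]:
        if isinstance(pairs, (str, Path)):
            _, pairs = read_pairs(pairs)
        out: dict[str, ContactPair] = {}
        for p in pairs:
            out.setdefault(p.read_id, p)
        return out

    a, b = load(pairs_a), load(pairs_b)
    report = ConcordanceReport(
        n_only_a=len(a.keys() - b.keys()), n_only_b=len(b.keys() - a.keys())
    )
    for rid in a.keys() & b.keys():
        report.n_common_read_ids += 1
        pa, pb = a[rid], b[rid]
        if _ends_match(
            pa.chrom1, pa.pos1, pa.chrom2, pa.pos2,
            pb.chrom1, pb.pos1, pb.chrom2, pb.pos2,
            tol,
        ):
            report.n_consistent += 1
    return report


@dataclass
class StitchYieldReport:
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    stitched_fraction: float = 0.0

    def as_dict(self) -> dict:
        return {"per_class": self.per_class, "stitched_fraction": self.stitched_fraction}


def stitch_yield(
    pairs: str | Path | Iterable[ContactPair],
    read_class: dict[str, str],
) -> StitchYieldReport:
    """Pairs yield for stitched vs unstitched reads.

    ``read_class`` is the preprocessing log's read-id → stitched/unstitched
    map; reported pairs with ids absent from the log are excluded.
    """
    if isinstance(pairs, (str, Path)):
        _, pairs = read_pairs(pairs)
    n_input = {"stitched": 0, "unstitched": 0}
    for cls in read_class.values():
        if cls in n_input:
            n_input[cls] += 1
    n_pairs = {"stitched": 0, "unstitched": 0}
    for p in pairs:
        cls = read_class.get(p.read_id)
        if cls in n_pairs:
            n_pairs[cls] += 1
    report = StitchYieldReport()
    for cls in ("stitched", "unstitched"):
        if n_input[cls] == 0:
            continue
        report.per_class[cls] = {
            "n_input": n_input[cls],
            "n_pairs": n_pairs[cls],
            "yield": n_pairs[cls] / n_input[cls],
        }
    total = n_input["stitched"] + n_input["unstitched"]
    report.stitched_fraction = n_input["stitched"] / total if total else 0.0
    return report
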