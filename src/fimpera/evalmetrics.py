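"""Evaluation of index answers against exact ground truth.

Every queried k-mer is classified against an exact oracle (the counted
k-mer table and the exact s-abundance map derived from it):

* TN — truly absent, reported absent;
* FP_construction — truly absent but every constituent s-mer has a true
  s-abundance > 0: the s-mer decomposition itself manufactures the hit,
  independently of the underlying filter;
* FP_collision — truly absent, reported present through filter collisions;
* TP_correct — present, reported at exactly the discretized truth;
* TP_overestimated_construction — present but the minimum true s-abundance
  over its window already exceeds its own abundance (neighboring, more
  abundant k-mers inflate every s-mer), a filter-independent error;
* TP_overestimated_collision — present, overestimated only through filter
  collisions.

Underestimation cannot happen by construction; observing one raises.
Summaries report the false positive rate #FP/(#FP+#TN), the share of true
positives with an incorrect abundance, the construction shares of both
error kinds, the mean error distance in rank units, and the overestimation
score (sum of squared rank errors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import sequence_io as sio
from .core import DiscretizationSpec, FimperaConfig, compute_sab

LABELS = (
    "TN",
    "TP_correct",
    "TP_overestimated_construction",
    "TP_overestimated_collision",
    "FP_construction",
    "FP_collision",
)


@dataclass
class GroundTruth:
    """Exact k-mer -> count and s-mer -> s_ab oracles plus the config in force."""

    kmer_counts: dict[str, int]
    sab: dict[str, int]
    config: FimperaConfig

    @classmethod
    def from_table(
        cls, table: sio.CountedKmerTable, config: FimperaConfig
    ) -> "GroundTruth":
        counts: dict[str, int] = {}
        for kmer, count in table:
            key = sio.canonical(kmer) if config.canonical else kmer
            counts[key] = max(counts.get(key, 0), count)
        sab = compute_sab(table, config.s, config.canonical)
        return cls(kmer_counts=counts, sab=sab, config=config)

    def _key(self, word: str) -> Optional[str]:
        word = word.upper()
        if any(c not in "ACGT" for c in word):
            return None  # non-ACGT k-mers are absent by definition
        return sio.canonical(word) if self.config.canonical else word

    def count(self, kmer: str) -> int:
        key = self._key(kmer)
        return 0 if key is None else self.kmer_counts.get(key, 0)

    def expected_response(self, kmer: str) -> int:
        """The exact answer in the report's shifted encoding (0 = absent)."""
        c = self.count(kmer)
        if c == 0:
            return 0
        spec = self.config.spec()
        return min(spec.discretize(c) + 1, spec.cap)

    def min_window_sab(self, kmer: str) -> int:
        """Minimum true s-abundance over the k-mer's z+1 s-mers (0 if any absent)."""
        key = self._key(kmer)
        if key is None:
            return 0
        s = self.config.s
        best: Optional[int] = None
        for i in range(len(kmer) - s + 1):
            smer = kmer.upper()[i : i + s]
            if self.config.canonical:
                smer = sio.canonical(smer)
            v = self.sab.get(smer, 0)
            if best is None or v < best:
                best = v
            if best == 0:
                return 0
        return best or 0

    def oracle_response(self, kmer: str) -> int:
        """What a collision-free filter would report (shifted encoding)."""
        m = self.min_window_sab(kmer)
        if m == 0:
            return 0
        spec = self.config.spec()
        return min(spec.discretize(m) + 1, spec.cap)


@dataclass
class CallClassification:
    """Per-call truth/response/label table (one row per queried k-mer)."""

    table: pd.DataFrame  # columns: kmer, truth, expected, oracle, reported, label

    def label_counts(self) -> dict[str, int]:
        counts = self.table["label"].value_counts().to_dict()
        return {lbl: int(counts.get(lbl, 0)) for lbl in LABELS}


@dataclass
class EvalSummary:
    n_calls: int
    fpr: Optional[float]
    incorrect_abundance_rate: Optional[float]
    construction_fp_share: Optional[float]
    construction_overest_share: Optional[float]
    mean_error_distance: Optional[float]
    overestimation_score: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def classify_calls(
    kmers: Sequence[str], reported: Iterable[int], truth: GroundTruth
) -> CallClassification:
    """Label every (queried k-mer, reported response) against the oracle.

    ``reported`` uses the shifted encoding the index emits. Construction
    versus collision is decided with the exact s-abundance oracle,
    independent of the filter: a mixed error (both construction and
    collision present) counts as construction, matching the
    filter-independent definition.
    """
    reported = np.asarray(list(reported), dtype=np.int64)
    if len(kmers) != reported.size:
        raise ValueError("kmers and reported responses differ in length")
    rows = []
    for kmer, rep in zip(kmers, reported.tolist()):
        t = truth.count(kmer)
        expected = truth.expected_response(kmer)
        oracle = truth.oracle_response(kmer)
        if t == 0:
            if rep == 0:
                label = "TN"
            elif oracle > 0:
                label = "FP_construction"
            else:
                label = "FP_collision"
        else:
            if rep < expected:
                raise ValueError(
                    f"underestimated call for {kmer!r}: reported {rep} < "
                    f"expected {expected} — the no-underestimation contract is broken"
                )
            if rep == expected:
                label = "TP_correct"
            elif oracle > expected:
                label = "TP_overestimated_construction"
            else:
                label = "TP_overestimated_collision"
        rows.append((kmer, t, expected, oracle, rep, label))
    df = pd.DataFrame(
        rows, columns=["kmer", "truth", "expected", "oracle", "reported", "label"]
    )
    return CallClassification(table=df)


def summarize(classification: CallClassification) -> EvalSummary:
    """Aggregate a classification into the headline rates.

    Rates with an empty denominator are reported as None (undefined), not
    0. The incorrect-abundance rate is computed over true positive calls
    only; the overestimation score sums squared rank errors over all calls.
    """
    df = classification.table
    if len(df) == 0:
        raise ValueError("cannot summarize an empty classification")
    lbl = df["label"]
    n_fp = int(lbl.str.startswith("FP").sum())
    n_tn = int((lbl == "TN").sum())
    n_tp = int(lbl.str.startswith("TP").sum())
    n_tp_wrong = int(lbl.str.startswith("TP_overestimated").sum())
    n_fp_constr = int((lbl == "FP_construction").sum())
    n_overest_constr = int((lbl == "TP_overestimated_construction").sum())
    err = df["reported"] - df["expected"]
    tp_err = err[lbl.str.startswith("TP_overestimated")]
    return EvalSummary(
        n_calls=len(df),
        fpr=n_fp / (n_fp + n_tn) if (n_fp + n_tn) else None,
        incorrect_abundance_rate=n_tp_wrong / n_tp if n_tp else None,
        construction_fp_share=n_fp_constr / n_fp if n_fp else None,
        construction_overest_share=(
            n_overest_constr / n_tp_wrong if n_tp_wrong else None
        ),
        mean_error_distance=float(tp_err.mean()) if n_tp_wrong else None,
        overestimation_score=float((err.astype(np.float64) ** 2).sum()),
    )


def overestimation_score(reported: Sequence[float], truth: Sequence[float]) -> float:
    """Sum of squared errors between reported and true values."""
    reported = np.asarray(reported, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if reported.shape != truth.shape:
        raise ValueError("reported and truth differ in shape")
    return float(((reported - truth) ** 2).sum())
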