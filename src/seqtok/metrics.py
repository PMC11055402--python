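"""Evaluation statistics for classification, regression and alignment tasks.

Classification is scored by accuracy, area under the ROC curve, and the
Matthews correlation coefficient

    MCC = (TN*TP - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the generalized multi-category form used for more than two classes
(the binary formula is its K=2 special case).  Regression is scored by the
Spearman rank correlation (Pearson correlation of average-rank vectors).
Pairwise alignments are scored by the column score (fraction of true
columns reproduced) and coverage (fraction of outputs that are valid
alignments); validity requires equal row lengths, no all-gap column, and
each row reducing to its ungapped source.  Tokenizer families are compared
across tasks with an exact two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .corpus import GAP_CHARS


class MetricError(ValueError):
    pass


class UndefinedMetricError(MetricError):
    """A metric is undefined for the given input (e.g. single-class AUC)."""


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    acc: float
    mcc: float
    auc: float | None = None
    spearman_rho: float | None = None

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.mcc <= 1.0 + 1e-12, self.mcc
        assert 0.0 <= self.acc <= 1.0
        if self.auc is not None:
            assert 0.0 - 1e-12 <= self.auc <= 1.0 + 1e-12
        if self.spearman_rho is not None:
            assert -1.0 - 1e-9 <= self.spearman_rho <= 1.0 + 1e-9


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Binary MCC; 0 by convention when any denominator factor is 0."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TN * c.TP - c.FN * c.FP) / math.sqrt(denom)


def mcc_multiclass(labels: Sequence[int], preds: Sequence[int]) -> float:
    """Generalized (multi-category) MCC over the K x K confusion matrix.

    Coincides with :func:`mcc_from_counts` for two classes; 0 when the
    denominator vanishes.
    """
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    classes = np.unique(np.concatenate([labels, preds]))
    idx = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    C = np.zeros((K, K), dtype=np.int64)
    for y, p in zip(labels, preds):
        C[idx[y], idx[p]] += 1
    t = C.sum(axis=1)  # true counts per class
    p = C.sum(axis=0)  # predicted counts per class
    n = C.sum()
    cov_yp = n * np.trace(C) - int(t @ p)
    cov_yy = n * n - int(t @ t)
    cov_pp = n * n - int(p @ p)
    if cov_yy == 0 or cov_pp == 0:
        return 0.0
    return float(cov_yp / math.sqrt(cov_yy) / math.sqrt(cov_pp))


def auc_binary(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC: probability a positive outscores a negative, ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("AUC requires both classes present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def classification_metrics(
    labels: Sequence[int], scores: np.ndarray
) -> MetricReport:
    """ACC, AUC and MCC from per-class score columns.

    ``scores`` has shape (n, K) with one column per class (class order =
    sorted unique labels); predictions are the argmax.  For K=2 the AUC
    uses the positive-class column; for K>2 it is macro-averaged
    one-vs-rest.  MCC uses the multi-category form, which reduces to the
    printed binary formula when K=2.
    """
    labels = np.asarray(labels)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(labels):
        raise MetricError("labels and scores must have equal length")
    classes = np.unique(labels)
    if scores.shape[1] < len(classes):
        raise MetricError("fewer score columns than classes")
    if len(classes) < 2:
        raise UndefinedMetricError("metrics require at least two classes")
    preds = classes[np.argmax(scores[:, : len(classes)], axis=1)]
    acc = float(np.mean(preds == labels))
    mcc = mcc_multiclass([int(x) for x in labels], [int(x) for x in preds])
    if len(classes) == 2:
        auc = auc_binary((labels == classes[1]).astype(int), scores[:, 1])
    else:
        aucs = [
            auc_binary((labels == c).astype(int), scores[:, i])
            for i, c in enumerate(classes)
        ]
        auc = float(np.mean(aucs))
    return MetricReport(acc=acc, mcc=mcc, auc=auc)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise MetricError("vectors must have equal length")
    if len(x) < 2:
        raise UndefinedMetricError("spearman requires length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMetricError("spearman is undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class PairwiseAlignment:
    """Two gapped rows plus their ungapped source sequences."""

    row1: str
    row2: str
    src1: str
    src2: str


@dataclass(frozen=True)
class ValidityVerdict:
    valid: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.valid


def _degap(row: str) -> str:
    for g in GAP_CHARS:
        row = row.replace(g, "")
    return row


def _is_gap(c: str) -> bool:
    return c in GAP_CHARS


def validate_alignment(aln: PairwiseAlignment) -> ValidityVerdict:
    """Check the three validity rules; invalidity is a verdict, not an error.

    Valid iff (a) the two rows have identical length, (b) no column is a
    gap in both rows, and (c) each row with gaps removed equals its source
    sequence.
    """
    if len(aln.row1) != len(aln.row2):
        return ValidityVerdict(False, "unequal row lengths")
    for c1, c2 in zip(aln.row1, aln.row2):
        if _is_gap(c1) and _is_gap(c2):
            return ValidityVerdict(False, "column with gap in both rows")
    if _degap(aln.row1) != aln.src1:
        return ValidityVerdict(False, "row 1 mismatch after gap removal")
    if _degap(aln.row2) != aln.src2:
        return ValidityVerdict(False, "row 2 mismatch after gap removal")
    return ValidityVerdict(True)


def _column_labels(aln: PairwiseAlignment) -> set[tuple]:
    """Position-anchored identity of every column.

    A residue side carries its 0-based source coordinate; a gap side
    carries a gap marker plus the source coordinate of the preceding
    residue (-1 before the first).  This makes identical alignments share
    all labels and is insensitive to column order.
    """
    labels = set()
    i = j = -1
    for c1, c2 in zip(aln.row1, aln.row2):
        if _is_gap(c1):
            side1 = ("gap", i)
        else:
            i += 1
            side1 = ("res", i)
        if _is_gap(c2):
            side2 = ("gap", j)
        else:
            j += 1
            side2 = ("res", j)
        labels.add((side1, side2))
    return labels


def column_score(inferred: PairwiseAlignment, truth: PairwiseAlignment) -> float:
    """Fraction of true-alignment columns present in the inferred alignment."""
    v1, v2 = validate_alignment(inferred), validate_alignment(truth)
    if not v1:
        raise MetricError(f"inferred alignment invalid: {v1.reason}")
    if not v2:
        raise MetricError(f"true alignment invalid: {v2.reason}")
    if (inferred.src1, inferred.src2) != (truth.src1, truth.src2):
        raise MetricError("alignments are over different source pairs")
    truth_labels = _column_labels(truth)
    inferred_labels = _column_labels(inferred)
    return len(inferred_labels & truth_labels) / len(truth.row1)


@dataclass
class AlignmentEvalReport:
    CS: float | None
    VA: int
    TA: int

    @property
    def coverage(self) -> float:
        return self.VA / self.TA

    @property
    def coverage_exact(self) -> Fraction:
        return Fraction(self.VA, self.TA)


def coverage(verdicts: Sequence[ValidityVerdict]) -> AlignmentEvalReport:
    """Coverage = VA / TA: valid alignments over total alignments tested."""
    if len(verdicts) == 0:
        raise MetricError("coverage requires at least one alignment")
    va = sum(1 for v in verdicts if v.valid)
    return AlignmentEvalReport(CS=None, VA=va, TA=len(verdicts))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float
    n_effective: int
    degenerate: bool = False


def _exact_signed_rank_p(ranks: Sequence[float], w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, via subset-sum DP.

    Average ranks for ties may be half-integers; ranks are doubled to keep
    the DP integral.
    """
    d = [int(round(2 * r)) for r in ranks]
    total = sum(d)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in d:
        counts[r:] += counts[: total + 1 - r].copy()
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_compare(
    perf_a: Sequence[float], perf_b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired performance vectors.

    Zero differences are dropped; tied magnitudes receive average ranks;
    the exact null distribution is enumerated for n <= ``exact_max_n``
    (normal approximation with tie correction beyond).  If every
    difference is zero the result is degenerate with p = 1.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if len(a) != len(b):
        raise MetricError("paired vectors must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_effective=0,
                              degenerate=True)
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    n = len(diffs)
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(sps.wilcoxon(a, b, zero_method="wilcox",
                               correction=True, mode="approx").pvalue)
    return WilcoxonResult(p_value=p, statistic=min(w_plus, ranks.sum() - w_plus),
                          n_effective=n)


# ---------------------------------------------------------------------------
# Gapped-FASTA alignment I/O (two records per pair, order = row order)
# ---------------------------------------------------------------------------


def write_alignment_pairs(
    alignments: Sequence[PairwiseAlignment], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        for i, aln in enumerate(alignments):
            fh.write(f">pair{i}_row1\n{aln.row1}\n>pair{i}_row2\n{aln.row2}\n")


def read_alignment_pairs(path: str | Path) -> list[PairwiseAlignment]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    rows: list[str] = []
    with open(path, "rt") as fh:
        for _, seq in SimpleFastaParser(fh):
            rows.append(seq.upper())
    if len(rows) % 2:
        raise MetricError("gapped FASTA must contain an even number of records")
    return [
        PairwiseAlignment(row1=r1, row2=r2, src1=_degap(r1), src2=_degap(r2))
        for r1, r2 in zip(rows[0::2], rows[1::2])
    ]
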