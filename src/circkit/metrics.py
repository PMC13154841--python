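"""Benchmark metrics for predicted circles against simulated ground truth.

True positives are truth circles recovered by a prediction under the
endpoint threshold (default 20 bp); matching is one-to-one and greedy by
endpoint offset, so duplicated predictions cannot claim the same truth
circle twice and inflate precision. From TP/FP/FN the usual
precision = TP/(TP+FP), recall = TP/(TP+FN) and
F = 2PR/(P+R) are reported.

Two further diagnostics follow the same matching:

* ``offset_ratio`` — of the truth circles recovered at the full threshold,
  the fraction recovered with both junction coordinates within 1 bp; a
  coordinate-precision measure (1.0 = every match is near-exact).
* ``length_ks`` — two-sample Kolmogorov–Smirnov comparison of predicted vs
  true length distributions, restricted to a length range of interest.

``contingency_chi2_yates`` is the 2x2 chi-square with Yates continuity
correction used for comparing detection-consistency proportions between
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import Circle, DEFAULT_MATCH_THRESHOLD, circles_match


@dataclass(frozen=True)
class MatchedPair:
    truth_index: int
    pred_index: int
    start_offset: int
    end_offset: int


def match_predictions(
    predicted: Sequence[Circle],
    truth: Sequence[Circle],
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> list[MatchedPair]:
    """One-to-one greedy assignment of predictions to truth circles.

    Candidate pairs (both endpoints within ``threshold``) are consumed in
    order of increasing start offset (ties: end offset, then input order);
    each prediction and each truth circle is used at most once.
    """
    candidates = []
    for ti, t in enumerate(truth):
        for pi, p in enumerate(predicted):
            if circles_match(p, t, threshold):
                candidates.append(
                    (abs(p.start - t.start), abs(p.end - t.end), ti, pi)
                )
    candidates.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches: list[MatchedPair] = []
    for ds, de, ti, pi in candidates:
        if ti not in used_t and pi not in used_p:
            used_t.add(ti)
            used_p.add(pi)
            matches.append(MatchedPair(ti, pi, ds, de))
    return matches


@dataclass
class BenchmarkReport:
    """Precision/recall/F for one prediction set against ground truth."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    offset_ratio: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, offset_ratio: float = 0.0):
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        return cls(tp, fp, fn, precision, recall, f, offset_ratio)


def benchmark(
    predicted: Sequence[Circle],
    truth: Sequence[Circle],
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> BenchmarkReport:
    """Score predictions against simulated truth at the given threshold."""
    if not truth:
        raise ValueError("truth set must be non-empty")
    matches = match_predictions(predicted, truth, threshold)
    tp = len(matches)
    fn = len(truth) - tp
    fp = len(predicted) - tp
    exact = sum(1 for m in matches if m.start_offset <= 1 and m.end_offset <= 1)
    ratio = exact / tp if tp > 0 else 0.0
    return BenchmarkReport.from_counts(tp, fp, fn, offset_ratio=ratio)


def offset_ratio(
    predicted: Sequence[Circle],
    truth: Sequence[Circle],
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> float:
    """Fraction of threshold-level matches whose both offsets are <= 1 bp."""
    matches = match_predictions(predicted, truth, threshold)
    if not matches:
        return 0.0
    exact = sum(1 for m in matches if m.start_offset <= 1 and m.end_offset <= 1)
    return exact / len(matches)


def length_ks(
    predicted_lengths: Sequence[int],
    truth_lengths: Sequence[int],
    length_range: tuple[int, int] = (175, 10_000),
) -> tuple[float, float]:
    """Two-sample KS test of length distributions within ``length_range``.

    Both samples are restricted to the closed range before testing; an empty
    sample after restriction is an error.
    """
    lo, hi = length_range
    a = np.asarray([x for x in predicted_lengths if lo <= x <= hi], dtype=float)
    b = np.asarray([x for x in truth_lengths if lo <= x <= hi], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("no lengths remain inside the requested range")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def contingency_chi2_yates(table) -> float:
    """Chi-square statistic with Yates continuity correction for a 2x2 table.

    ``sum((max(|O - E| - 0.5, 0))^2 / E)`` with expectations from the row and
    column marginals; the correction term is clamped at zero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all row and column marginals must be positive")
    expected = np.outer(rows, cols) / total
    dev = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    return float((dev**2 / expected).sum())
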