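"""Junction read-imbalance statistic (ΔCJ) for circle quality control.

A read spanning a circular junction (CJ) can be assigned to either side of
the junction by the aligner. Under a correct circle call both sides are (up
to mappability) equally likely, so a strong left/right imbalance flags a
suspect circle — its supporting reads likely belong to another circle or to
a misalignment. This gives a ground-truth-free quality proxy for circle
detection in biological data.

For each circle, reads are collected in windows of ``n_offset`` (default
20) nucleotides around the start and end junction coordinates. Each read
contributes its probability of correct alignment, ``w_i = 1 - 10^(-MAPQ_i/10)``,
and the per-side weighted sums are rounded up to effective integer counts
``k_L`` and ``k_R``, with ``N = k_L + k_R``. The imbalance statistic is

    ΔCJ = |k_L - k_R| / N                      (0 balanced .. 1 one-sided)

Its significance is assessed with a two-sided binomial tail. With equal
side probabilities the symmetric doubled tail is

    p = P(X <= k) = 2 * 0.5^N * sum_{i<=k} C(N, i),   k = min(k_L, k_R),

set to 1 at the even-N midpoint ``k = N/2`` (where the raw sum double-counts
the central term and can exceed 1). When the 30-nt regions just inside the
two junction boundaries differ in mappability, the expected left-side
probability is corrected to ``p_L = M_L / (M_L + M_R)`` and the tail is
evaluated on the deficit side (the side observed below its expectation),
doubled, and capped at 1. p-values for a result set are Benjamini–Hochberg
adjusted; ``p_adj < 0.05`` marks a circle as significantly skewed.

Solving ``2(N+1) * 0.5^N < alpha`` shows that at least N = 9 junction reads
(continuous bound 8.58) are needed before even a fully one-sided circle can
reach alpha = 0.05, which motivates the cohort metric "proportion of circles
with N >= 9".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Circle

#: Window half-width around each junction coordinate (nt).
DEFAULT_N_OFFSET = 20
#: Width of the inside-junction regions over which mappability is averaged.
MAPPABILITY_REGION = 30


# ---------------------------------------------------------------------------
# data access contracts


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one aligned read: identifier, MAPQ, alignment span."""

    name: str
    mapq: int
    reference_start: Optional[int] = None
    reference_end: Optional[int] = None


class AlignmentSource(Protocol):
    """Contract: fetch aligned reads overlapping a window, deterministically."""

    def fetch(self, chrom: str, start: int, end: int) -> Sequence[AlignmentRecord]:
        ...


class MappabilityTrack(Protocol):
    """Contract: mean mappability over an interval, ``None`` when no data."""

    def mean(self, chrom: str, start: int, end: int) -> Optional[float]:
        ...


# ---------------------------------------------------------------------------
# elementary pieces


def mapq_weight(mapq: int) -> float:
    """Probability of correct alignment encoded by a MAPQ value.

    ``w = 1 - 10^(-MAPQ/10)``: 0 at MAPQ 0, 0.9 at 10, 0.99 at 20.
    """
    if mapq < 0:
        raise ValueError("MAPQ must be >= 0")
    return 1.0 - 10.0 ** (-mapq / 10.0)


def junction_probability(m_l: float, m_r: float) -> Optional[float]:
    """Expected left-side probability from the two region mappabilities.

    ``p_L = M_L / (M_L + M_R)``. Returns ``None`` when both mappabilities are
    zero (no information; callers fall back to 0.5).
    """
    if m_l < 0 or m_r < 0:
        raise ValueError("mappability values must be >= 0")
    if m_l + m_r == 0:
        return None
    return m_l / (m_l + m_r)


def delta_cj(k_l: int, k_r: int) -> float:
    """Normalized junction imbalance ``|k_L - k_R| / (k_L + k_R)``."""
    n = k_l + k_r
    if n <= 0:
        raise ValueError("delta_cj undefined for N == 0")
    return abs(k_l - k_r) / n


def symmetric_tail_raw(k: int, n: int) -> float:
    """Doubled symmetric binomial tail ``2 * 0.5^N * sum_{i<=k} C(N, i)``.

    Exact evaluation of the printed sum; exceeds 1 at the even-N midpoint
    (the central term is counted twice there). ``k`` must not exceed N/2.
    """
    if n < 0 or k < 0:
        raise ValueError("k and n must be >= 0")
    if 2 * k > n:
        raise ValueError(f"k must be <= n/2, got k={k}, n={n}")
    total = sum(math.comb(n, i) for i in range(k + 1))
    return 2.0 * total / 2.0**n


def symmetric_p(k: int, n: int) -> float:
    """Symmetric two-sided tail probability, capped at 1.

    Exactly 1 at the even-N midpoint ``k == n/2``: a perfectly balanced
    split is never evidence of skew.
    """
    if n % 2 == 0 and k == n // 2:
        return 1.0
    return min(symmetric_tail_raw(k, n), 1.0)


def adjusted_p(k_l: int, k_r: int, p_l: float) -> float:
    """Mappability-adjusted two-sided binomial tail probability.

    With side probabilities ``(p_L, 1 - p_L)`` the tail is evaluated on the
    deficit side — the side whose observed count falls below its expected
    count — then doubled and capped at 1. At ``p_L = 0.5`` this reduces to
    the symmetric tail on ``min(k_L, k_R)``. Degenerate ``p_L`` of exactly 0
    or 1 yields p = 0 when the impossible side nevertheless has reads, else 1.
    """
    if k_l < 0 or k_r < 0:
        raise ValueError("counts must be >= 0")
    n = k_l + k_r
    if n == 0:
        raise ValueError("adjusted_p undefined for N == 0")
    if not 0.0 <= p_l <= 1.0:
        raise ValueError("p_l must be in [0, 1]")
    if p_l == 1.0:
        return 0.0 if k_r > 0 else 1.0
    if p_l == 0.0:
        return 0.0 if k_l > 0 else 1.0
    # deficit side: observed below expectation
    if k_l <= n * p_l:
        tail = stats.binom.cdf(k_l, n, p_l)
    else:
        tail = stats.binom.cdf(k_r, n, 1.0 - p_l)
    return min(2.0 * float(tail), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class MinReads:
    """Continuous and integer solutions of ``2(N+1) * 0.5^N < alpha``."""

    continuous: float
    integer: int


def min_reads_for_significance(alpha: float = 0.05) -> MinReads:
    """Minimum junction reads N for a fully one-sided circle to reach alpha.

    Solves ``2(N+1) * 0.5^N = alpha`` (the doubled ``P(X <= 1)`` tail under
    p = 0.5) for continuous N by bisection to 1e-6, and reports the smallest
    integer N satisfying the strict inequality. alpha = 0.05 gives 8.58 / 9;
    alpha = 0.01 gives 11.25 / 12.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    def f(n: float) -> float:
        return 2.0 * (n + 1.0) * 0.5**n - alpha

    lo, hi = 1.0, 1.0
    while f(hi) > 0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    continuous = 0.5 * (lo + hi)
    integer = math.floor(continuous) + 1
    while f(float(integer)) >= 0:  # guard against boundary rounding
        integer += 1
    return MinReads(continuous=continuous, integer=integer)


# ---------------------------------------------------------------------------
# evidence collection


@dataclass
class JunctionEvidence:
    """Effective read counts and expected side probability for one junction.

    ``k_l``/``k_r`` are ceilings of MAPQ-weighted read sums over the two
    junction windows; ``m_l``/``m_r`` the mean mappabilities of the 30-nt
    regions just inside the circle (``None`` when the track has no data);
    ``p_l`` the mappability-corrected expected left probability.
    """

    k_l: int
    k_r: int
    m_l: Optional[float]
    m_r: Optional[float]
    p_l: float
    mappability_missing: bool = False

    @property
    def n(self) -> int:
        return self.k_l + self.k_r


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _weighted_side_sums(
    left_reads: Sequence[AlignmentRecord],
    right_reads: Sequence[AlignmentRecord],
    left_win: tuple[int, int],
    right_win: tuple[int, int],
) -> tuple[float, float]:
    """Per-side MAPQ-weight sums over unique reads.

    A read identifier appearing in both windows is counted once, on the side
    its alignment overlaps more; exact ties (or unknown alignment spans) are
    side-uninformative and contribute to neither sum.
    """
    left = {r.name: r for r in left_reads}
    right = {r.name: r for r in right_reads}
    shared = set(left) & set(right)
    sum_l = sum(mapq_weight(r.mapq) for name, r in left.items() if name not in shared)
    sum_r = sum(mapq_weight(r.mapq) for name, r in right.items() if name not in shared)
    for name in shared:
        r = left[name]
        if r.reference_start is None or r.reference_end is None:
            continue
        ov_l = _overlap(r.reference_start, r.reference_end, *left_win)
        ov_r = _overlap(r.reference_start, r.reference_end, *right_win)
        if ov_l > ov_r:
            sum_l += mapq_weight(r.mapq)
        elif ov_r > ov_l:
            sum_r += mapq_weight(r.mapq)
    return sum_l, sum_r


def collect_evidence(
    source: AlignmentSource,
    circle: Circle,
    mappability: Optional[MappabilityTrack] = None,
    n_offset: int = DEFAULT_N_OFFSET,
    chrom_length: Optional[int] = None,
) -> JunctionEvidence:
    """Gather junction read counts and mappability for one circle.

    Windows span ``n_offset`` nucleotides up- and downstream of each
    junction coordinate (clipped at chromosome bounds). Weighted sums are
    rounded up per side, so any strictly positive support yields an integer
    count of at least 1, while an empty side stays 0.
    """
    lw = (max(0, circle.start - n_offset), circle.start + n_offset + 1)
    rw = (max(0, circle.end - n_offset), circle.end + n_offset + 1)
    if chrom_length is not None:
        lw = (lw[0], min(lw[1], chrom_length))
        rw = (rw[0], min(rw[1], chrom_length))

    sum_l, sum_r = _weighted_side_sums(
        source.fetch(circle.chrom, *lw),
        source.fetch(circle.chrom, *rw),
        lw,
        rw,
    )
    k_l = math.ceil(sum_l - 1e-9) if sum_l > 0 else 0
    k_r = math.ceil(sum_r - 1e-9) if sum_r > 0 else 0

    # 30-nt regions immediately inside the circle; short circles use the
    # whole (overlapping) span for both sides.
    if circle.length >= 2 * MAPPABILITY_REGION:
        l_region = (circle.start, circle.start + MAPPABILITY_REGION)
        r_region = (circle.end - MAPPABILITY_REGION, circle.end)
    else:
        l_region = r_region = (circle.start, circle.end)

    m_l = m_r = None
    if mappability is not None:
        m_l = mappability.mean(circle.chrom, *l_region)
        m_r = mappability.mean(circle.chrom, *r_region)

    missing = m_l is None or m_r is None
    if missing:
        p_l = 0.5
    else:
        p = junction_probability(m_l, m_r)
        if p is None:
            p_l, missing = 0.5, True
        else:
            p_l = p
    return JunctionEvidence(k_l, k_r, m_l, m_r, p_l, mappability_missing=missing)


# ---------------------------------------------------------------------------
# per-circle results and cohort metrics


@dataclass
class DeltaCJResult:
    """ΔCJ statistic and significance for one circle.

    ``delta``/``p``/``p_adj`` are ``None`` when no junction reads were found
    (N == 0); such circles are excluded from the BH family.
    """

    circle: Circle
    evidence: JunctionEvidence
    delta: Optional[float]
    p: Optional[float]
    p_adj: Optional[float] = None

    @property
    def n(self) -> int:
        return self.evidence.n

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p_adj is None else bool(self.p_adj < 0.05)


def evaluate_circles(
    circles: Sequence[Circle],
    source: AlignmentSource,
    mappability: Optional[MappabilityTrack] = None,
    n_offset: int = DEFAULT_N_OFFSET,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[DeltaCJResult]:
    """ΔCJ with BH-adjusted significance for a set of circles.

    One invocation is one BH family (one result set per tool, filter or
    combination), matching per-dataset correction.
    """
    results: list[DeltaCJResult] = []
    for c in circles:
        ev = collect_evidence(
            source,
            c,
            mappability,
            n_offset,
            chrom_length=(chrom_lengths or {}).get(c.chrom),
        )
        if ev.n == 0:
            results.append(DeltaCJResult(c, ev, None, None))
        else:
            d = delta_cj(ev.k_l, ev.k_r)
            p = adjusted_p(ev.k_l, ev.k_r, ev.p_l)
            results.append(DeltaCJResult(c, ev, d, p))
    defined = [i for i, r in enumerate(results) if r.p is not None]
    if defined:
        adj = bh_adjust([results[i].p for i in defined])
        for i, a in zip(defined, adj):
            results[i].p_adj = float(a)
    return results


@dataclass
class CohortMetrics:
    """The three cohort-level circle-quality metrics.

    * ``prop_n_ge_9`` — proportion of circles with enough junction reads
      (N >= 9) for a one-sided circle to be detectable at alpha = 0.05;
    * ``mean_delta`` / ``median_delta`` — ΔCJ over those circles (``None``
      when no circle qualifies);
    * ``prop_significant`` — proportion with BH-adjusted p < 0.05.
    """

    prop_n_ge_9: float
    mean_delta: Optional[float]
    median_delta: Optional[float]
    prop_significant: float


def cohort_metrics(
    results: Sequence[DeltaCJResult], min_n: int = 9
) -> CohortMetrics:
    """Summarize a ΔCJ result set into the three quality metrics."""
    defined = [r for r in results if r.n > 0]
    if not defined:
        raise ValueError("no circles with junction reads in cohort")
    selected = [r for r in defined if r.n >= min_n]
    deltas = np.array([r.delta for r in selected], dtype=float)
    n_sig = sum(1 for r in defined if r.p_adj is not None and r.p_adj < 0.05)
    return CohortMetrics(
        prop_n_ge_9=len(selected) / len(defined),
        mean_delta=float(deltas.mean()) if deltas.size else None,
        median_delta=float(np.median(deltas)) if deltas.size else None,
        prop_significant=n_sig / len(defined),
    )


def delta_delta_cj(
    reference: Sequence[DeltaCJResult], other: Sequence[DeltaCJResult]
) -> float:
    """Difference of mean ΔCJ between two cohorts (reference minus other)."""
    ref = cohort_metrics(reference)
    oth = cohort_metrics(other)
    if ref.mean_delta is None or oth.mean_delta is None:
        raise ValueError("both cohorts need circles with N >= 9")
    return ref.mean_delta - oth.mean_delta
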