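"""ΔCJ statistic: weights, tails, BH adjustment, evidence collection."""

import itertools
import math

import numpy as np
import pytest

from circkit.deltacj import (
    AlignmentRecord,
    adjusted_p,
    bh_adjust,
    cohort_metrics,
    collect_evidence,
    delta_cj,
    delta_delta_cj,
    evaluate_circles,
    junction_probability,
    mapq_weight,
    min_reads_for_significance,
    symmetric_p,
    symmetric_tail_raw,
    DeltaCJResult,
    JunctionEvidence,
)
from circkit.io import FixtureAlignmentSource, FixtureMappabilityTrack
from circkit.model import Circle


# ---------------------------------------------------------------------------
# elementary pieces


@pytest.mark.parametrize("mapq, expected", [(0, 0.0), (10, 0.9), (20, 0.99)])
def test_mapq_weight(mapq, expected):
    assert mapq_weight(mapq) == pytest.approx(expected)


def test_mapq_weight_negative_errors():
    with pytest.raises(ValueError):
        mapq_weight(-1)


def test_junction_probability():
    assert junction_probability(0.8, 0.8) == pytest.approx(0.5)
    assert junction_probability(1.0, 0.470) == pytest.approx(0.6803, abs=1e-4)
    assert junction_probability(1.0, 0.0) == 1.0
    assert junction_probability(0.0, 0.0) is None


def test_delta_cj_values():
    assert delta_cj(22, 22) == 0.0
    assert delta_cj(28, 0) == 1.0
    assert delta_cj(3, 1) == 0.5
    with pytest.raises(ValueError):
        delta_cj(0, 0)


# ---------------------------------------------------------------------------
# symmetric tails


def test_symmetric_tail_worked_examples():
    assert symmetric_tail_raw(3, 6) == pytest.approx(1.3125)
    assert symmetric_tail_raw(3, 7) == pytest.approx(1.0)
    assert symmetric_tail_raw(0, 2) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        symmetric_tail_raw(4, 7)


def test_symmetric_p_midpoint_rule():
    assert symmetric_p(3, 6) == 1.0
    assert symmetric_p(22, 44) == 1.0
    assert symmetric_p(1, 9) == pytest.approx(2 * 0.5**9 * 10)


def _enumeration_tail(k, n):
    """Oracle: exhaustive enumeration of all 2^n equally likely left/right
    assignments; doubled lower-tail mass P(X <= k)."""
    count = sum(
        1
        for bits in itertools.product((0, 1), repeat=n)
        if sum(bits) <= k
    )
    return 2 * count / 2**n


@pytest.mark.parametrize("n", range(1, 13))
def test_symmetric_tail_matches_enumeration(n):
    for k in range(n // 2 + 1):
        assert symmetric_tail_raw(k, n) == pytest.approx(_enumeration_tail(k, n))


@pytest.mark.parametrize("n", range(1, 13))
def test_adjusted_p_reduces_to_symmetric_at_half(n):
    for k_l in range(n + 1):
        k_r = n - k_l
        k = min(k_l, k_r)
        assert adjusted_p(k_l, k_r, 0.5) == pytest.approx(symmetric_p(k, n))


def test_symmetric_p_monotone_in_k():
    for n in (5, 8, 11):
        vals = [symmetric_p(k, n) for k in range(n // 2 + 1)]
        assert vals == sorted(vals)


def test_adjusted_p_deficit_side():
    # left side below expectation under p_l = 0.68; doubled tail on the right
    expected = 2 * 0.68**28
    assert adjusted_p(28, 0, 0.68) == pytest.approx(expected, rel=1e-9)
    # balanced at expectation -> capped at 1
    assert adjusted_p(10, 10, 0.5) == 1.0


def test_adjusted_p_degenerate_probabilities():
    assert adjusted_p(5, 3, 1.0) == 0.0   # reads on an impossible side
    assert adjusted_p(5, 0, 1.0) == 1.0
    assert adjusted_p(0, 5, 0.0) == 1.0


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_single_value_unchanged():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)


def test_bh_step_up_hand_computed():
    out = bh_adjust([0.01, 0.02, 0.03])
    assert out == pytest.approx([0.03, 0.03, 0.03])


def test_bh_all_ones():
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_against_handrolled_oracle(rng):
    def oracle(p):
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    for _ in range(5):
        p = rng.random(20)
        assert bh_adjust(p) == pytest.approx(oracle(p))


def test_bh_properties(rng):
    p = rng.random(50)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# minimum-N derivation


def test_min_reads_for_significance():
    res = min_reads_for_significance(0.05)
    assert res.continuous == pytest.approx(8.58, abs=0.01)
    assert res.integer == 9
    res = min_reads_for_significance(0.01)
    assert res.continuous == pytest.approx(11.25, abs=0.01)
    assert res.integer == 12
    # direct evaluation of the bound around the integer solution
    assert 2 * 9 * 0.5**8 > 0.05 > 2 * 10 * 0.5**9


# ---------------------------------------------------------------------------
# evidence collection


def _circle():
    return Circle("chr1", 1000, 2000)


def test_collect_evidence_one_sided():
    """Three MAPQ-60 reads in the left window only: k_L=3, k_R=0."""
    src = FixtureAlignmentSource.from_window_spec(
        {("chr1", 980, 1021): [60, 60, 60]}
    )
    ev = collect_evidence(src, _circle())
    assert (ev.k_l, ev.k_r, ev.n) == (3, 0, 3)


def test_collect_evidence_empty():
    src = FixtureAlignmentSource({})
    ev = collect_evidence(src, _circle())
    assert ev.n == 0


def test_collect_evidence_low_mapq_ceiling():
    """One MAPQ-3 read per side: weight ~0.4988 rounds up to 1 per side."""
    src = FixtureAlignmentSource.from_window_spec(
        {("chr1", 980, 1021): [3], ("chr1", 1980, 2021): [3]}
    )
    ev = collect_evidence(src, _circle())
    assert (ev.k_l, ev.k_r) == (1, 1)


def test_collect_evidence_shared_read_tie_uninformative():
    """A read overlapping both windows equally is side-uninformative."""
    rec = AlignmentRecord("shared", 60, 980, 2021)  # same 41-base overlap each side
    left_only = AlignmentRecord("left", 60, 985, 1015)
    src = FixtureAlignmentSource({"chr1": [rec, left_only]})
    ev = collect_evidence(src, Circle("chr1", 1000, 2000))
    assert (ev.k_l, ev.k_r) == (1, 0)


def test_collect_evidence_shared_read_majority_side():
    rec = AlignmentRecord("shared", 60, 995, 2005)  # 26 bases left, 25 right
    src = FixtureAlignmentSource({"chr1": [rec]})
    ev = collect_evidence(src, Circle("chr1", 1000, 2000))
    assert (ev.k_l, ev.k_r) == (1, 0)


def test_collect_evidence_mappability():
    src = FixtureAlignmentSource.from_window_spec(
        {("chr1", 980, 1021): [60], ("chr1", 1980, 2021): [60]}
    )
    track = FixtureMappabilityTrack(
        default=1.0, values={("chr1", 1970, 2000): 0.470}
    )
    ev = collect_evidence(src, _circle(), track)
    assert ev.m_l == pytest.approx(1.0)
    assert ev.m_r == pytest.approx(0.470)
    assert ev.p_l == pytest.approx(1.0 / 1.470)
    assert not ev.mappability_missing


def test_collect_evidence_missing_mappability_falls_back():
    src = FixtureAlignmentSource.from_window_spec({("chr1", 980, 1021): [60]})
    track = FixtureMappabilityTrack(default=None)
    ev = collect_evidence(src, _circle(), track)
    assert ev.p_l == 0.5
    assert ev.mappability_missing


def test_collect_evidence_short_circle_shared_region():
    src = FixtureAlignmentSource({})
    track = FixtureMappabilityTrack(default=0.8)
    ev = collect_evidence(src, Circle("chr1", 100, 140), track)
    assert ev.m_l == pytest.approx(0.8)
    assert ev.m_l == ev.m_r


# ---------------------------------------------------------------------------
# cohorts


def _result(k_l, k_r, p_adj=None):
    ev = JunctionEvidence(k_l, k_r, 1.0, 1.0, 0.5)
    n = k_l + k_r
    d = abs(k_l - k_r) / n if n else None
    p = adjusted_p(k_l, k_r, 0.5) if n else None
    r = DeltaCJResult(Circle("chr1", 0, 1000), ev, d, p)
    r.p_adj = p_adj if p_adj is not None else p
    return r


def test_cohort_all_balanced():
    results = [_result(10, 10) for _ in range(5)]
    m = cohort_metrics(results)
    assert m.prop_n_ge_9 == 1.0
    assert m.mean_delta == 0.0
    assert m.median_delta == 0.0
    assert m.prop_significant == 0.0


def test_cohort_all_low_n():
    results = [_result(2, 2) for _ in range(5)]
    m = cohort_metrics(results)
    assert m.prop_n_ge_9 == 0.0
    assert m.mean_delta is None and m.median_delta is None


def test_cohort_mixed_hand_tally():
    results = [
        _result(10, 10),          # N=20, delta 0, p 1
        _result(20, 0),           # N=20, delta 1, p tiny
        _result(2, 2),            # N=4 below cutoff
        _result(6, 14),           # N=20, delta 0.4
    ]
    m = cohort_metrics(results)
    assert m.prop_n_ge_9 == pytest.approx(3 / 4)
    assert m.mean_delta == pytest.approx((0 + 1 + 0.4) / 3)
    assert m.median_delta == pytest.approx(0.4)
    assert m.prop_significant == pytest.approx(
        sum(r.p_adj < 0.05 for r in results if r.n > 0) / 4
    )


def test_delta_delta_cj():
    ref = [_result(10, 10) for _ in range(4)]
    other = [_result(20, 0) for _ in range(4)]
    assert delta_delta_cj(ref, ref) == 0.0
    assert delta_delta_cj(ref, other) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        delta_delta_cj(ref, [])


# ---------------------------------------------------------------------------
# end-to-end over the fixture contract


def test_evaluate_circles_family():
    windows = {}
    circles = []
    for i in range(10):
        start, end = 10_000 * (i + 1), 10_000 * (i + 1) + 2000
        circles.append(Circle("chr1", start, end))
        # balanced junctions except circle 0, fully one-sided with 28 reads
        left = [60] * (28 if i == 0 else 11)
        right = [] if i == 0 else [60] * 11
        windows[("chr1", start - 20, start + 21)] = left
        if right:
            windows[("chr1", end - 20, end + 21)] = right
    src = FixtureAlignmentSource.from_window_spec(windows)
    results = evaluate_circles(circles, src)
    assert results[0].delta == 1.0
    assert results[0].p_adj < 0.05 and results[0].significant
    assert all(r.delta == 0.0 and not r.significant for r in results[1:])
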