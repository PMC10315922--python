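"""Trace engine: pairwise statistics, merging, hierarchical alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracelfq import (
    IntensityTrace,
    TraceSet,
    capped_shift,
    hierarchical_shift,
    merge_pair,
    pairwise_stats,
    select_anchor_traces,
)
from tracelfq.traces import apply_shifts

from .conftest import fuzz_trace_set, make_trace_set
from .naive_shift import naive_hierarchical_shift

NAN = np.nan


@pytest.mark.parametrize(
    "a, b, median, variance, n_overlap",
    [
        ([23, 25, NAN], [22, 24, 26], 1.0, 0.0, 2),   # constant offset
        ([10, 11, 12], [10, 11, 12], 0.0, 0.0, 3),     # identity
        ([10, 12], [11, 15], -2.0, 2.0, 2),            # ddof=1 two-point
        ([10, NAN], [NAN, 12], NAN, NAN, 0),           # disjoint support
    ],
)
def test_pairwise_stats_examples(a, b, median, variance, n_overlap):
    stats = pairwise_stats(IntensityTrace("a", a), IntensityTrace("b", b))
    assert stats.n_overlap == n_overlap
    if n_overlap == 0:
        assert np.isnan(stats.median_shift) and np.isnan(stats.variance)
        assert not stats.comparable
    else:
        assert stats.median_shift == median
        assert stats.variance == variance


def test_single_feature_overlap_has_undefined_variance():
    stats = pairwise_stats(IntensityTrace("a", [10, NAN]),
                           IntensityTrace("b", [8, 9]))
    assert stats.n_overlap == 1
    assert stats.median_shift == 2.0
    assert np.isinf(stats.variance)


def test_merge_pair_fills_missing_and_counts_members():
    a = IntensityTrace("a", [23, 25, NAN])
    b = IntensityTrace("b", [22, 24, 26])
    merged = merge_pair(a, b, pairwise_stats(a, b))
    np.testing.assert_array_equal(merged.values, [23, 25, 27])
    assert merged.n_members == 2


def test_merge_pair_member_weighting():
    # aligned values coincide, so the weighted mean is invisible but the
    # member count accumulates
    a = IntensityTrace("a", [10.0, 10.0], n_members=3)
    b = IntensityTrace("b", [13.0, 13.0], n_members=1)
    merged = merge_pair(a, b, pairwise_stats(a, b))
    np.testing.assert_allclose(merged.values, [10, 10])
    assert merged.n_members == 4


def test_merge_pair_rejects_incomparable():
    a = IntensityTrace("a", [10, NAN])
    b = IntensityTrace("b", [NAN, 12])
    with pytest.raises(ValueError, match="incomparable"):
        merge_pair(a, b, pairwise_stats(a, b))


def test_hierarchical_shift_recovers_exact_offsets():
    base = np.array([10.0, 12.0, 14.0])
    ts = make_trace_set([base, base + 3, base - 1])
    sol = hierarchical_shift(ts)
    aligned = apply_shifts(ts, sol).values_matrix()
    # all traces identical after alignment (up to a common constant)
    np.testing.assert_allclose(aligned - aligned[0], 0.0, atol=1e-12)
    assert not sol.unmerged


def test_hierarchical_shift_singleton_and_empty():
    ts = make_trace_set([[1.0, 2.0]])
    sol = hierarchical_shift(ts)
    assert sol.shifts == pytest.approx([0.0])
    with pytest.raises(ValueError):
        hierarchical_shift(TraceSet(features=[], traces=[]))


def test_disjoint_traces_flagged_with_zero_shift():
    ts = make_trace_set([[10, NAN, NAN], [NAN, 5, 6]])
    sol = hierarchical_shift(ts)
    np.testing.assert_array_equal(sol.shifts, [0.0, 0.0])
    assert sol.unmerged == {"T0", "T1"}


def test_side_component_keeps_zero_shift():
    # traces 0-2 form the main component; 3-4 a disjoint side component
    base = np.array([10.0, 12.0, 14.0, NAN, NAN])
    side = np.array([NAN, NAN, NAN, 5.0, 6.0])
    ts = make_trace_set([base, base + 1, base + 2, side, side + 4])
    sol = hierarchical_shift(ts)
    assert sol.unmerged == {"T3", "T4"}
    np.testing.assert_array_equal(sol.shifts[3:], [0.0, 0.0])
    aligned = apply_shifts(ts, sol).values_matrix()[:3, :3]
    np.testing.assert_allclose(aligned - aligned[0], 0.0, atol=1e-12)


@pytest.mark.parametrize(
    "missing_counts, nmax, expected",
    [
        ([0, 2, 1], 2, [0, 2]),   # ranked by ascending missing count
        ([0, 0, 0], 2, [0, 1]),   # ties broken by input order
        ([1, 0], 5, [0, 1]),      # nmax >= n keeps input order
    ],
)
def test_select_anchor_traces(missing_counts, nmax, expected):
    mat = []
    for m in missing_counts:
        row = [20.0] * 4
        row[:m] = [NAN] * m
        mat.append(row)
    ts = make_trace_set(mat)
    assert select_anchor_traces(ts, nmax) == expected


def test_capped_equals_hierarchical_in_noise_free_case():
    base = np.array([10.0, 12.0, 14.0])
    ts = make_trace_set([base, base + 3, base - 1])
    for nmax in (2, 3):
        aligned = apply_shifts(ts, capped_shift(ts, nmax)).values_matrix()
        np.testing.assert_allclose(aligned - aligned[0], 0.0, atol=1e-12)


def test_capped_shift_single_anchor():
    base = np.arange(5, dtype=float)
    ts = make_trace_set([base + c for c in [0, 2, 4, 6, 8]])
    sol = capped_shift(ts, nmax=1)
    aligned = apply_shifts(ts, sol).values_matrix()
    np.testing.assert_allclose(aligned - aligned[0], 0.0, atol=1e-12)
    # anchor set of one: every other trace compared exactly once
    assert sol.n_comparisons == 4


def test_comparison_count_bound():
    rng = np.random.default_rng(11)
    nmax = 8
    for n in (20, 40):
        ts = make_trace_set(rng.normal(20, 2, size=(n, 30)))
        sol = capped_shift(ts, nmax=nmax)
        assert sol.n_comparisons <= nmax * (nmax - 1) // 2 + (n - nmax)


def test_shift_solution_idempotent():
    rng = np.random.default_rng(5)
    ts = fuzz_trace_set(rng, n_traces=6, n_features=20, missing_p=0.2)
    sol = hierarchical_shift(ts)
    again = hierarchical_shift(apply_shifts(ts, sol))
    np.testing.assert_allclose(again.shifts, 0.0, atol=1e-9)


def test_capped_shift_idempotent_beyond_nmax():
    rng = np.random.default_rng(6)
    ts = fuzz_trace_set(rng, n_traces=12, n_features=25, missing_p=0.2)
    sol = capped_shift(ts, nmax=5)
    again = capped_shift(apply_shifts(ts, sol), nmax=5)
    np.testing.assert_allclose(again.shifts, 0.0, atol=1e-9)


@given(data=st.data())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_oracle_equivalence_and_invariances(data):
    """Incremental engine == naive full-recomputation oracle, bit for bit;
    plus global-offset equivariance and shape preservation."""
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    ts = fuzz_trace_set(rng)
    mat = ts.values_matrix()

    sol = hierarchical_shift(ts)
    naive_shifts, naive_unmerged = naive_hierarchical_shift(mat)
    np.testing.assert_array_equal(sol.shifts, naive_shifts)
    assert {ts.trace_ids[i] for i in naive_unmerged} == sol.unmerged

    # determinism: identical input, identical output
    sol2 = hierarchical_shift(make_trace_set(mat.copy()))
    np.testing.assert_array_equal(sol.shifts, sol2.shifts)

    # global-offset equivariance: +c on every trace changes no alignment
    c = data.draw(st.floats(-8, 8, allow_nan=False))
    sol_c = hierarchical_shift(make_trace_set(mat + c))
    np.testing.assert_allclose(sol_c.shifts, sol.shifts, atol=1e-9)

    # shape preservation: output differs by exactly one additive constant
    aligned = apply_shifts(ts, sol).values_matrix()
    obs = ~np.isnan(mat)
    expected = np.broadcast_to(sol.shifts[:, None], mat.shape)
    np.testing.assert_allclose((aligned - mat)[obs], expected[obs], atol=0)
    assert np.array_equal(np.isnan(aligned), ~obs)
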