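"""Sampling, per-read coverage, classification and derived estimators."""

import logging
import math

import numpy as np
import pytest

from overlapqc import (
    CoverageParams,
    Overlap,
    PerReadCoverage,
    SequenceRecord,
    SketchParams,
    detect_adapter_boundary,
    estimate_error_rate,
    estimate_nonsense_fraction,
    length_binned_standardized,
    per_read_coverage,
    sample_reads,
    standardize_coverage,
)

from conftest import random_dna


def _query(length=10_000, seed=50):
    return SequenceRecord("q", random_dna(length, seed))


def _ov(target, q_start, q_end, q_len=10_000, n_shared=10):
    return Overlap("q", target, q_len, 12_000, q_start, q_end, 0, q_end - q_start, "+", n_shared)


# --- sampling ------------------------------------------------------------


def _tiny_records(lengths, seed=0):
    return [SequenceRecord(f"r{i}", "ACGTACGT") for i in range(len(lengths))]


def test_undersized_pool_returns_all():
    recs = [SequenceRecord(f"r{i}", "A" * 2000) for i in range(10)]
    out = sample_reads(recs, CoverageParams(sample_size=5000))
    assert [r.read_id for r in out] == [r.read_id for r in recs]


def test_sampling_deterministic_per_seed():
    recs = [SequenceRecord(f"r{i}", "A" * 1500) for i in range(500)]
    p = CoverageParams(sample_size=50, seed=11)
    a = [r.read_id for r in sample_reads(recs, p)]
    b = [r.read_id for r in sample_reads(recs, p)]
    c = [r.read_id for r in sample_reads(recs, CoverageParams(sample_size=50, seed=12))]
    assert a == b
    assert a != c


def test_short_reads_excluded_and_empty_pool_errors():
    recs = [SequenceRecord("short", "A" * 500), SequenceRecord("long", "A" * 1500)]
    out = sample_reads(recs, CoverageParams())
    assert [r.read_id for r in out] == ["long"]
    with pytest.raises(ValueError, match="1000"):
        sample_reads([SequenceRecord("s", "A" * 10)], CoverageParams())


def test_reservoir_inclusion_frequencies_uniform():
    """Inclusion frequency of each read over seeded repetitions matches
    the binomial expectation (99% of reads within 3 sigma)."""
    n, size, reps = 1500, 75, 150
    recs = [SequenceRecord(f"r{i}", "A" * 1200) for i in range(n)]
    counts = np.zeros(n)
    for s in range(reps):
        for rec in sample_reads(recs, CoverageParams(sample_size=size, seed=s)):
            counts[int(rec.read_id[1:])] += 1
    p = size / n
    sigma = math.sqrt(p * (1 - p) / reps)
    within = np.abs(counts / reps - p) <= 3 * sigma
    assert within.mean() >= 0.99
    assert abs(counts.sum() / reps - size) < 1e-9


# --- per-read coverage ---------------------------------------------------


def test_no_overlaps_is_nonsense_with_zero_coverage():
    q = _query()
    prc = per_read_coverage(q, [])
    assert prc.n_partners == 0
    assert prc.covered_fraction == 0.0
    assert prc.mean_depth == 0.0
    assert prc.is_nonsense
    assert prc.left_uncovered == q.length
    assert prc.est_error is None


def test_interval_arithmetic_two_partners():
    """Overlaps [0,6000) and [4000,10000) tile the read: coverage 1.0,
    mean depth 1.2, and two partners still counts as non-sense under
    the default threshold of 2."""
    q = _query()
    prc = per_read_coverage(q, [_ov("t1", 0, 6000), _ov("t2", 4000, 10_000)])
    assert prc.n_partners == 2
    assert prc.covered_fraction == 1.0
    assert prc.mean_depth == pytest.approx(1.2)
    assert prc.is_nonsense
    assert (prc.left_uncovered, prc.right_uncovered) == (0, 0)


def test_three_partners_not_nonsense():
    q = _query()
    ovs = [_ov("t1", 0, 4000), _ov("t2", 3000, 7000), _ov("t3", 6000, 10_000)]
    prc = per_read_coverage(q, ovs)
    assert prc.n_partners == 3
    assert not prc.is_nonsense


def test_partner_count_is_distinct_targets():
    q = _query()
    ovs = [_ov("t1", 0, 5000), _ov("t1", 5000, 10_000)]
    assert per_read_coverage(q, ovs).n_partners == 1


def test_foreign_query_id_rejected():
    q = _query()
    bad = Overlap("other", "t", 10_000, 10_000, 0, 5000, 0, 5000, "+", 5)
    with pytest.raises(ValueError, match="other"):
        per_read_coverage(q, [bad])


def test_uncovered_margins():
    q = _query()
    prc = per_read_coverage(q, [_ov("t1", 100, 9800), _ov("t2", 150, 9000), _ov("t3", 200, 9900)])
    assert prc.left_uncovered == 100
    assert prc.right_uncovered == 100
    assert prc.left_uncovered + prc.right_uncovered <= q.length


# --- noise fraction ------------------------------------------------------


def _prc(read_id, n_partners, depth=1.0, length=5000, left=0, right=0):
    return PerReadCoverage(read_id, length, n_partners, 1.0, depth, left, right, n_partners <= 2)


def test_all_flagged_fraction_one():
    s = estimate_nonsense_fraction([_prc("a", 0), _prc("b", 1)])
    assert s.nonsense_fraction == 1.0
    assert s.nonsense_ci[1] == 1.0


def test_none_flagged_fraction_zero_ci_floor():
    recs = [_prc(f"r{i}", 5) for i in range(1000)]
    s = estimate_nonsense_fraction(recs)
    assert s.nonsense_fraction == 0.0
    assert s.nonsense_ci[0] == 0.0
    assert s.nonsense_ci[0] <= s.nonsense_fraction <= s.nonsense_ci[1]


def test_empty_input_errors():
    with pytest.raises(ValueError):
        estimate_nonsense_fraction([])


# --- standardization -----------------------------------------------------


def test_standardize_hand_example():
    recs = [_prc("a", 5, 2.0), _prc("b", 5, 4.0), _prc("c", 5, 6.0)]
    standardize_coverage(recs)
    assert [r.std_coverage for r in recs] == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_degenerate_sd(caplog):
    recs = [_prc("a", 5, 3.0), _prc("b", 5, 3.0)]
    with caplog.at_level(logging.WARNING):
        standardize_coverage(recs)
    assert all(r.std_coverage == 0.0 for r in recs)
    assert "zero variance" in caplog.text


def test_standardize_zscore_identity():
    rng = np.random.default_rng(1)
    recs = [_prc(f"r{i}", 5, float(d)) for i, d in enumerate(rng.gamma(5, 3, 200))]
    standardize_coverage(recs)
    stds = np.array([r.std_coverage for r in recs])
    assert abs(stds.mean()) < 1e-9
    assert abs(stds.std(ddof=1) - 1.0) < 1e-9


def test_length_binned_payload_has_quantile_bins():
    rng = np.random.default_rng(2)
    recs = [
        _prc(f"r{i}", 5, float(d), length=int(l))
        for i, (d, l) in enumerate(zip(rng.gamma(5, 3, 500), rng.integers(1000, 20_000, 500)))
    ]
    standardize_coverage(recs)
    bins = length_binned_standardized(recs, n_bins=10)
    assert len(bins) == 10
    assert sum(b["n"] for b in bins) == 500
    for b in bins:
        assert b["q1"] <= b["median"] <= b["q3"]


# --- error estimator -----------------------------------------------------


def test_error_free_overlaps_give_zero():
    q = _query(2000, seed=60)
    qpos = np.arange(0, 1000, 5)
    ov = Overlap("q", "t", 2000, 2000, 0, 1000, 0, 1000, "+", n_shared=qpos.size)
    est = estimate_error_rate(q, [ov], SketchParams(), _query_minimizer_pos=qpos)
    assert est == 0.0


def test_single_overlap_algebraic_inversion():
    """With survival f = (1-eps)^(2k) the estimator returns eps."""
    eps, k = 0.05, 15
    denom = 100_000
    n_shared = round(denom * (1 - eps) ** (2 * k))
    qpos = np.arange(denom)  # one minimizer per base in [0, denom)
    ov = Overlap("q", "t", denom + 20, denom + 20, 0, denom, 0, denom, "+", n_shared)
    q = SequenceRecord("q", "A" * (denom + 20))
    est = estimate_error_rate(q, [ov], SketchParams(k=k), _query_minimizer_pos=qpos)
    assert est == pytest.approx(eps, abs=1e-4)


def test_no_usable_window_returns_none():
    q = _query(2000, seed=61)
    ov = Overlap("q", "t", 2000, 2000, 1000, 1600, 0, 600, "+", 5)
    est = estimate_error_rate(q, [ov], _query_minimizer_pos=np.array([10, 20]))
    assert est is None


# --- adapter boundary ----------------------------------------------------


def test_adapter_undetermined_below_contributor_floor(caplog):
    recs = [_prc(f"r{i}", 5, left=60, right=60) for i in range(10)]
    with caplog.at_level(logging.WARNING):
        left, right = detect_adapter_boundary(recs)
    assert left is None and right is None
    assert "undetermined" in caplog.text


def test_adapter_noise_floor_suppresses_small_margins():
    recs = [_prc(f"r{i}", 5, left=12, right=8) for i in range(100)]
    assert detect_adapter_boundary(recs) == (0.0, 0.0)


def test_adapter_boundary_recovers_common_offset():
    rng = np.random.default_rng(3)
    recs = [
        _prc(f"r{i}", 5, left=45 + int(g), right=int(h))
        for i, (g, h) in enumerate(zip(rng.exponential(12, 200), rng.exponential(12, 200)))
    ]
    left, right = detect_adapter_boundary(recs)
    assert 40 <= left <= 60
    assert right == 0.0
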