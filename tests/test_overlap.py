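"""Overlap index, chaining and spurious-overlap filtering."""

import numpy as np
import pytest

from overlapqc import (
    Overlap,
    OverlapFilterParams,
    SequenceRecord,
    SketchParams,
    build_index,
    filter_overlaps,
    find_overlaps,
    overlaps_to_paf,
    revcomp,
)
from overlapqc.overlap import projected_span
from overlapqc.sketch import minimizer_arrays

from conftest import random_dna


def _ov(n_shared=10, q_start=0, q_end=2000, t_start=3000, t_end=5000, q_len=5000, t_len=5000, strand="+", target="t1"):
    return Overlap("q", target, q_len, t_len, q_start, q_end, t_start, t_end, strand, n_shared)


# --- index ---------------------------------------------------------------


def test_empty_dataset_rejected():
    with pytest.raises(ValueError, match="no reads"):
        build_index([])


def test_single_read_index_contains_its_hashes():
    seq = random_dna(3000, seed=1)
    p = SketchParams()
    idx = build_index([SequenceRecord("r1", seq)], p)
    _, hashes, _ = minimizer_arrays(seq, p)
    assert set(idx.distinct_hashes().tolist()) == set(hashes.tolist())
    assert idx.n_reads == 1
    assert idx.total_bases == 3000


def test_two_identical_reads_double_postings():
    seq = random_dna(3000, seed=2)
    idx = build_index([SequenceRecord("a", seq), SequenceRecord("b", seq)])
    _, hashes, _ = minimizer_arrays(seq, SketchParams())
    assert idx.n_postings == 2 * hashes.size


def test_distinct_hash_count_matches_per_read_union(small_library):
    _, records, _ = small_library
    subset = records[:100]
    idx = build_index(subset)
    p = SketchParams()
    union = set()
    for r in subset:
        union.update(minimizer_arrays(r.seq, p)[1].tolist())
    # no masking expected at this scale (cutoff floor is 100 reads)
    assert idx.n_masked_hashes == 0
    assert idx.distinct_hashes().size == len(union)


def test_duplicate_read_ids_rejected():
    seq = random_dna(2000, seed=3)
    with pytest.raises(ValueError, match="duplicate"):
        build_index([SequenceRecord("r", seq), SequenceRecord("r", seq)])


# --- find_overlaps -------------------------------------------------------


def test_self_hit_excluded():
    seq = random_dna(5000, seed=4)
    rec = SequenceRecord("only", seq)
    idx = build_index([rec])
    assert find_overlaps(rec, idx) == []


def test_constructed_shared_substring_pair():
    """Two reads sharing an exact 2 kb substring overlap exactly once,
    with an anchor span no more than w+k short of the truth."""
    shared = random_dna(2000, seed=10)
    a = SequenceRecord("a", random_dna(3000, seed=11) + shared)
    b = SequenceRecord("b", shared + random_dna(3000, seed=12))
    p = SketchParams()
    idx = build_index([a, b], p)
    ovs = find_overlaps(a, idx, p)
    assert len(ovs) == 1
    ov = ovs[0]
    assert ov.target_id == "b"
    assert ov.strand == "+"
    assert ov.q_span >= 2000 - (p.w + p.k)
    assert ov.q_start >= 3000 - (p.w + p.k)


def test_reverse_strand_overlap_detected():
    shared = random_dna(2000, seed=20)
    a = SequenceRecord("a", random_dna(2000, seed=21) + shared)
    b = SequenceRecord("b", revcomp(shared + random_dna(2000, seed=22)))
    idx = build_index([a, b])
    ovs = find_overlaps(a, idx)
    assert len(ovs) == 1
    assert ovs[0].strand == "-"
    # '-' coordinates are on the target's forward strand: the shared
    # block sits at the *end* of b's forward sequence
    assert ovs[0].t_end >= 3900


def test_independent_random_reads_share_nothing():
    a = SequenceRecord("a", random_dna(10_000, seed=30))
    b = SequenceRecord("b", random_dna(10_000, seed=31))
    idx = build_index([a, b])
    assert find_overlaps(a, idx) == []
    # brute-force confirmation: far fewer shared canonical k-mers than min_shared
    k = 15
    ka = {min(a.seq[i : i + k], revcomp(a.seq[i : i + k])) for i in range(len(a.seq) - k + 1)}
    kb = {min(b.seq[i : i + k], revcomp(b.seq[i : i + k])) for i in range(len(b.seq) - k + 1)}
    assert len(ka & kb) < OverlapFilterParams().min_shared


def test_mismatched_sketch_params_rejected(small_index, small_library):
    _, records, _ = small_library
    with pytest.raises(ValueError, match="param"):
        find_overlaps(records[0], small_index, SketchParams(k=17))


# --- filter_overlaps -----------------------------------------------------


def test_filter_empty():
    assert filter_overlaps([]) == []


def test_filter_min_shared_boundary():
    filt = OverlapFilterParams()
    below = _ov(n_shared=filt.min_shared - 1)
    at = _ov(n_shared=filt.min_shared)
    assert filter_overlaps([below], filt) == []
    assert filter_overlaps([at], filt) == [at]


def test_filter_min_span_uses_projected_span():
    """min_span applies to the dovetail-projected span: a 400-base anchor
    chain whose flanks project it to exactly 500 sits on the boundary."""
    filt = OverlapFilterParams()
    dovetail = _ov(q_start=4550, q_end=4950, t_start=50, t_end=450)
    assert projected_span(dovetail) == 400 + 50 + 50
    assert filter_overlaps([dovetail], filt) == [dovetail]
    assert filter_overlaps([dovetail], OverlapFilterParams(min_span=501)) == []


def test_filter_rejects_internal_repeat_keeps_dovetail():
    """Equal-evidence internal match is dropped; dovetail survives."""
    dovetail = _ov(q_start=3000, q_end=4990, t_start=10, t_end=2000, target="t_dove")
    internal = _ov(
        q_start=1500, q_end=3500, t_start=1500, t_end=3500, q_len=10_000, t_len=10_000, target="t_int"
    )
    kept = filter_overlaps([dovetail, internal])
    assert [o.target_id for o in kept] == ["t_dove"]


def test_filter_keeps_best_per_target_strand():
    weak = _ov(n_shared=5, target="t1")
    strong = _ov(n_shared=9, target="t1")
    other = _ov(n_shared=5, target="t2")
    kept = filter_overlaps([weak, strong, other])
    assert {(o.target_id, o.n_shared) for o in kept} == {("t1", 9), ("t2", 5)}


def test_filter_monotonicity(small_library, small_index):
    """Raising min_shared or min_span never increases accepted overlaps."""
    _, records, _ = small_library
    queries = records[:15]

    def count(filt):
        return sum(len(find_overlaps(q, small_index, filt=filt)) for q in queries)

    base = count(OverlapFilterParams())
    assert count(OverlapFilterParams(min_shared=8)) <= base
    assert count(OverlapFilterParams(min_span=2000)) <= base


def test_paf_export_schema():
    table = overlaps_to_paf([_ov()])
    assert list(table.columns) == [
        "query_id", "q_len", "q_start", "q_end", "strand",
        "target_id", "t_len", "t_start", "t_end", "n_shared", "q_span",
    ]
    assert table.iloc[0]["q_span"] == 2000


def test_overlap_invariants():
    with pytest.raises(ValueError):
        Overlap("q", "q", 100, 100, 0, 10, 0, 10, "+", 5)
    with pytest.raises(ValueError):
        Overlap("q", "t", 100, 100, 10, 10, 0, 10, "+", 5)
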