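"""Read-to-read overlap detection from minimizer sketches.

A desk-scale overlap engine: every read in the dataset is sketched and
its minimizers stored in a sorted hash index; a sampled query read is
then matched against the index, shared minimizers are grouped per
(target read, relative strand) and chained into the longest collinear
run, and the resulting candidate overlaps are filtered for spurious
(repeat-induced, internal-only) matches.

Highly repetitive minimizer hashes — those occurring in an unusually
large number of reads, such as repeats or un-trimmed adapters shared by
every read — are masked at indexing time; this is the standard control
against spurious overlaps and is what makes un-trimmed terminal adapters
visible downstream as uncovered read ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .io import SequenceRecord
from .sketch import SketchParams, minimizer_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapFilterParams:
    """Acceptance rules for candidate overlaps.

    min_shared
        Minimum number of chained shared minimizers.
    min_span
        Minimum extent of the overlap on the query, bases.
    max_gap
        Maximum positional gap (query or target) between consecutive
        chained minimizers, bases.
    max_diag_drift
        Maximum difference between the query gap and the target gap of
        consecutive chained minimizers, bases — the indel budget between
        anchors. Keeps a chain inside one alignment band and stops
        off-diagonal anchors (e.g. shared terminal artifact sequence)
        from attaching to a genuine chain.
    terminal_slack
        How close an overlap must come to a read end, on the query or
        the target, to count as a proper dovetail/containment rather
        than an internal (repeat-like) match, bases.
    """

    min_shared: int = 4
    min_span: int = 500
    max_gap: int = 2000
    max_diag_drift: int = 500
    terminal_slack: int = 1000

    def __post_init__(self) -> None:
        for name in ("min_shared", "min_span", "max_gap", "max_diag_drift", "terminal_slack"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Overlap:
    """An accepted pairwise overlap between a query read and a target read.

    Coordinates are 0-based half-open on the forward strand of each
    read; for '-' overlaps the target interval is still reported on the
    target's forward strand. ``n_shared`` counts chained shared
    minimizers.
    """

    query_id: str
    target_id: str
    q_len: int
    t_len: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # '+' or '-'
    n_shared: int

    def __post_init__(self) -> None:
        if self.query_id == self.target_id:
            raise ValueError("self-overlap is not a valid Overlap")
        if not (self.q_start < self.q_end and self.t_start < self.t_end):
            raise ValueError("overlap intervals must be non-empty")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


class OverlapIndex:
    """Sorted minimizer-hash index over a whole dataset.

    Postings are stored as parallel arrays sorted by hash; lookups use
    binary search. Hashes occurring in more reads than the masking
    cutoff are dropped (and counted in ``n_masked_hashes``).
    """

    def __init__(
        self,
        params: SketchParams,
        hashes: np.ndarray,
        read_idx: np.ndarray,
        pos: np.ndarray,
        fwd_canon: np.ndarray,
        read_ids: List[str],
        read_lengths: np.ndarray,
        total_bases: int,
        n_masked_hashes: int,
        mask_cutoff: float,
    ) -> None:
        self.params = params
        self._hashes = hashes
        self._read_idx = read_idx
        self._pos = pos
        self._fwd_canon = fwd_canon
        self.read_ids = read_ids
        self._id_to_idx = {rid: i for i, rid in enumerate(read_ids)}
        self.read_lengths = read_lengths
        self.total_bases = total_bases
        self.n_masked_hashes = n_masked_hashes
        self.mask_cutoff = mask_cutoff

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_postings(self) -> int:
        return int(self._hashes.size)

    def distinct_hashes(self) -> np.ndarray:
        return np.unique(self._hashes)

    def lookup(self, query_hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posting ranges ``(lo, hi)`` for each query hash."""
        lo = np.searchsorted(self._hashes, query_hashes, side="left")
        hi = np.searchsorted(self._hashes, query_hashes, side="right")
        return lo, hi


def build_index(
    dataset: Iterable[SequenceRecord],
    params: Optional[SketchParams] = None,
) -> OverlapIndex:
    """Sketch every read of ``dataset`` and build the hash index.

    Raises ``ValueError`` on an empty dataset. Hashes occurring in more
    distinct reads than ``max(index_min_occ_cutoff, q-quantile)`` of the
    per-hash read-count distribution are masked.
    """
    params = params or SketchParams()
    read_ids: List[str] = []
    lengths: List[int] = []
    all_hashes: List[np.ndarray] = []
    all_pos: List[np.ndarray] = []
    all_fwd: List[np.ndarray] = []
    all_ridx: List[np.ndarray] = []
    seen = set()
    for i, rec in enumerate(dataset):
        if rec.read_id in seen:
            raise ValueError(f"duplicate read id {rec.read_id!r} in dataset")
        seen.add(rec.read_id)
        pos, hashes, fwd = minimizer_arrays(rec.seq, params)
        read_ids.append(rec.read_id)
        lengths.append(rec.length)
        all_hashes.append(hashes)
        all_pos.append(pos)
        all_fwd.append(fwd)
        all_ridx.append(np.full(pos.size, i, dtype=np.int32))
    if not read_ids:
        raise ValueError("no reads: cannot build an overlap index from an empty dataset")

    hashes = np.concatenate(all_hashes)
    pos = np.concatenate(all_pos).astype(np.int32)
    ridx = np.concatenate(all_ridx)
    fwd = np.concatenate(all_fwd)

    order = np.argsort(hashes, kind="stable")
    hashes, pos, ridx, fwd = hashes[order], pos[order], ridx[order], fwd[order]

    # distinct-read count per hash -> masking cutoff
    uniq, start = np.unique(hashes, return_index=True)
    bounds = np.append(start, hashes.size)
    read_counts = np.empty(uniq.size, dtype=np.int64)
    for j in range(uniq.size):
        read_counts[j] = np.unique(ridx[bounds[j] : bounds[j + 1]]).size
    cutoff = max(
        float(params.index_min_occ_cutoff),
        float(np.quantile(read_counts, params.index_max_occ_quantile)),
    )
    masked = read_counts > cutoff
    n_masked = int(masked.sum())
    if n_masked:
        drop = np.zeros(hashes.size, dtype=bool)
        for j in np.flatnonzero(masked):
            drop[bounds[j] : bounds[j + 1]] = True
        keep = ~drop
        hashes, pos, ridx, fwd = hashes[keep], pos[keep], ridx[keep], fwd[keep]
        logger.info("masked %d high-frequency minimizer hashes (cutoff %.0f reads)", n_masked, cutoff)

    return OverlapIndex(
        params=params,
        hashes=hashes,
        read_idx=ridx,
        pos=pos,
        fwd_canon=fwd,
        read_ids=read_ids,
        read_lengths=np.asarray(lengths, dtype=np.int64),
        total_bases=int(np.sum(lengths)),
        n_masked_hashes=n_masked,
        mask_cutoff=cutoff,
    )


def _chain(q: np.ndarray, t: np.ndarray, max_gap: int, max_drift: int) -> np.ndarray:
    """Longest collinear chain over hits sorted by (q, t): both strictly
    increasing, neither gap exceeding ``max_gap``, and the diagonal
    drift between consecutive anchors at most ``max_drift``. Returns
    indices of chained hits (into the sorted arrays)."""
    n = q.size
    # fast path: already one monotone chain
    if n >= 2:
        dq = np.diff(q)
        dt = np.diff(t)
        if np.all((dq > 0) & (dt > 0) & (dq <= max_gap) & (dt <= max_gap) & (np.abs(dq - dt) <= max_drift)):
            return np.arange(n)
    elif n <= 1:
        return np.arange(n)
    best_len = np.ones(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        ok = (
            (q[:i] < q[i])
            & (t[:i] < t[i])
            & (q[i] - q[:i] <= max_gap)
            & (t[i] - t[:i] <= max_gap)
            & (np.abs((q[i] - q[:i]) - (t[i] - t[:i])) <= max_drift)
        )
        if ok.any():
            cand = np.where(ok, best_len[:i], 0)
            j = int(cand.argmax())
            if cand[j] > 0:
                best_len[i] = cand[j] + 1
                parent[i] = j
    end = int(best_len.argmax())
    chain = []
    while end != -1:
        chain.append(end)
        end = int(parent[end])
    return np.asarray(chain[::-1], dtype=np.int64)


def find_overlaps(
    query: SequenceRecord,
    index: OverlapIndex,
    sketch: Optional[SketchParams] = None,
    filt: Optional[OverlapFilterParams] = None,
    _query_minimizers: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> List[Overlap]:
    """Accepted overlaps of ``query`` against all indexed reads.

    Shared minimizers are grouped per (target, relative strand); the
    longest collinear chain under ``max_gap`` forms the candidate
    overlap; candidates then pass through :func:`filter_overlaps`.
    Self-hits (identical read id) are always discarded.
    """
    sketch = sketch or index.params
    if sketch != index.params:
        raise ValueError("query must be sketched with the index's parameters")
    filt = filt or OverlapFilterParams()
    if _query_minimizers is not None:
        qpos, qhash, qfwd = _query_minimizers
    else:
        qpos, qhash, qfwd = minimizer_arrays(query.seq, sketch)
    if qpos.size == 0:
        return []

    lo, hi = index.lookup(qhash)
    counts = hi - lo
    has_hit = counts > 0
    if not has_hit.any():
        return []
    # expand posting ranges into flat hit arrays
    reps = counts[has_hit]
    flat = np.concatenate([np.arange(l, h) for l, h in zip(lo[has_hit], hi[has_hit])])
    hit_q = np.repeat(qpos[has_hit], reps)
    hit_qfwd = np.repeat(qfwd[has_hit], reps)
    hit_t = index._pos[flat]
    hit_ridx = index._read_idx[flat]
    hit_tfwd = index._fwd_canon[flat]
    # same relative strand when both or neither k-mer is forward-canonical
    hit_same = hit_qfwd == hit_tfwd

    self_idx = index._id_to_idx.get(query.read_id, -1)
    keep = hit_ridx != self_idx
    if not keep.all():
        hit_q, hit_t, hit_ridx, hit_same = hit_q[keep], hit_t[keep], hit_ridx[keep], hit_same[keep]
    if hit_q.size == 0:
        return []

    k = sketch.k
    q_len = query.length
    raw: List[Overlap] = []
    # group by (target read, relative strand)
    group_key = hit_ridx.astype(np.int64) * 2 + hit_same.astype(np.int64)
    order = np.argsort(group_key, kind="stable")
    group_key = group_key[order]
    hit_q, hit_t = hit_q[order], hit_t[order]
    starts = np.flatnonzero(np.r_[True, group_key[1:] != group_key[:-1]])
    starts = np.append(starts, group_key.size)
    for s, e in zip(starts[:-1], starts[1:]):
        if e - s < filt.min_shared:
            continue
        ridx = int(group_key[s] // 2)
        same = bool(group_key[s] % 2)
        q = hit_q[s:e].astype(np.int64)
        t_fwd = hit_t[s:e].astype(np.int64)
        t = t_fwd if same else -t_fwd
        sub = np.lexsort((t, q))
        # drop repeated (q, t) pairs (duplicate minimizer positions)
        q, t = q[sub], t[sub]
        chain = _chain(q, t, filt.max_gap, filt.max_diag_drift)
        if chain.size < filt.min_shared:
            continue
        cq = q[chain]
        ct = t_fwd[sub][chain]
        t_len = int(index.read_lengths[ridx])
        raw.append(
            Overlap(
                query_id=query.read_id,
                target_id=index.read_ids[ridx],
                q_len=q_len,
                t_len=t_len,
                q_start=int(cq.min()),
                q_end=int(cq.max()) + k,
                t_start=int(ct.min()),
                t_end=int(ct.max()) + k,
                strand="+" if same else "-",
                n_shared=int(chain.size),
            )
        )
    return filter_overlaps(raw, filt)


def _t_flanks(ov: Overlap) -> tuple[int, int]:
    """Target bases beyond the overlap on the query's left/right side."""
    if ov.strand == "+":
        return ov.t_start, ov.t_len - ov.t_end
    return ov.t_len - ov.t_end, ov.t_start


def _is_proper(ov: Overlap, slack: int) -> bool:
    """Dovetail/containment test: the overlap must reach within ``slack``
    of a read end on both its left and right flanks (on the query or on
    the target, whichever side continues there)."""
    t_left, t_right = _t_flanks(ov)
    left_ok = ov.q_start <= slack or t_left <= slack
    right_ok = (ov.q_len - ov.q_end) <= slack or t_right <= slack
    return left_ok and right_ok


def projected_span(ov: Overlap) -> int:
    """Overlap span extended along the diagonal to the nearer read end.

    Chained minimizers start and stop short of the true overlap
    boundaries (by the anchor sampling gap), so the anchor span
    underestimates the overlap length. Extending each end by the
    smaller of the two reads' remaining flanks projects the chain to
    the point where one read ends — for a genuine dovetail or
    containment this equals the true overlap length. The minimum-span
    filter is applied to this quantity.
    """
    t_left, t_right = _t_flanks(ov)
    return ov.q_span + min(ov.q_start, t_left) + min(ov.q_len - ov.q_end, t_right)


def filter_overlaps(raw: Sequence[Overlap], filt: Optional[OverlapFilterParams] = None) -> List[Overlap]:
    """Drop spurious overlaps from one query's candidate list.

    Keeps an overlap iff it has at least ``min_shared`` chained
    minimizers, spans at least ``min_span`` bases (measured as the
    dovetail-projected span, see :func:`projected_span`), and is a
    proper dovetail/containment (internal-only matches are
    repeat-induced). At most one overlap survives per (target, strand):
    largest ``n_shared``, ties by larger ``q_span``, then target id.
    """
    filt = filt or OverlapFilterParams()
    best: dict[tuple[str, str], Overlap] = {}
    for ov in raw:
        if ov.n_shared < filt.min_shared:
            continue
        if projected_span(ov) < filt.min_span:
            continue
        if not _is_proper(ov, filt.terminal_slack):
            continue
        key = (ov.target_id, ov.strand)
        cur = best.get(key)
        if cur is None or (ov.n_shared, ov.q_span, cur.target_id) > (
            cur.n_shared,
            cur.q_span,
            ov.target_id,
        ):
            best[key] = ov
    return sorted(best.values(), key=lambda o: (o.target_id, o.strand))


PAF_COLUMNS = [
    "query_id",
    "q_len",
    "q_start",
    "q_end",
    "strand",
    "target_id",
    "t_len",
    "t_start",
    "t_end",
    "n_shared",
    "q_span",
]


def overlaps_to_paf(overlaps: Iterable[Overlap]):
    """Overlaps as a PAF-like table (one row per accepted overlap)."""
    import pandas as pd

    rows = [
        {
            "query_id": o.query_id,
            "q_len": o.q_len,
            "q_start": o.q_start,
            "q_end": o.q_end,
            "strand": o.strand,
            "target_id": o.target_id,
            "t_len": o.t_len,
            "t_start": o.t_start,
            "t_end": o.t_end,
            "n_shared": o.n_shared,
            "q_span": o.q_span,
        }
        for o in overlaps
    ]
    return pd.DataFrame(rows, columns=PAF_COLUMNS)
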