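"""Minimizer sketching of reads.

A (w,k)-minimizer sketch selects, from every window of ``w`` consecutive
k-mers, the k-mer with the smallest 64-bit hash of its *canonical* form
(the lexicographically smaller of the k-mer and its reverse complement,
compared as 2-bit packed integers). Canonical hashing makes the sketch
strand-invariant: a read and its reverse complement yield the same
multiset of hashes. The selected positions are the anchors the overlap
engine matches between reads.

k-mers containing N are never selected. Hashing is a fixed splitmix64
mixer over the packed k-mer, deterministic across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

_U64 = np.uint64
_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SketchParams:
    """Parameters of the minimizer scheme.

    k is the k-mer length, w the number of consecutive k-mers per
    selection window. ``index_max_occ_quantile`` and ``index_min_occ_cutoff``
    control masking of high-frequency (repeat-like) hashes when an index
    is built: a hash is dropped when the number of distinct reads it
    occurs in exceeds both the given quantile of the per-hash read-count
    distribution and the absolute floor.
    """

    k: int = 15
    w: int = 10
    index_max_occ_quantile: float = 0.999
    index_min_occ_cutoff: int = 100

    def __post_init__(self) -> None:
        if self.k < 5:
            raise ValueError("k must be >= 5")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.k > 31:
            raise ValueError("k must fit in a 64-bit packed word (k <= 31)")


@dataclass(frozen=True)
class Minimizer:
    """One selected k-mer: canonical hash, 0-based start position on the
    forward strand, and which strand's k-mer is canonical."""

    hash: int
    pos: int
    strand: str  # '+' if the forward k-mer is canonical, else '-'


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finalizer; deterministic 64-bit mixing."""
    z = x.astype(_U64) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical hash and canonical-strand flag for every k-mer of ``seq``.

    Returns ``(hashes, fwd_is_canonical)`` of length ``len(seq) - k + 1``;
    k-mers containing N carry the sentinel hash 2**64-1.
    """
    codes = _encode(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64), np.empty(0, dtype=bool)
    fwd = np.zeros(n, dtype=_U64)
    rev = np.zeros(n, dtype=_U64)
    valid_codes = codes < 4
    safe = np.where(valid_codes, codes, 0).astype(_U64)
    comp = np.where(valid_codes, 3 - codes, 0).astype(_U64)
    for j in range(k):
        fwd |= safe[j : j + n] << _U64(2 * (k - 1 - j))
        rev |= comp[j : j + n] << _U64(2 * j)
    canonical = np.minimum(fwd, rev)
    fwd_is_canonical = fwd <= rev
    hashes = splitmix64(canonical)
    # invalidate k-mers containing N
    invalid = np.convolve((~valid_codes).astype(np.int32), np.ones(k, dtype=np.int32))[
        k - 1 : k - 1 + n
    ] > 0
    hashes[invalid] = _SENTINEL
    return hashes, fwd_is_canonical


def minimizer_arrays(seq: str, params: SketchParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, hashes and canonical-strand flags of the (w,k)-minimizers.

    For every window of ``w`` consecutive k-mers the k-mer with the
    smallest hash is selected (leftmost on ties); duplicate selections
    are collapsed. Sequences with fewer than ``w`` k-mers use a single
    window spanning all k-mers. Output is sorted by position.
    """
    k, w = params.k, params.w
    hashes, fwd_canon = kmer_hashes(seq, k)
    n = hashes.size
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=_U64), np.empty(0, dtype=bool)
    if n <= w:
        sel = np.array([int(np.argmin(hashes))])
    else:
        windows = np.lib.stride_tricks.sliding_window_view(hashes, w)
        sel = windows.argmin(axis=1) + np.arange(n - w + 1)
        sel = np.unique(sel)
    keep = hashes[sel] != _SENTINEL
    sel = sel[keep]
    return sel.astype(np.int64), hashes[sel], fwd_canon[sel]


def compute_minimizers(seq: str, params: SketchParams) -> List[Minimizer]:
    """(w,k)-minimizers of ``seq`` as :class:`Minimizer` objects.

    A sequence shorter than k yields an empty list.
    """
    pos, hashes, fwd_canon = minimizer_arrays(seq, params)
    return [
        Minimizer(int(h), int(p), "+" if f else "-")
        for p, h, f in zip(pos, hashes, fwd_canon)
    ]
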