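"""Descriptive per-read statistics: length, GC, per-read QV, complexity.

These are the format-independent summaries a long-read dataset is
screened with before any alignment: the length distribution and N50,
per-read GC content (a bimodal GC histogram is a classic contamination
signature), the mean sequencer-assigned quality per read where Phred
values exist, and windowed Shannon entropy as a low-complexity measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LengthStats:
    n_reads: int
    total_bases: int
    mean: float
    median: float
    n50: int
    bin_edges: List[float]
    counts: List[int]


@dataclass
class ReadComplexity:
    """Windowed-entropy summary of one read."""

    mean_entropy: float
    low_complexity_fraction: float
    n_windows: int


def length_stats(lengths: Sequence[int], n_bins: int = 50) -> LengthStats:
    """Length summary with N50 and a histogram.

    N50 is the length L such that reads of length >= L contain at least
    half of all bases (descending cumulative sum). The median of an
    even-sized sample is the lower of the two middle values, so it is
    always an observed read length.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("length_stats requires at least one read")
    if (arr <= 0).any():
        raise ValueError("read lengths must be positive")
    total = int(arr.sum())
    desc = np.sort(arr)[::-1]
    n50 = int(desc[np.searchsorted(np.cumsum(desc), total / 2.0)])
    median = float(np.sort(arr)[(arr.size - 1) // 2])
    counts, edges = np.histogram(arr, bins=n_bins)
    return LengthStats(
        n_reads=int(arr.size),
        total_bases=total,
        mean=float(arr.mean()),
        median=median,
        n50=n50,
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
    )


def gc_content(seq: str) -> Optional[float]:
    """Fraction (G+C)/(A+C+G+T); Ns excluded; None for an all-N read."""
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return None
    return gc / denom


def per_read_qv(quals: Sequence[int]) -> float:
    """Mean sequencer-assigned Phred value of one read.

    The arithmetic mean of the quality scores (not the Phred of the
    mean error probability), matching how per-read QV is conventionally
    reported by sequencers.
    """
    arr = np.asarray(quals)
    if arr.size == 0:
        raise ValueError("per_read_qv requires a non-empty quality vector")
    return float(arr.mean())


_ENTROPY_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENTROPY_CODE[ord(_b)] = _i


def sequence_complexity(
    seq: str,
    window: int = 64,
    step: Optional[int] = None,
    low_entropy_threshold: float = 1.0,
) -> ReadComplexity:
    """Windowed Shannon entropy of a read, bits in [0, 2].

    Entropy is computed over A/C/G/T frequencies per window (Ns
    ignored); the read-level value is the mean over windows, and a
    window counts as low-complexity below ``low_entropy_threshold``
    bits. A read shorter than ``window`` is scored as one window.
    """
    if window < 16:
        raise ValueError("window must be >= 16")
    step = step or window
    codes = _ENTROPY_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n <= window:
        starts = [0]
        window_eff = n
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] + window < n:
            starts.append(n - window)
        window_eff = window
    entropies = []
    for s in starts:
        chunk = codes[s : s + window_eff]
        counts = np.bincount(chunk[chunk < 4], minlength=4).astype(float)
        tot = counts.sum()
        if tot == 0:
            continue
        p = counts[counts > 0] / tot
        entropies.append(float(-(p * np.log2(p)).sum()))
    if not entropies:
        return ReadComplexity(float("nan"), float("nan"), 0)
    ent = np.asarray(entropies)
    return ReadComplexity(
        mean_entropy=float(ent.mean()),
        low_complexity_fraction=float((ent < low_entropy_threshold).mean()),
        n_windows=int(ent.size),
    )


def safe_spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation, defined as 0.0 when degenerate.

    Pairs with missing values are dropped; with fewer than three pairs,
    or when either variable is constant, there is no evidence of
    association and 0.0 is returned instead of NaN.
    """
    from scipy.stats import spearmanr

    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    if xa.size < 3 or np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return 0.0
    rho = spearmanr(xa, ya).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def gc_mode_positions(
    gc_values: Sequence[float],
    bin_width: float = 0.01,
    min_separation: float = 0.05,
    min_prominence_fraction: float = 0.005,
) -> List[float]:
    """Positions (GC fractions) of the modes of a per-read GC histogram.

    The histogram over [0, 1] is lightly smoothed (3-bin moving
    average) and peaks are detected with a prominence floor of
    ``min_prominence_fraction`` of the number of reads (at least 5
    reads) and a minimum separation of ``min_separation``. Two or more
    returned modes indicate a mixed (e.g. contaminated) library.
    """
    from scipy.signal import find_peaks

    vals = np.asarray([v for v in gc_values if v is not None and np.isfinite(v)])
    if vals.size == 0:
        return []
    n_bins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    smooth = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
    prominence = max(5.0, min_prominence_fraction * vals.size)
    distance = max(1, int(round(min_separation / bin_width)))
    peaks, _ = find_peaks(smooth, prominence=prominence, distance=distance)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return [float(centers[p]) for p in peaks]
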