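"""Per-read coverage, non-sense read classification and derived estimators.

This is the core of the engine. A subsample of reads is drawn from the
dataset and each sampled read is overlapped against every other read.
Because genomic DNA fragments randomly, a genuine read at adequate depth
must overlap other reads from the same locus; a read with (by default)
two or fewer distinct overlapping partners is flagged as a *non-sense
read* — a unique read that maps onto no other molecule in the library.
The fraction of flagged reads estimates the dataset's noise level.

From the same overlaps, three further quantities are read off per
sampled read:

* a per-base depth profile (mean depth, covered fraction, uncovered
  terminal lengths);
* a k-mer-survival error estimate — the fraction of the read's
  minimizers confirmed by each overlapping partner decays like
  ``(1 - e)^(2k)`` in the per-read error rate ``e``, so inverting the
  survival fraction recovers ``e``;
* adapter-like boundary lengths — un-trimmed terminal adapters are
  masked as high-frequency repeats at indexing time, leaving a
  consistent uncovered margin at read ends whose median exceeds the
  sketch noise floor.

Standardized per-read coverage (mean depth z-scored across the sample)
feeds the length-binned whisker plot used to spot short-fragment noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import SequenceRecord
from .overlap import Overlap
from .sketch import SketchParams, minimizer_arrays

logger = logging.getLogger(__name__)

#: Multiplicative calibration of the k-mer-survival error estimate.
#: Minimizer selection is only partially conserved between two
#: erroneous copies of the same locus, which inflates the raw survival
#: estimate by a roughly constant factor; this constant was fixed once
#: by parameter recovery on simulated reads at 5/10/15% true error
#: (see docs/methods.md) and is not a per-dataset fit.
DEFAULT_ERROR_CALIBRATION = 1.0


@dataclass(frozen=True)
class CoverageParams:
    """Sampling and classification parameters.

    A read is flagged non-sense when it has ``nonsense_max_partners``
    or fewer distinct overlapping partners (default 2). ``sd_lines``
    is the +/- reference (in standard deviations) drawn on the
    standardized-coverage plot.
    """

    sample_size: int = 5000
    min_read_len: int = 1000
    nonsense_max_partners: int = 2
    sd_lines: float = 3.0
    seed: int = 7
    error_calibration: float = DEFAULT_ERROR_CALIBRATION

    def __post_init__(self) -> None:
        if self.nonsense_max_partners < 0:
            raise ValueError("nonsense_max_partners must be >= 0")
        if self.sample_size < 1:
            raise ValueError("sample_size must be positive")


@dataclass
class PerReadCoverage:
    """Coverage summary of one sampled read."""

    read_id: str
    length: int
    n_partners: int
    covered_fraction: float
    mean_depth: float
    left_uncovered: int
    right_uncovered: int
    is_nonsense: bool
    est_error: Optional[float] = None
    std_coverage: Optional[float] = None


@dataclass
class CoverageSummary:
    """Dataset-level summary of the sampled per-read coverage records."""

    n_sampled: int
    n_flagged: int
    nonsense_fraction: float
    nonsense_ci: Tuple[float, float]
    coverage_mean: float
    coverage_sd: float
    sd_lines: float = 3.0
    length_binned_std: List[dict] = field(default_factory=list)
    adapter_left: Optional[float] = None
    adapter_right: Optional[float] = None


def sample_reads(
    dataset: Iterable[SequenceRecord], params: Optional[CoverageParams] = None
) -> List[SequenceRecord]:
    """Uniform sample without replacement of eligible reads.

    Single-pass reservoir sampling (Algorithm R) over reads of length
    >= ``min_read_len``; deterministic for a fixed seed and input
    order. Returns every eligible read when fewer than ``sample_size``
    exist.
    """
    params = params or CoverageParams()
    rng = np.random.default_rng(params.seed)
    reservoir: List[SequenceRecord] = []
    n_eligible = 0
    for rec in dataset:
        if rec.length < params.min_read_len:
            continue
        n_eligible += 1
        if len(reservoir) < params.sample_size:
            reservoir.append(rec)
        else:
            j = int(rng.integers(0, n_eligible))
            if j < params.sample_size:
                reservoir[j] = rec
    if not reservoir:
        raise ValueError(f"no reads of length >= {params.min_read_len} to sample")
    if len(reservoir) < 100:
        logger.warning(
            "only %d sampled reads; the noise-fraction estimate will be coarse",
            len(reservoir),
        )
    return reservoir


def per_read_coverage(
    query: SequenceRecord,
    overlaps: Sequence[Overlap],
    params: Optional[CoverageParams] = None,
    sketch: Optional[SketchParams] = None,
) -> PerReadCoverage:
    """Coverage profile and non-sense flag for one sampled read.

    ``overlaps`` must be the post-filter overlaps of this query. The
    depth profile stacks the query intervals of all accepted overlaps;
    partners are distinct target reads. The error estimate is filled
    when at least one overlap exists.
    """
    params = params or CoverageParams()
    for ov in overlaps:
        if ov.query_id != query.read_id:
            raise ValueError(
                f"overlap with query {ov.query_id!r} passed for read {query.read_id!r}"
            )
    length = query.length
    diff = np.zeros(length + 1, dtype=np.int32)
    for ov in overlaps:
        diff[ov.q_start] += 1
        diff[ov.q_end] -= 1
    depth = np.cumsum(diff[:-1])
    covered = depth > 0
    n_covered = int(covered.sum())
    if n_covered:
        first = int(np.argmax(covered))
        last = length - 1 - int(np.argmax(covered[::-1]))
        left_unc, right_unc = first, length - 1 - last
    else:
        left_unc, right_unc = length, 0
    n_partners = len({ov.target_id for ov in overlaps})
    est = None
    if n_partners > 0:
        est = estimate_error_rate(query, overlaps, sketch or SketchParams(), params.error_calibration)
    return PerReadCoverage(
        read_id=query.read_id,
        length=length,
        n_partners=n_partners,
        covered_fraction=n_covered / length,
        mean_depth=float(depth.mean()),
        left_uncovered=left_unc,
        right_uncovered=right_unc,
        is_nonsense=n_partners <= params.nonsense_max_partners,
        est_error=est,
    )


def estimate_error_rate(
    query: SequenceRecord,
    overlaps: Sequence[Overlap],
    sketch: Optional[SketchParams] = None,
    calibration: float = DEFAULT_ERROR_CALIBRATION,
    _query_minimizer_pos: Optional[np.ndarray] = None,
) -> Optional[float]:
    """K-mer-survival estimate of the per-base error rate of one read.

    For each accepted overlap the survival fraction
    ``f = n_shared / (query minimizers inside the overlap window)`` is
    the probability that a k-mer is error-free in *both* reads, i.e.
    roughly ``(1 - e)^(2k)`` at symmetric per-read error ``e``; each
    overlap therefore contributes ``1 - f**(1/(2k))`` and the read's
    estimate is the calibrated median over overlaps. Returns ``None``
    when no overlap yields a usable window.
    """
    sketch = sketch or SketchParams()
    if _query_minimizer_pos is not None:
        qpos = _query_minimizer_pos
    else:
        qpos, _, _ = minimizer_arrays(query.seq, sketch)
    if qpos.size == 0 or not overlaps:
        return None
    two_k = 2.0 * sketch.k
    per_overlap = []
    for ov in overlaps:
        n_window = int(np.searchsorted(qpos, ov.q_end) - np.searchsorted(qpos, ov.q_start))
        if n_window == 0:
            continue
        f = min(1.0, ov.n_shared / n_window)
        per_overlap.append(1.0 - f ** (1.0 / two_k))
    if not per_overlap:
        return None
    return float(np.clip(calibration * float(np.median(per_overlap)), 0.0, 1.0))


def estimate_nonsense_fraction(records: Sequence[PerReadCoverage]) -> CoverageSummary:
    """Noise fraction of the dataset with a 95% Wilson confidence interval.

    The fraction of sampled reads flagged non-sense, plus the first two
    moments of the per-read mean depth across the sample.
    """
    from statsmodels.stats.proportion import proportion_confint

    if not records:
        raise ValueError("estimate_nonsense_fraction requires at least one record")
    n = len(records)
    flagged = sum(r.is_nonsense for r in records)
    lo, hi = proportion_confint(flagged, n, alpha=0.05, method="wilson")
    lo = 0.0 if flagged == 0 else max(0.0, float(lo))
    hi = 1.0 if flagged == n else min(1.0, float(hi))
    depths = np.asarray([r.mean_depth for r in records])
    return CoverageSummary(
        n_sampled=n,
        n_flagged=flagged,
        nonsense_fraction=flagged / n,
        nonsense_ci=(float(lo), float(hi)),
        coverage_mean=float(depths.mean()),
        coverage_sd=float(depths.std(ddof=1)) if n > 1 else 0.0,
    )


def standardize_coverage(records: Sequence[PerReadCoverage]) -> Sequence[PerReadCoverage]:
    """Fill ``std_coverage``: mean depth centred by the sample mean and
    divided by the sample standard deviation (n-1).

    The standardized values have mean 0 and standard deviation 1; a
    zero-variance sample gets all zeros with a warning.
    """
    if len(records) < 2:
        raise ValueError("standardization requires at least two records")
    depths = np.asarray([r.mean_depth for r in records])
    mean = float(depths.mean())
    sd = float(depths.std(ddof=1))
    if sd == 0.0:
        logger.warning("per-read coverage has zero variance; standardized coverage set to 0")
        for r in records:
            r.std_coverage = 0.0
        return records
    for r, d in zip(records, depths):
        r.std_coverage = float((d - mean) / sd)
    return records


def length_binned_standardized(
    records: Sequence[PerReadCoverage], n_bins: int = 10
) -> List[dict]:
    """Whisker-plot payload: standardized coverage per read-length bin.

    Reads are split into ``n_bins`` equal-count quantile bins of
    length; each bin reports median, quartiles and 1.5-IQR whiskers of
    the standardized coverage.
    """
    recs = [r for r in records if r.std_coverage is not None]
    if not recs:
        return []
    lengths = np.asarray([r.length for r in recs], dtype=float)
    stds = np.asarray([r.std_coverage for r in recs], dtype=float)
    n_bins = min(n_bins, len(recs))
    edges = np.quantile(lengths, np.linspace(0.0, 1.0, n_bins + 1))
    edges[-1] += 1.0
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (lengths >= lo) & (lengths < hi)
        if not mask.any():
            continue
        vals = stds[mask]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        out.append(
            {
                "len_lo": float(lo),
                "len_hi": float(hi),
                "n": int(mask.sum()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_lo": float(max(vals.min(), q1 - 1.5 * iqr)),
                "whisker_hi": float(min(vals.max(), q3 + 1.5 * iqr)),
            }
        )
    return out


#: Minimum number of contributing reads for an adapter-boundary call.
MIN_ADAPTER_CONTRIBUTORS = 50
#: Histogram bin width (bases) for the modal boundary estimate.
ADAPTER_BOUNDARY_BIN = 5


def _modal_boundary(values: np.ndarray, floor: float) -> float:
    """Boundary = median of the modal histogram bin (plus neighbours).

    A shared un-trimmed adapter puts a sharp cluster of uncovered
    margins just above the adapter length; residual anchor noise both
    below (rare unmasked adapter anchors) and above (anchor gaps) is
    one-sided and diffuse, so the modal bin locates the cluster far
    more robustly than a mean, median or extreme quantile.
    """
    bin_w = ADAPTER_BOUNDARY_BIN
    edges = np.arange(0, values.max() + 2 * bin_w, bin_w)
    counts, _ = np.histogram(values, edges)
    m = int(counts.argmax())
    lo, hi = edges[m] - bin_w, edges[m + 1] + bin_w
    sel = values[(values >= lo) & (values < hi)]
    est = float(np.median(sel))
    return est if est > floor else 0.0


def detect_adapter_boundary(
    records: Sequence[PerReadCoverage], sketch: Optional[SketchParams] = None
) -> Tuple[Optional[float], Optional[float]]:
    """Adapter-like terminal boundary lengths (left, right), bases.

    An un-trimmed adapter shared by every read is masked as a
    high-frequency repeat at indexing time, so overlap anchors cluster
    at or just after the adapter/insert junction: the per-read
    uncovered terminal lengths of well-covered reads pile up at the
    adapter length, and the boundary is read off as the median of the
    modal histogram bin of that distribution. A side is reported as 0
    when the estimate does not exceed the sketch noise floor
    ``w + k + 5`` (margins of that order arise on adapter-free data
    from minimizer spacing alone).

    Only reads with >= 3 partners contribute; with fewer than
    ``MIN_ADAPTER_CONTRIBUTORS`` of them the boundary is undetermined
    and ``(None, None)`` is returned with a warning.
    """
    sketch = sketch or SketchParams()
    contrib = [r for r in records if r.n_partners >= 3]
    if len(contrib) < MIN_ADAPTER_CONTRIBUTORS:
        logger.warning(
            "adapter boundary undetermined: only %d reads with >= 3 partners", len(contrib)
        )
        return None, None
    floor = sketch.w + sketch.k + 5
    left = _modal_boundary(np.asarray([r.left_uncovered for r in contrib]), floor)
    right = _modal_boundary(np.asarray([r.right_uncovered for r in contrib]), floor)
    return left, right
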