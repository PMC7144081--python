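"""End-to-end QC pipeline and the machine-readable report.

``run_qc`` wires the stages together: ingest -> per-read descriptive
stats -> minimizer index over the whole dataset -> read subsample ->
overlap detection -> per-read coverage, noise fraction, error rates and
adapter boundaries -> JSON report (plus TSV tables and plots). The
pipeline is deterministic for a fixed seed; plot rendering is isolated
so numeric outputs never depend on plotting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (
    CoverageParams,
    CoverageSummary,
    PerReadCoverage,
    detect_adapter_boundary,
    estimate_nonsense_fraction,
    length_binned_standardized,
    per_read_coverage,
    sample_reads,
    standardize_coverage,
)
from .io import SequenceRecord, read_sequences, sniff_format, write_tsv
from .overlap import OverlapFilterParams, build_index, find_overlaps, overlaps_to_paf
from .sketch import SketchParams, minimizer_arrays
from .stats import gc_content, gc_mode_positions, length_stats, per_read_qv, sequence_complexity

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"
TOOL = "overlapqc"

#: Noise level above which the report carries a warning. Normal
#: long-read libraries typically sit below a 10% non-sense fraction.
DEFAULT_ALERT_LEVEL = 0.10


@dataclass
class QCReport:
    """Aggregated dataset summary; serializes losslessly to JSON."""

    tool: str
    schema_version: str
    created: str
    input: dict
    params: dict
    lengths: dict
    gc: dict
    complexity: dict
    qv: dict
    coverage: dict
    error: dict
    warnings: List[str] = field(default_factory=list)
    plots: List[str] = field(default_factory=list)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, allow_nan=False)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QCReport":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            source = Path(source).read_text()
        data = json.loads(source)
        return cls(**data)


def _py(x):
    """Convert numpy scalars (and None-safe floats) to JSON-clean values."""
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


class PipelineResult:
    """run_qc output: the report plus the per-read tables behind it."""

    def __init__(
        self,
        report: QCReport,
        per_read: pd.DataFrame,
        coverage_records: List[PerReadCoverage],
        overlaps_paf: pd.DataFrame,
    ) -> None:
        self.report = report
        self.per_read = per_read
        self.coverage_records = coverage_records
        self.overlaps_paf = overlaps_paf


def analyze_records(
    records: Sequence[SequenceRecord],
    *,
    input_path: str = "<memory>",
    input_format: str = "records",
    sketch: Optional[SketchParams] = None,
    filt: Optional[OverlapFilterParams] = None,
    cov: Optional[CoverageParams] = None,
    alert_level: float = DEFAULT_ALERT_LEVEL,
    timestamp: Optional[str] = None,
    keep_overlaps: bool = True,
    complexity_window: int = 64,
) -> PipelineResult:
    """Run the full QC computation on in-memory records.

    This is the library entry point behind :func:`run_qc`; it performs
    every numeric stage but writes nothing to disk.
    """
    sketch = sketch or SketchParams()
    filt = filt or OverlapFilterParams()
    cov = cov or CoverageParams()
    records = list(records)
    if not records:
        raise ValueError("no reads in input")
    warnings: List[str] = []

    t0 = time.perf_counter()
    # --- descriptive per-read statistics -------------------------------
    lengths = [r.length for r in records]
    lstats = length_stats(lengths)
    gc_vals = [gc_content(r.seq) for r in records]
    comp = [sequence_complexity(r.seq, window=complexity_window) for r in records]
    qv_vals = [per_read_qv(r.quals) if r.quals is not None and len(r.quals) else None for r in records]
    logger.info("stats stage: %d reads in %.1fs", len(records), time.perf_counter() - t0)

    # --- overlap engine -------------------------------------------------
    t1 = time.perf_counter()
    index = build_index(records, sketch)
    logger.info(
        "index stage: %d postings, %d masked hashes in %.1fs",
        index.n_postings,
        index.n_masked_hashes,
        time.perf_counter() - t1,
    )
    t2 = time.perf_counter()
    sampled = sample_reads(records, cov)
    cov_records: List[PerReadCoverage] = []
    paf_frames = []
    for rec in sampled:
        qmin = minimizer_arrays(rec.seq, sketch)
        ovs = find_overlaps(rec, index, sketch, filt, _query_minimizers=qmin)
        prc = per_read_coverage(rec, ovs, cov, sketch)
        cov_records.append(prc)
        if keep_overlaps and ovs:
            paf_frames.append(overlaps_to_paf(ovs))
    logger.info(
        "overlap stage: %d sampled reads in %.1fs", len(sampled), time.perf_counter() - t2
    )
    standardize_coverage(cov_records)
    summary = estimate_nonsense_fraction(cov_records)
    summary.sd_lines = cov.sd_lines
    summary.length_binned_std = length_binned_standardized(cov_records)
    summary.adapter_left, summary.adapter_right = detect_adapter_boundary(cov_records, sketch)
    if summary.adapter_left is None:
        warnings.append("adapter boundary undetermined (too few well-covered reads)")
    if summary.nonsense_fraction > alert_level:
        warnings.append(
            f"non-sense read fraction {summary.nonsense_fraction:.3f} exceeds "
            f"alert level {alert_level:.2f}"
        )

    # --- assemble tables -------------------------------------------------
    per_read = pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "length": lengths,
            "gc": [_py(v) for v in gc_vals],
            "mean_qv": [_py(v) for v in qv_vals],
            "mean_entropy": [_py(c.mean_entropy) for c in comp],
            "low_complexity_fraction": [_py(c.low_complexity_fraction) for c in comp],
        }
    )
    cov_df = pd.DataFrame(
        {
            "read_id": [c.read_id for c in cov_records],
            "n_partners": [c.n_partners for c in cov_records],
            "covered_fraction": [c.covered_fraction for c in cov_records],
            "mean_depth": [c.mean_depth for c in cov_records],
            "std_coverage": [c.std_coverage for c in cov_records],
            "left_uncovered": [c.left_uncovered for c in cov_records],
            "right_uncovered": [c.right_uncovered for c in cov_records],
            "is_nonsense": [c.is_nonsense for c in cov_records],
            "est_error": [_py(c.est_error) for c in cov_records],
        }
    )
    per_read = per_read.merge(cov_df, on="read_id", how="left")
    overlaps_paf = (
        pd.concat(paf_frames, ignore_index=True) if paf_frames else overlaps_to_paf([])
    )

    # --- report -----------------------------------------------------------
    gc_clean = np.asarray([v for v in gc_vals if v is not None], dtype=float)
    gc_counts, gc_edges = np.histogram(gc_clean, bins=100, range=(0.0, 1.0))
    qv_clean = np.asarray([v for v in qv_vals if v is not None], dtype=float)
    ent_clean = np.asarray(
        [c.mean_entropy for c in comp if np.isfinite(c.mean_entropy)], dtype=float
    )
    est_errors = np.asarray(
        [c.est_error for c in cov_records if c.est_error is not None], dtype=float
    )
    report = QCReport(
        tool=TOOL,
        schema_version=SCHEMA_VERSION,
        created=timestamp or "",
        input={
            "path": str(input_path),
            "format": input_format,
            "n_reads": len(records),
            "total_bases": int(sum(lengths)),
        },
        params={
            "sketch": dataclasses.asdict(sketch),
            "filter": dataclasses.asdict(filt),
            "coverage": dataclasses.asdict(cov),
            "alert_level": alert_level,
            "complexity_window": complexity_window,
        },
        lengths=dataclasses.asdict(lstats),
        gc={
            "mean": _py(gc_clean.mean()) if gc_clean.size else None,
            "sd": _py(gc_clean.std(ddof=1)) if gc_clean.size > 1 else None,
            "bin_edges": [float(e) for e in gc_edges],
            "counts": [int(c) for c in gc_counts],
            "modes": gc_mode_positions(gc_clean),
        },
        complexity={
            "mean_entropy": _py(ent_clean.mean()) if ent_clean.size else None,
            "low_complexity_fraction": _py(
                float(np.mean([c.low_complexity_fraction for c in comp if np.isfinite(c.low_complexity_fraction)]))
            )
            if ent_clean.size
            else None,
        },
        qv={
            "available": bool(qv_clean.size),
            "mean": _py(qv_clean.mean()) if qv_clean.size else None,
            "sd": _py(qv_clean.std(ddof=1)) if qv_clean.size > 1 else None,
        },
        coverage={
            "n_sampled": summary.n_sampled,
            "n_flagged": summary.n_flagged,
            "nonsense_fraction": _py(summary.nonsense_fraction),
            "nonsense_ci": [_py(summary.nonsense_ci[0]), _py(summary.nonsense_ci[1])],
            "coverage_mean": _py(summary.coverage_mean),
            "coverage_sd": _py(summary.coverage_sd),
            "sd_lines": _py(summary.sd_lines),
            "length_binned_std": summary.length_binned_std,
            "adapter_left": _py(summary.adapter_left),
            "adapter_right": _py(summary.adapter_right),
            "index_masked_hashes": index.n_masked_hashes,
        },
        error={
            "median_est_error": _py(float(np.median(est_errors))) if est_errors.size else None,
            "n_estimated": int(est_errors.size),
        },
        warnings=warnings,
    )
    return PipelineResult(report, per_read, cov_records, overlaps_paf)


def run_qc(
    input_path: str | Path,
    out_dir: Optional[str | Path] = None,
    *,
    format_hint: Optional[str] = None,
    sketch: Optional[SketchParams] = None,
    filt: Optional[OverlapFilterParams] = None,
    cov: Optional[CoverageParams] = None,
    alert_level: float = DEFAULT_ALERT_LEVEL,
    make_plots: bool = True,
    timestamp: Optional[str] = None,
) -> QCReport:
    """Run the whole QC pipeline on a sequence file.

    Writes ``report.json``, ``per_read.tsv``, ``overlaps.paf.tsv`` and
    (optionally) plots plus an HTML summary into ``out_dir``; returns
    the report. Deterministic for a fixed coverage seed.
    """
    input_path = Path(input_path)
    fmt = format_hint or sniff_format(input_path)
    records = list(read_sequences(input_path, fmt))
    if timestamp is None:
        timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    result = analyze_records(
        records,
        input_path=str(input_path),
        input_format=fmt,
        sketch=sketch,
        filt=filt,
        cov=cov,
        alert_level=alert_level,
        timestamp=timestamp,
    )
    report = result.report
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(result.per_read, out_dir / "per_read.tsv")
        write_tsv(result.overlaps_paf, out_dir / "overlaps.paf.tsv")
        if make_plots:
            from .plots import render_plots

            report.plots = render_plots(result, out_dir)
        report.to_json(out_dir / "report.json")
    return report
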