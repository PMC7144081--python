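"""Plot rendering for the QC report.

All plots are written as PNG with the Agg backend (no display needed)
and embedded in a single self-contained HTML summary. Rendering is kept
strictly downstream of the numeric pipeline: nothing here feeds back
into the report's numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def render_plots(result, out_dir: str | Path) -> List[str]:
    """Render the standard plot set for one pipeline result.

    Emits a read-length histogram, the length-binned standardized
    coverage whisker plot (with the +/- SD reference lines), the
    per-read coverage distribution, the GC histogram, and — when both
    QV and error estimates exist — a QV vs estimated-error scatter.
    Returns the written paths (relative to ``out_dir``).
    """
    out_dir = Path(out_dir)
    plots_dir = out_dir / "plots"
    plots_dir.mkdir(parents=True, exist_ok=True)
    report = result.report
    written: List[str] = []

    # (a) read length histogram
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.asarray(report.lengths["bin_edges"])
    counts = np.asarray(report.lengths["counts"])
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="#4878cf")
    ax.set_xlabel("read length (bases)")
    ax.set_ylabel("reads")
    ax.set_title(f"Read lengths (N50 = {report.lengths['n50']:,})")
    written.append(_save(fig, plots_dir / "length_hist.png", out_dir))

    # (b) length-binned standardized coverage whiskers
    bins = report.coverage["length_binned_std"]
    if bins:
        fig, ax = plt.subplots(figsize=(7, 4))
        centers = [(b["len_lo"] + b["len_hi"]) / 2.0 for b in bins]
        widths = [max((b["len_hi"] - b["len_lo"]) * 0.4, 1.0) for b in bins]
        stats = [
            {
                "med": b["median"],
                "q1": b["q1"],
                "q3": b["q3"],
                "whislo": b["whisker_lo"],
                "whishi": b["whisker_hi"],
                "label": f"{int(b['len_lo'])}",
            }
            for b in bins
        ]
        ax.bxp(stats, positions=centers, widths=widths, showfliers=False)
        sd = report.coverage["sd_lines"]
        for y in (-sd, sd):
            ax.axhline(y, color="#4878cf", lw=1.2)
        ax.set_xlabel("read length bin (bases)")
        ax.set_ylabel("standardized per-read coverage")
        ax.set_title("Coverage by read length")
        written.append(_save(fig, plots_dir / "coverage_whisker.png", out_dir))

    # (c) per-read coverage distribution
    depths = [c.mean_depth for c in result.coverage_records]
    if depths:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(depths, bins=60, color="#4878cf")
        ax.set_xlabel("per-read mean depth")
        ax.set_ylabel("sampled reads")
        ax.set_title("Per-read coverage")
        written.append(_save(fig, plots_dir / "coverage_dist.png", out_dir))

    # (d) GC histogram
    fig, ax = plt.subplots(figsize=(6, 4))
    gc_edges = np.asarray(report.gc["bin_edges"])
    gc_counts = np.asarray(report.gc["counts"])
    ax.bar(gc_edges[:-1], gc_counts, width=np.diff(gc_edges), align="edge", color="#4878cf")
    ax.set_xlabel("per-read GC fraction")
    ax.set_ylabel("reads")
    ax.set_xlim(0, 1)
    ax.set_title("GC content")
    written.append(_save(fig, plots_dir / "gc_hist.png", out_dir))

    # (e) QV vs estimated error scatter (when both available)
    pr = result.per_read
    if "mean_qv" in pr and "est_error" in pr:
        sub = pr[["mean_qv", "est_error"]].dropna()
        if len(sub) >= 3:
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(sub["mean_qv"], sub["est_error"], s=6, alpha=0.4, color="#4878cf")
            ax.set_xlabel("per-read QV (sequencer)")
            ax.set_ylabel("estimated per-read error rate")
            ax.set_title("QV vs estimated error")
            written.append(_save(fig, plots_dir / "qv_vs_error.png", out_dir))

    _write_html(result, written, out_dir / "report.html")
    return written


def _save(fig, path: Path, out_dir: Path) -> str:
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return str(path.relative_to(out_dir))


def _write_html(result, plot_paths: List[str], path: Path) -> None:
    r = result.report
    cov = r.coverage
    adapter = (
        f"{cov['adapter_left']} / {cov['adapter_right']}"
        if cov["adapter_left"] is not None
        else "undetermined"
    )
    qv = f"{r.qv['mean']:.2f}" if r.qv["available"] else "unavailable (no Phred scores)"
    rows = "".join(
        f"<tr><td>{k}</td><td>{v}</td></tr>"
        for k, v in [
            ("Input", f"{r.input['path']} ({r.input['format']})"),
            ("Reads / bases", f"{r.input['n_reads']:,} / {r.input['total_bases']:,}"),
            ("Mean / median / N50 length", f"{r.lengths['mean']:.0f} / {r.lengths['median']:.0f} / {r.lengths['n50']:,}"),
            ("Mean GC", f"{r.gc['mean']:.3f}" if r.gc["mean"] is not None else "n/a"),
            ("Mean per-read QV", qv),
            (
                "Non-sense read fraction",
                f"{cov['nonsense_fraction']:.3f} "
                f"(95% CI {cov['nonsense_ci'][0]:.3f}-{cov['nonsense_ci'][1]:.3f}, "
                f"n = {cov['n_sampled']})",
            ),
            ("Median estimated error rate", r.error["median_est_error"]),
            ("Adapter boundary (left / right, bases)", adapter),
        ]
    )
    warn_html = "".join(f"<li>{w}</li>" for w in r.warnings)
    imgs = "".join(f'<div><img src="{p}" style="max-width:720px"></div>' for p in plot_paths)
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>overlapqc report</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td{{border:1px solid #ccc;padding:4px 10px}}</style></head>
<body><h1>overlapqc report</h1>
<table>{rows}</table>
{f'<h2>Warnings</h2><ul>{warn_html}</ul>' if warn_html else ''}
<h2>Plots</h2>{imgs}
</body></html>
"""
    path.write_text(html)
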