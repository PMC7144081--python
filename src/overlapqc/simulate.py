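"""Synthetic long-read datasets with known ground truth.

The generator emulates a single-genome long-read library the way the QC
engine sees one: a random genome, reads drawn uniformly with a
log-normal length distribution from both strands, per-base
substitution/insertion/deletion errors, and — the quantities the QC
estimators are tested against — an injectable fraction of "non-sense"
reads (i.i.d. random sequence that overlaps nothing else in the
library), optional un-trimmed terminal adapters, and optional
short-fragment contaminant reads drawn from one window of a second,
GC-divergent genome. Every emitted read carries a ground-truth record
(origin, source coordinates, true error rate, adapter lengths) for
parameter-recovery tests.

Quality strings encode each read's true per-base error rate as a
constant Phred value, so per-read QV has a known truth; non-sense reads
are given a fixed, misleadingly high QV of 10, mimicking artifact reads
that carry good sequencer quality but no biological signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .sketch import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library.

    Defaults describe a typical desk-scale long-read run: a 1 Mb
    genome at 25x depth, log-normal read lengths with mean ~8 kb, and a
    10% total error rate split 5/2.5/2.5 between substitutions,
    insertions and deletions.
    """

    genome_length: int = 1_000_000
    gc: float = 0.45
    depth: float = 25.0
    read_len_lognorm: Tuple[float, float] = (8.8623, 0.5)  # mean length ~8000
    min_len: int = 500
    error_rates: Tuple[float, float, float] = (0.05, 0.025, 0.025)  # mismatch, ins, del
    per_read_error_range: Optional[Tuple[float, float]] = None
    nonsense_fraction: float = 0.0
    nonsense_mode: str = "random"  # or "high_error": genomic origin at 35% error
    short_fragment_mode: bool = False  # non-sense lengths ~ lognormal mean 1000
    nonsense_qv: int = 10
    adapter_seq: Optional[str] = None
    adapter_sides: str = "both"  # 'left', 'right' or 'both'
    contaminant_fraction: float = 0.0
    contaminant_genome_length: int = 2_000_000
    contaminant_window_length: int = 50_000
    contaminant_gc: float = 0.55
    contaminant_len_lognorm: Tuple[float, float] = (8.2491, 0.3)  # mean length ~4000
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonsense_fraction <= 1.0:
            raise ValueError("nonsense_fraction must be in [0, 1]")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if self.nonsense_fraction + self.contaminant_fraction > 1.0:
            raise ValueError("nonsense + contaminant fractions exceed 1")
        if sum(self.error_rates) >= 0.5:
            raise ValueError("total error probability must be < 0.5")
        if any(r < 0 for r in self.error_rates):
            raise ValueError("error rates must be non-negative")
        if self.min_len <= 0 or self.genome_length <= 0:
            raise ValueError("lengths must be positive")
        if self.nonsense_mode not in ("random", "high_error"):
            raise ValueError("nonsense_mode must be 'random' or 'high_error'")
        if self.adapter_sides not in ("left", "right", "both"):
            raise ValueError("adapter_sides must be 'left', 'right' or 'both'")

    @property
    def mean_read_len(self) -> float:
        mu, sigma = self.read_len_lognorm
        return math.exp(mu + sigma**2 / 2.0)


SHORT_FRAGMENT_LOGNORM = (6.7828, 0.5)  # mean length ~1000
HIGH_ERROR_RATE = 0.35  # 'high_error' non-sense reads: genomic at this total error


@dataclass
class SimTruth:
    """Ground truth for every emitted read.

    ``reads`` has one row per read: read_id, origin
    (genome/nonsense/contaminant), source_start/source_end (on the
    origin genome, -1 for random reads), strand, true_error (per-base
    total error rate; NaN for random reads), adapter_left/adapter_right
    (bases added). ``genome`` and ``contaminant_genome`` are the source
    sequences; ``contaminant_window`` the (start, end) of the window
    contaminant reads were drawn from.
    """

    reads: pd.DataFrame
    genome: str
    contaminant_genome: Optional[str] = None
    contaminant_window: Optional[Tuple[int, int]] = None

    def to_tsv(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False, na_rep=".")


def generate_genome(length: int, gc: float, seed: int) -> str:
    """I.i.d. random genome with P(G) = P(C) = gc/2; deterministic per seed."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10,000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at])
    return _BASES[codes].tobytes().decode("ascii")


def _apply_errors(
    seq: str, rates: Tuple[float, float, float], rng: np.random.Generator
) -> str:
    """Per-base substitution/insertion/deletion errors.

    Substitution replaces the base with a uniformly random *different*
    base; insertion adds a uniformly random base after the current one;
    deletion drops the base.
    """
    mm, ins, dele = rates
    if mm + ins + dele == 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.searchsorted(_BASES, codes)  # ACGT are sorted bytes
    n = codes.size
    u = rng.random(n)
    sub_mask = u < mm
    del_mask = (u >= mm) & (u < mm + dele)
    ins_mask = (u >= mm + dele) & (u < mm + dele + ins)
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        base_idx[sub_mask] = (base_idx[sub_mask] + shift) % 4
    out = _BASES[base_idx % 4]
    out[codes == ord("N")] = ord("N")  # never mutate N placeholders
    keep = ~del_mask
    if ins_mask.any():
        ins_at = np.flatnonzero(ins_mask & keep)
        ins_bases = _BASES[rng.integers(0, 4, size=ins_at.size)]
        pieces = np.insert(out[keep], np.searchsorted(np.flatnonzero(keep), ins_at) + 1, ins_bases)
    else:
        pieces = out[keep]
    return pieces.tobytes().decode("ascii")


def _error_to_phred(err: float) -> int:
    if err <= 0:
        return 60
    return int(np.clip(round(-10.0 * math.log10(err)), 0, 93))


def _draw_length(rng: np.random.Generator, lognorm: Tuple[float, float], min_len: int, cap: int) -> int:
    mu, sigma = lognorm
    for _ in range(100):
        ln = int(round(rng.lognormal(mu, sigma)))
        if ln >= min_len:
            return min(ln, cap)
    return min_len


def simulate_dataset(config: SimConfig) -> Tuple[List[SequenceRecord], SimTruth]:
    """Simulate one library and its ground truth.

    The number of reads is ``depth * genome_length / mean_read_len``.
    Each read is, independently, a contaminant with probability
    ``contaminant_fraction``, non-sense with probability
    ``nonsense_fraction``, otherwise genomic. Genomic reads start
    uniformly on the genome, are truncated at the genome end (redrawn if
    shorter than ``min_len``) and come from either strand equiprobably;
    errors are applied per base. Adapters are appended verbatim
    (error-free) after the error process.
    """
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config.genome_length, config.gc, int(rng.integers(2**31)))
    contaminant_genome = None
    contaminant_window = None
    if config.contaminant_fraction > 0:
        contaminant_genome = generate_genome(
            config.contaminant_genome_length, config.contaminant_gc, int(rng.integers(2**31))
        )
        wstart = int(
            rng.integers(0, config.contaminant_genome_length - config.contaminant_window_length + 1)
        )
        contaminant_window = (wstart, wstart + config.contaminant_window_length)

    n_reads = int(round(config.depth * config.genome_length / config.mean_read_len))
    if n_reads < 50:
        import warnings

        warnings.warn(
            f"only {n_reads} reads at this depth/length; fraction estimates will be unreliable",
            stacklevel=2,
        )

    base_rates = np.asarray(config.error_rates, dtype=float)
    total_rate = float(base_rates.sum())

    records: List[SequenceRecord] = []
    rows = []
    origin_draw = rng.random(n_reads)
    for i in range(n_reads):
        read_id = f"sim_{i:06d}"
        if origin_draw[i] < config.contaminant_fraction:
            origin = "contaminant"
        elif origin_draw[i] < config.contaminant_fraction + config.nonsense_fraction:
            origin = "nonsense"
        else:
            origin = "genome"

        if origin == "nonsense" and config.nonsense_mode == "random":
            lognorm = (
                SHORT_FRAGMENT_LOGNORM if config.short_fragment_mode else config.read_len_lognorm
            )
            ln = _draw_length(rng, lognorm, config.min_len, config.genome_length)
            seq = _BASES[rng.integers(0, 4, size=ln)].tobytes().decode("ascii")
            start = end = -1
            strand = "+"
            true_err = float("nan")
            qv = config.nonsense_qv
        else:
            if origin == "contaminant":
                src = contaminant_genome
                w0, w1 = contaminant_window
                ln = _draw_length(
                    rng, config.contaminant_len_lognorm, config.min_len, w1 - w0
                )
                start = int(rng.integers(w0, w1))
                end = min(start + ln, w1)
                if end - start < config.min_len:
                    start = max(w0, end - ln)
            else:
                src = genome
                ln = _draw_length(rng, config.read_len_lognorm, config.min_len, config.genome_length)
                while True:
                    start = int(rng.integers(0, config.genome_length))
                    end = min(start + ln, config.genome_length)
                    if end - start >= config.min_len:
                        break
            template = src[start:end]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                template = revcomp(template)
            if origin == "nonsense":  # high_error mode
                rates = base_rates * (HIGH_ERROR_RATE / total_rate) if total_rate > 0 else np.array(
                    [HIGH_ERROR_RATE, 0.0, 0.0]
                )
                true_err = HIGH_ERROR_RATE
                qv = config.nonsense_qv
            else:
                if config.per_read_error_range is not None:
                    lo, hi = config.per_read_error_range
                    target = float(rng.uniform(lo, hi))
                    rates = (
                        base_rates * (target / total_rate)
                        if total_rate > 0
                        else np.array([target, 0.0, 0.0])
                    )
                else:
                    rates = base_rates
                true_err = float(rates.sum())
                qv = _error_to_phred(true_err)
            seq = _apply_errors(template, tuple(rates), rng)

        adapter_left = adapter_right = 0
        if config.adapter_seq:
            if config.adapter_sides in ("left", "both"):
                seq = config.adapter_seq + seq
                adapter_left = len(config.adapter_seq)
            if config.adapter_sides in ("right", "both"):
                seq = seq + revcomp(config.adapter_seq)
                adapter_right = len(config.adapter_seq)

        quals = np.full(len(seq), qv, dtype=np.uint8)
        records.append(SequenceRecord(read_id, seq, quals))
        rows.append(
            {
                "read_id": read_id,
                "origin": origin,
                "source_start": start,
                "source_end": end,
                "strand": strand,
                "true_error": true_err,
                "adapter_left": adapter_left,
                "adapter_right": adapter_right,
                "length": len(seq),
            }
        )

    truth = SimTruth(
        reads=pd.DataFrame(rows),
        genome=genome,
        contaminant_genome=contaminant_genome,
        contaminant_window=contaminant_window,
    )
    return records, truth
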