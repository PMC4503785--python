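"""Synthetic multi-sample WGBS methylomes with planted DMRs.

The generator emulates the shape of a real whole-genome bisulfite
methylome: CpG sites at geometric spacing, per-site *true* methylation
levels drawn from a U-shaped (bimodal) Beta mixture — most CpGs are either
strongly methylated or strongly unmethylated — and observed counts drawn
per sample as binomial reads at Poisson depth. Background true levels are
shared across samples, so outside planted regions every between-sample
difference is pure sampling noise: a clean null. Inside a planted DMR each
sample's true level is overridden by the plant's per-sample targets.

:func:`score_calls` compares a called region set against the planted truth
at base level (bp intersections) and at region level (reciprocal overlap
>= 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ChromArrays, MethylomeSet


@dataclass(frozen=True)
class PlantedDMR:
    """A region whose true methylation differs between samples.

    ``levels`` gives one target true level per sample; alternatively
    ``delta`` shifts the shared background level of the region by +delta in
    the first sample (clipped into [0, 1], with a warning when clipping
    bites).
    """

    start: int  # 1-based inclusive
    end: int
    levels: tuple[float, ...] | None = None
    delta: float | None = None

    def __post_init__(self):
        if (self.levels is None) == (self.delta is None):
            raise ValueError("specify exactly one of levels / delta")
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid planted interval")


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Defaults mirror a mammalian WGBS study at desk scale: mean CpG spacing
    50 bp, Poisson coverage with mean 30 (truncated at one read), and an
    equal-weight U-shaped mixture Beta(0.5, 8) / Beta(8, 0.5) for the shared
    background levels, giving the strongly bimodal marginal typical of real
    methylomes.
    """

    genome_length: int = 1_000_000
    cpg_spacing: float = 50.0
    n_samples: int = 2
    coverage_mean: float = 30.0
    w_low: float = 0.5
    beta_low: tuple[float, float] = (0.5, 8.0)
    beta_high: tuple[float, float] = (8.0, 0.5)
    dmrs: tuple[PlantedDMR, ...] = ()
    seed: int = 0
    chrom: str = "chrSim"
    sample_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0 <= self.w_low <= 1:
            raise ValueError("w_low must lie in [0, 1]")
        if min(*self.beta_low, *self.beta_high) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        spans = sorted((d.start, d.end) for d in self.dmrs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted DMRs must not overlap")
        for d in self.dmrs:
            if d.end > self.genome_length:
                raise ValueError("planted DMR outside the genome")
            if d.levels is not None and len(d.levels) != self.n_samples:
                raise ValueError("plant levels must name one level per sample")

    @property
    def samples(self) -> tuple[str, ...]:
        if self.sample_names is not None:
            return self.sample_names
        return tuple(f"sample{i + 1}" for i in range(self.n_samples))


def simulate_methylomes(params: SimParams) -> tuple[MethylomeSet, pd.DataFrame]:
    """Draw a MethylomeSet and its truth table from ``params``.

    Fully reproducible from ``params.seed``. The truth table lists each
    planted region with its per-sample true levels and the realised
    between-sample level range.
    """
    rng = np.random.default_rng(params.seed)
    # CpG positions: geometric gaps (mean cpg_spacing, minimum 2 bp so two
    # CpGs never collide) accumulated until the chromosome end.
    mean_gap = max(params.cpg_spacing, 2.0)
    n_expect = int(params.genome_length / mean_gap * 1.3) + 16
    gaps = rng.geometric(1.0 / (mean_gap - 1.0), size=n_expect) + 1
    positions = np.cumsum(gaps)
    while positions[-1] < params.genome_length:
        extra = rng.geometric(1.0 / (mean_gap - 1.0), size=n_expect) + 1
        positions = np.concatenate([positions, positions[-1] + np.cumsum(extra)])
    positions = positions[positions <= params.genome_length].astype(np.int64)
    n = positions.size

    # shared bimodal background true levels
    low = rng.random(n) < params.w_low
    background = np.where(
        low,
        rng.beta(*params.beta_low, size=n),
        rng.beta(*params.beta_high, size=n),
    )
    true_levels = np.tile(background, (params.n_samples, 1))

    rows = []
    for dmr in params.dmrs:
        inside = (positions >= dmr.start) & (positions <= dmr.end)
        if dmr.levels is not None:
            target = np.asarray(dmr.levels, dtype=float)[:, None]
        else:
            target = np.vstack([background[inside] + dmr.delta] + [background[inside]] * (params.n_samples - 1))
        clipped = np.clip(target, 0.0, 1.0)
        if np.any(clipped != target):
            warnings.warn(
                f"planted levels clipped into [0,1] for region {dmr.start}-{dmr.end}", stacklevel=2
            )
        true_levels[:, inside] = clipped
        sample_levels = clipped.mean(axis=-1) if clipped.ndim > 1 else clipped
        row = {"chrom": params.chrom, "start": dmr.start, "end": dmr.end, "n_sites": int(inside.sum())}
        for name, lev in zip(params.samples, np.atleast_1d(sample_levels)):
            row[f"level_{name}"] = float(lev)
        row["delta"] = float(np.max(sample_levels) - np.min(sample_levels))
        rows.append(row)
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites"]
                         + [f"level_{s}" for s in params.samples] + ["delta"]) \
        if rows else pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "delta"])

    depth = np.maximum(rng.poisson(params.coverage_mean, size=(params.n_samples, n)), 1)
    meth = rng.binomial(depth, true_levels)
    unmeth = depth - meth

    chroms = {
        params.chrom: ChromArrays(
            positions=positions,
            meth=meth.astype(np.int64),
            unmeth=unmeth.astype(np.int64),
            context=np.full(n, "CG", dtype="U7"),
        )
    }
    mset = MethylomeSet(
        samples=list(params.samples),
        chroms=chroms,
        chrom_sizes={params.chrom: params.genome_length},
    )
    return mset, truth


def plant_random_dmrs(
    params: SimParams,
    n_dmrs: int,
    length_range: tuple[int, int] = (1000, 3000),
    delta_range: tuple[float, float] = (0.3, 0.6),
    min_separation: int = 5000,
    seed: int | None = None,
) -> SimParams:
    """Return ``params`` with ``n_dmrs`` random non-overlapping plants added.

    Each plant draws a length uniformly from ``length_range`` and a
    between-sample level range uniformly from ``delta_range``; per-sample
    target levels place the extreme samples delta apart around a uniformly
    drawn midpoint, intermediate samples (three or more) uniformly in
    between, with sample order shuffled so no sample is systematically
    hyper-methylated. Plants are separated by at least ``min_separation`` bp
    so merged calls cannot bridge two distinct truths.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    plants: list[PlantedDMR] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(plants) < n_dmrs:
        attempts += 1
        if attempts > 10000 * n_dmrs:
            raise RuntimeError("could not place the requested plants; genome too small")
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(1, params.genome_length - length + 1))
        end = start + length - 1
        if any(s - min_separation <= end and start <= e + min_separation for s, e in occupied):
            continue
        delta = float(rng.uniform(*delta_range))
        lo = float(rng.uniform(0.05, 0.95 - delta))
        levels = [lo, lo + delta]
        if params.n_samples > 2:
            levels += list(rng.uniform(lo, lo + delta, size=params.n_samples - 2))
        levels = np.array(levels)
        rng.shuffle(levels)
        plants.append(PlantedDMR(start=start, end=end, levels=tuple(float(x) for x in levels)))
        occupied.append((start, end))
    plants.sort(key=lambda d: d.start)
    return replace(params, dmrs=tuple(plants))


# ---------------------------------------------------------------------------
# scoring against planted truth
# ---------------------------------------------------------------------------


def _as_intervals(regions) -> list[tuple[str, int, int]]:
    out = []
    for r in regions:
        if isinstance(r, tuple):
            out.append((str(r[0]), int(r[1]), int(r[2])))
        elif isinstance(r, pd.Series) or isinstance(r, dict):
            out.append((str(r["chrom"]), int(r["start"]), int(r["end"])))
        else:
            out.append((str(r.chrom), int(r.start), int(r.end)))
    return sorted(out)


def _frame_intervals(obj) -> list[tuple[str, int, int]]:
    if isinstance(obj, pd.DataFrame):
        return sorted(zip(obj["chrom"].astype(str), obj["start"].astype(int), obj["end"].astype(int)))
    return _as_intervals(obj)


def _total_bp(iv: Sequence[tuple[str, int, int]]) -> int:
    return sum(e - s + 1 for _, s, e in iv)


def _intersect_bp(a: Sequence[tuple[str, int, int]], b: Sequence[tuple[str, int, int]]) -> int:
    total = 0
    for chrom_a, sa, ea in a:
        for chrom_b, sb, eb in b:
            if chrom_a == chrom_b:
                total += max(0, min(ea, eb) - max(sa, sb) + 1)
    return total


def score_calls(called, truth) -> dict[str, float | None]:
    """Precision/recall/F1 of a called region set against planted truth.

    Base-level metrics are computed from bp intersections; region-level
    metrics count a region as recovered when some counterpart achieves
    reciprocal overlap >= 0.5 (the intersection covers at least half of both
    regions). With empty truth, recall is undefined (``None``); with no
    calls, precision is undefined.
    """
    called_iv = _frame_intervals(called)
    truth_iv = _frame_intervals(truth)
    out: dict[str, float | None] = {}

    tp_bp = _intersect_bp(called_iv, truth_iv)
    called_bp = _total_bp(called_iv)
    truth_bp = _total_bp(truth_iv)
    out["base_precision"] = tp_bp / called_bp if called_bp else None
    out["base_recall"] = tp_bp / truth_bp if truth_bp else None

    def reciprocal(a, b):
        chrom_a, sa, ea = a
        chrom_b, sb, eb = b
        if chrom_a != chrom_b:
            return 0.0
        ov = max(0, min(ea, eb) - max(sa, sb) + 1)
        return min(ov / (ea - sa + 1), ov / (eb - sb + 1))

    if truth_iv:
        recovered = sum(1 for t in truth_iv if any(reciprocal(t, c) >= 0.5 for c in called_iv))
        out["region_recall"] = recovered / len(truth_iv)
    else:
        out["region_recall"] = None
    if called_iv:
        matched = sum(1 for c in called_iv if any(reciprocal(c, t) >= 0.5 for t in truth_iv))
        out["region_precision"] = matched / len(called_iv)
    else:
        out["region_precision"] = None

    for kind in ("base", "region"):
        p, r = out[f"{kind}_precision"], out[f"{kind}_recall"]
        out[f"{kind}_f1"] = (2 * p * r / (p + r)) if p and r else (0.0 if (p == 0 or r == 0) else None)
    return out
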