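"""Downstream summaries of a DMR set.

All reports are pure functions of (DMR set, methylomes) returning data
tables; optional matplotlib renderings are thin wrappers over the tables and
are not part of the tested surface.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import MethylomeSet


def _dmr_intervals(dmrs) -> list[tuple[str, int, int]]:
    if isinstance(dmrs, pd.DataFrame):
        if dmrs.empty:
            return []
        return [(str(c), int(s), int(e)) for c, s, e in zip(dmrs["chrom"], dmrs["start"], dmrs["end"])]
    return [(str(d.chrom), int(d.start), int(d.end)) for d in dmrs]


def length_distribution(dmrs, bin_width: int = 100) -> pd.DataFrame:
    """Histogram of DMR lengths (end - start + 1) in fixed-width bins.

    Bins are [k*bin_width, (k+1)*bin_width) with automatic range; empty
    interior bins are kept so the table plots directly. Counts always sum to
    the number of DMRs.
    """
    lengths = np.array([e - s + 1 for _, s, e in _dmr_intervals(dmrs)])
    if lengths.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lo = int(lengths.min() // bin_width) * bin_width
    hi = int(lengths.max() // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def dmr_level_matrix(
    dmrs,
    methylomes: MethylomeSet,
    mode: str = "site",
    max_rows: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Methylation level matrix underlying clustering and boxplot summaries.

    ``mode="site"``: one row per cytosine inside a DMR (per-sample level,
    NaN at depth 0), capped at ``max_rows`` rows by seeded uniform
    subsampling. ``mode="dmr"``: one row per DMR with per-sample mean
    levels over its covered sites.
    """
    if mode not in ("site", "dmr"):
        raise ValueError("mode must be 'site' or 'dmr'")
    rows = []
    index = []
    for chrom, start, end in _dmr_intervals(dmrs):
        arr = methylomes.chroms.get(chrom)
        if arr is None:
            continue
        lo = int(np.searchsorted(arr.positions, start, side="left"))
        hi = int(np.searchsorted(arr.positions, end, side="right"))
        levels = arr.levels()[:, lo:hi]
        if mode == "site":
            for j in range(levels.shape[1]):
                rows.append(levels[:, j])
                index.append((chrom, int(arr.positions[lo + j])))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-NaN columns
                rows.append(np.nanmean(levels, axis=1))
            index.append((chrom, start))
    if not rows:
        return pd.DataFrame(columns=methylomes.samples)
    mat = pd.DataFrame(rows, columns=methylomes.samples,
                       index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"]))
    if mode == "site" and len(mat) > max_rows:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(mat), size=max_rows, replace=False))
        mat = mat.iloc[keep]
    return mat


def cluster_samples(
    dmrs,
    methylomes: MethylomeSet,
    mode: str = "site",
    max_rows: int = 100_000,
    seed: int = 0,
) -> dict:
    """Complete-linkage hierarchical clustering of samples over DMR levels.

    Samples are the clustered objects; their feature vectors are the DMR
    methylation levels (per site by default, per DMR in ``mode="dmr"``).
    Distance is Euclidean over the sites where every sample has coverage.
    Ties in merge heights resolve by scipy's deterministic ordering, which
    follows sample input order. A sample with no covered level is excluded
    with a warning.

    Returns ``{"linkage": (k-1, 4) scipy linkage matrix, "samples": labels,
    "matrix": the level matrix used}``.
    """
    mat = dmr_level_matrix(dmrs, methylomes, mode=mode, max_rows=max_rows, seed=seed)
    if mat.empty:
        raise ValueError("no DMR methylation levels to cluster")
    complete = mat.dropna(axis=0)
    all_missing = [s for s in mat.columns if mat[s].isna().all()]
    cols = [s for s in mat.columns if s not in all_missing]
    if all_missing:
        warnings.warn(f"samples with no covered level excluded: {', '.join(all_missing)}", stacklevel=2)
        complete = mat[cols].dropna(axis=0)
    if len(cols) < 2:
        raise ValueError("need at least two samples with data to cluster")
    data = complete[cols].to_numpy().T  # observations = samples
    z = linkage(data, method="complete", metric="euclidean")
    return {"linkage": z, "samples": cols, "matrix": complete[cols]}


def level_summary(dmrs, methylomes: MethylomeSet) -> pd.DataFrame:
    """Per-sample five-number summary of per-DMR mean methylation levels.

    Quartiles use linear interpolation (numpy default). This is the table
    behind a per-sample boxplot of DMR methylation.
    """
    mat = dmr_level_matrix(dmrs, methylomes, mode="dmr")
    rows = []
    for sample in methylomes.samples:
        values = mat[sample].dropna().to_numpy() if sample in mat else np.array([])
        if values.size == 0:
            rows.append(dict(sample=sample, n=0, min=np.nan, q1=np.nan,
                             median=np.nan, q3=np.nan, max=np.nan))
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append(dict(sample=sample, n=int(values.size), min=float(values.min()),
                         q1=float(q1), median=float(med), q3=float(q3), max=float(values.max())))
    return pd.DataFrame(rows, columns=["sample", "n", "min", "q1", "median", "q3", "max"])


def dmr_profile(dmr, methylomes: MethylomeSet, flank_bp: int = 2000) -> pd.DataFrame:
    """Per-site methylation levels across a DMR and its flanking regions.

    Covers ``[start - flank_bp, end + flank_bp]`` (clipped at position 1 and
    the chromosome end when known) and lists every site covered in at least
    one sample; a sample without coverage at a site carries NaN.
    """
    chrom, start, end = _dmr_intervals([dmr])[0]
    arr = methylomes.chroms[chrom]
    span_start = max(1, start - flank_bp)
    span_end = end + flank_bp
    size = (methylomes.chrom_sizes or {}).get(chrom)
    if size is not None:
        span_end = min(span_end, size)
    lo = int(np.searchsorted(arr.positions, span_start, side="left"))
    hi = int(np.searchsorted(arr.positions, span_end, side="right"))
    depth = arr.depth[:, lo:hi]
    covered = np.any(depth >= 1, axis=0)
    levels = arr.levels()[:, lo:hi][:, covered]
    positions = arr.positions[lo:hi][covered]
    out = pd.DataFrame({"chrom": chrom, "pos": positions})
    for s, name in enumerate(methylomes.samples):
        out[f"level_{name}"] = levels[s]
    out["in_dmr"] = (positions >= start) & (positions <= end)
    return out
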