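"""Orchestration of the full DMR detection pass.

The pipeline runs, per chromosome: sliding-window tiling -> admission
filters -> per-window hypothesis test -> genome-wide Benjamini-Hochberg
adjustment. Windows whose adjusted p falls below the FDR cutoff are
*potential* DMRs. A left-to-right merge-and-retest extension then joins
nearby potential DMRs: a merge is accepted only if the selected test,
re-run from scratch on the union span, stays below the p cutoff; when a
merge fails, the current region is finalised and the next potential seeds a
new extension. Finalised regions are re-tested on their own span, BH-adjusted
a second time, optionally re-checked against the window effect-size criteria
on the merged span, and emitted as *candidate* DMRs when p and q clear the
cutoffs.
"""

from __future__ import annotations

import hashlib
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MethylomeSet, write_dmr_bed
from .stats import TESTS, bh_fdr, counts_test, default_test, level_test
from .windows import (
    ChromWindowTable,
    WindowParams,
    _admitted_mask,
    passes_filters,
    scan_chromosome,
    summarize_window,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    """Full configuration of a detection run.

    ``test=None`` selects Fisher's exact test for two samples and one-way
    ANOVA for three or more. ``max_gap=None`` defaults to the window step
    size: adjacent sliding windows differ by one step, so gaps below one
    step indicate the same underlying signal.
    """

    window: WindowParams = field(default_factory=WindowParams)
    test: str | None = None
    p_cutoff: float = 0.01
    fdr_cutoff: float = 0.01
    max_gap: int | None = None
    recheck_span: bool = True

    def __post_init__(self):
        if not (0 < self.p_cutoff <= 1 and 0 < self.fdr_cutoff <= 1):
            raise ValueError("cutoffs must lie in (0, 1]")
        if self.max_gap is not None and self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.test is not None and self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}; choose from {sorted(TESTS)}")

    def resolve_test(self, n_samples: int) -> str:
        name = self.test or default_test(n_samples)
        TESTS[name].check_arity(n_samples)
        return name

    @property
    def gap(self) -> int:
        return self.window.step_size if self.max_gap is None else self.max_gap


@dataclass
class DMRRegion:
    """A potential or candidate DMR with its re-test statistics."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_sites: int
    mean_level: np.ndarray
    fold_change: float
    diff: float
    p_value: float
    q_value: float | None = None
    source_window_count: int = 1
    status: str = "potential"  # potential | candidate | rejected

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_pvalue(table: ChromWindowTable, i: int, test: str) -> float:
    spec = TESTS[test]
    if spec.data_mode == "counts":
        return counts_test(table.meth_sum[:, i], table.unmeth_sum[:, i], test)
    lo, hi = table.site_lo[i], table.site_hi[i]
    levels = [table.admitted_levels[s, lo:hi] for s in range(table.admitted_levels.shape[0])]
    return level_test(levels, test)


def _evaluate_span(chrom, start, end, methylomes, params: CallerParams, test: str):
    """Re-run summary + selected test from scratch on an arbitrary span."""
    stats = summarize_window(chrom, int(start), int(end), methylomes, params.window)
    if stats.empty:
        return 1.0, stats
    spec = TESTS[test]
    arr = methylomes.chroms[chrom]
    lo = np.searchsorted(arr.positions, start, side="left")
    hi = np.searchsorted(arr.positions, end, side="right")
    admitted = _admitted_mask(arr.depth[:, lo:hi], params.window)
    meth = arr.meth[:, lo:hi][:, admitted]
    unmeth = arr.unmeth[:, lo:hi][:, admitted]
    if spec.data_mode == "counts":
        p = counts_test(meth.sum(axis=1), unmeth.sum(axis=1), test)
    else:
        with np.errstate(invalid="ignore"):
            levels = meth / np.maximum(meth + unmeth, 1)
        p = level_test(list(levels), test)
    return p, stats


def call_potential_dmrs(
    methylomes: MethylomeSet,
    params: CallerParams,
    tables: Sequence[ChromWindowTable] | None = None,
) -> tuple[list[DMRRegion], pd.DataFrame]:
    """Scan, filter, test and BH-adjust windows; return potential DMRs.

    Every window passing the admission criteria is tested; q values are
    computed by Benjamini-Hochberg across *all* tested windows genome-wide.
    Windows with q below the FDR cutoff become potential DMRs, sorted by
    (chrom, start). Also returns the per-window audit table (all generated
    windows with their summary statistics, p and q).
    """
    test = params.resolve_test(len(methylomes.samples))
    if tables is None:
        tables = [scan_chromosome(c, methylomes, params.window) for c in methylomes.chroms]

    frames = []
    tested_ps: list[float] = []
    tested_where: list[tuple[int, int]] = []  # (table index, window index)
    for t_i, table in enumerate(tables):
        df = pd.DataFrame(
            {
                "chrom": table.chrom,
                "start": table.starts,
                "end": table.ends,
                "n_sites": table.n_sites,
                "fold_change": table.fold_change,
                "diff": table.diff,
                "passed": table.passed,
                "fail_reason": table.fail_reason,
            }
        )
        for s, name in enumerate(methylomes.samples):
            df[f"mean_{name}"] = table.mean_level[s]
        df["p_value"] = np.nan
        df["q_value"] = np.nan
        for i in np.nonzero(table.passed)[0]:
            tested_ps.append(_window_pvalue(table, int(i), test))
            tested_where.append((t_i, int(i)))
        frames.append(df)

    qs = bh_fdr(tested_ps)
    potentials: list[DMRRegion] = []
    for (t_i, i), p, q in zip(tested_where, tested_ps, qs):
        table = tables[t_i]
        frames[t_i].iloc[i, frames[t_i].columns.get_loc("p_value")] = p
        frames[t_i].iloc[i, frames[t_i].columns.get_loc("q_value")] = q
        if q < params.fdr_cutoff:
            potentials.append(
                DMRRegion(
                    chrom=table.chrom,
                    start=int(table.starts[i]),
                    end=int(table.ends[i]),
                    n_sites=int(table.n_sites[i]),
                    mean_level=table.mean_level[:, i].copy(),
                    fold_change=float(table.fold_change[i]),
                    diff=float(table.diff[i]),
                    p_value=float(p),
                    q_value=float(q),
                    status="potential",
                )
            )
    audit = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    # potentials inherit chromosome input order, windows are already sorted
    return potentials, audit


def merge_extend(
    potentials: Sequence[DMRRegion],
    methylomes: MethylomeSet,
    params: CallerParams,
) -> list[DMRRegion]:
    """Greedy left-to-right merge-and-retest extension of potential DMRs.

    Two potential DMRs on the same chromosome are eligible for merging when
    the gap between them is at most ``max_gap`` (overlapping regions always
    are). Each merge is accepted only if the selected test, re-run on the
    union span with admitted sites recomputed from scratch, gives
    p < p_cutoff; a failed merge finalises the current region and seeds a new
    extension at the next potential. Final regions are BH-adjusted a second
    time and labelled candidate when p < p_cutoff, q < fdr_cutoff and (by
    default) the window effect-size criteria re-checked on the merged span
    still hold.
    """
    test = params.resolve_test(len(methylomes.samples))
    finals: list[DMRRegion] = []
    if not potentials:
        return finals

    def finalize(chrom, start, end, n_windows, prev_end) -> DMRRegion:
        if prev_end is not None and start <= prev_end:
            start = prev_end + 1  # keep finalised regions non-overlapping
        p, stats = _evaluate_span(chrom, start, end, methylomes, params, test)
        return DMRRegion(
            chrom=chrom,
            start=int(start),
            end=int(end),
            n_sites=stats.n_sites,
            mean_level=stats.mean_level,
            fold_change=stats.fold_change,
            diff=stats.diff,
            p_value=float(p),
            source_window_count=n_windows,
            status="potential",
        )

    cur = potentials[0]
    cur_chrom, cur_start, cur_end, cur_n = cur.chrom, cur.start, cur.end, 1
    prev_end_on_chrom: dict[str, int] = {}
    for nxt in potentials[1:]:
        gap = nxt.start - cur_end - 1
        if nxt.chrom == cur_chrom and gap <= params.gap:
            p_union, _ = _evaluate_span(cur_chrom, cur_start, max(cur_end, nxt.end), methylomes, params, test)
            if p_union < params.p_cutoff:
                cur_end = max(cur_end, nxt.end)
                cur_n += 1
                continue
        region = finalize(cur_chrom, cur_start, cur_end, cur_n, prev_end_on_chrom.get(cur_chrom))
        prev_end_on_chrom[cur_chrom] = region.end
        finals.append(region)
        cur_chrom, cur_start, cur_end, cur_n = nxt.chrom, nxt.start, nxt.end, 1
    region = finalize(cur_chrom, cur_start, cur_end, cur_n, prev_end_on_chrom.get(cur_chrom))
    finals.append(region)

    qs = bh_fdr([r.p_value for r in finals])
    for region, q in zip(finals, qs):
        region.q_value = float(q)
        ok = region.p_value < params.p_cutoff and q < params.fdr_cutoff
        if ok and params.recheck_span:
            stats_proxy = summarize_window(region.chrom, region.start, region.end, methylomes, params.window)
            ok = passes_filters(stats_proxy, params.window)[0]
        region.status = "candidate" if ok else "rejected"
    return finals


@dataclass
class PipelineResult:
    """Everything a detection run produces."""

    candidates: list[DMRRegion]
    all_regions: list[DMRRegion]
    potentials: list[DMRRegion]
    windows: pd.DataFrame
    summary: dict

    def candidate_frame(self, samples: Sequence[str]) -> pd.DataFrame:
        return regions_to_frame(self.candidates, samples)


def regions_to_frame(regions: Sequence[DMRRegion], samples: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "n_sites": r.n_sites,
        }
        for s, name in enumerate(samples):
            row[f"mean_{name}"] = float(r.mean_level[s]) if r.mean_level is not None else np.nan
        row.update(
            diff=r.diff,
            fold_change=r.fold_change,
            p_value=r.p_value,
            q_value=r.q_value,
            source_window_count=r.source_window_count,
            status=r.status,
        )
        rows.append(row)
    cols = ["chrom", "start", "end", "length", "n_sites"]
    cols += [f"mean_{name}" for name in samples]
    cols += ["diff", "fold_change", "p_value", "q_value", "source_window_count", "status"]
    return pd.DataFrame(rows, columns=cols)


def _digest(methylomes: MethylomeSet) -> str:
    h = hashlib.sha256()
    for chrom, arr in methylomes.chroms.items():
        h.update(chrom.encode())
        h.update(arr.positions.tobytes())
        h.update(arr.meth.tobytes())
        h.update(arr.unmeth.tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    methylomes: MethylomeSet,
    params: CallerParams | None = None,
    outdir: str | Path | None = None,
    threads: int = 1,
) -> PipelineResult:
    """Run the full detection pass and (optionally) write its outputs.

    Deterministic for fixed inputs and configuration regardless of
    ``threads``: chromosomes are scanned independently (possibly in a thread
    pool) and results are assembled in chromosome input order. With
    ``outdir`` set, writes ``dmrs.tsv``, ``dmrs.bed``, ``windows.tsv`` and
    ``summary.tsv``.
    """
    params = params or CallerParams()
    test = params.resolve_test(len(methylomes.samples))  # validate before any work
    chrom_names = list(methylomes.chroms)
    logger.info("input digest %s; test=%s; %d chromosomes", _digest(methylomes), test, len(chrom_names))

    if threads > 1 and len(chrom_names) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            futures = {c: pool.submit(scan_chromosome, c, methylomes, params.window) for c in chrom_names}
            tables = [futures[c].result() for c in chrom_names]
    else:
        tables = [scan_chromosome(c, methylomes, params.window) for c in chrom_names]

    potentials, audit = call_potential_dmrs(methylomes, params, tables=tables)
    finals = merge_extend(potentials, methylomes, params)
    candidates = [r for r in finals if r.status == "candidate"]

    summary = {
        "n_samples": len(methylomes.samples),
        "test": test,
        "windows_generated": int(len(audit)),
        "windows_passed_filters": int(audit["passed"].sum()) if len(audit) else 0,
        "windows_tested": int(audit["p_value"].notna().sum()) if len(audit) else 0,
        "potential_dmrs": len(potentials),
        "merged_regions": len(finals),
        "candidate_dmrs": len(candidates),
    }
    logger.info("count funnel: %s", summary)

    result = PipelineResult(candidates, finals, potentials, audit, summary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        regions_to_frame(finals, methylomes.samples).to_csv(outdir / "regions.tsv", sep="\t", index=False)
        regions_to_frame(candidates, methylomes.samples).to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        write_dmr_bed(candidates, outdir / "dmrs.bed")
        audit.to_csv(outdir / "windows.tsv", sep="\t", index=False, float_format="%.6g")
        pd.Series(summary).to_csv(outdir / "summary.tsv", sep="\t", header=False)
    return result
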