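"""Hypothesis tests on window methylation data and BH false-discovery control.

Six selectable tests are provided. The two count-based tests (Fisher exact,
chi-square) compare the methylated/unmethylated read counts pooled over a
window's admitted sites between exactly two samples. The four level-based
tests (paired t, Wilcoxon signed-rank, one-way ANOVA, Kruskal-Wallis) treat
the per-site methylation levels at the admitted sites as observations; t and
Wilcoxon are paired across matched sites (sites are shared between samples
by construction), ANOVA and Kruskal-Wallis accept two or more samples.

All p values are two-sided: a region is differentially methylated whether it
gains or loses methylation. Degenerate inputs (zero variance everywhere,
all-zero tables) yield p = 1.0 rather than NaN so a genome scan never
aborts mid-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestSpec:
    """A selectable hypothesis test: name, sample-count requirement, data mode."""

    name: str
    arity: str  # "two" (exactly 2 samples) or "multi" (>= 2)
    data_mode: str  # "counts" or "levels"

    def check_arity(self, n_samples: int) -> None:
        if n_samples < 2:
            raise ValueError("hypothesis tests require at least two samples")
        if self.arity == "two" and n_samples != 2:
            raise ValueError(
                f"test {self.name!r} compares exactly two samples, got {n_samples}; "
                "use anova or kruskal for three or more"
            )


TESTS: dict[str, TestSpec] = {
    "fisher": TestSpec("fisher", "two", "counts"),
    "chisq": TestSpec("chisq", "two", "counts"),
    "ttest": TestSpec("ttest", "two", "levels"),
    "wilcoxon": TestSpec("wilcoxon", "two", "levels"),
    "anova": TestSpec("anova", "multi", "levels"),
    "kruskal": TestSpec("kruskal", "multi", "levels"),
}


def default_test(n_samples: int) -> str:
    """Fisher exact for two samples, one-way ANOVA for three or more."""
    return "fisher" if n_samples == 2 else "anova"


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of pooled meth/unmeth counts.

    The p value is the sum of hypergeometric probabilities, at the observed
    margins, of all tables as or less probable than the observed one (ties
    resolved with a small relative tolerance). An all-zero table has a single
    attainable configuration, hence p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if t.sum() == 0:
        warnings.warn("all-zero contingency table; p = 1.0", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def chisq_2x2(table: Sequence[Sequence[int]], yates: bool = False) -> float:
    """Pearson chi-square p (1 df) for a 2x2 table, no continuity correction
    by default.

    When any expected count falls below 1 the asymptotic approximation is
    unreliable, so the test falls back to :func:`fisher_exact_2x2` with a
    warning. Degenerate margins (an empty row or column) give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    n = t.sum()
    if n == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if np.any(expected < 1):
        warnings.warn("expected count < 1; falling back to Fisher exact test", stacklevel=2)
        return fisher_exact_2x2(t)
    res = sps.chi2_contingency(t, correction=yates)
    return float(res.pvalue)


def level_test(levels_by_sample: Sequence[np.ndarray], test: str) -> float:
    """Two-sided p for per-site methylation levels across samples.

    ``levels_by_sample`` holds one equal-length vector per sample over the
    window's admitted sites. ``ttest`` and ``wilcoxon`` are paired on the
    shared sites (two samples); ``anova``/``kruskal`` treat the per-site
    levels of each sample as one group. Wilcoxon uses the exact signed-rank
    null for n <= 25 and the tie-corrected normal approximation beyond.
    """
    spec = TESTS[test]
    if spec.data_mode != "levels":
        raise ValueError(f"{test!r} is a count test; use fisher_exact_2x2/chisq_2x2")
    groups = [np.asarray(g, dtype=float) for g in levels_by_sample]
    spec.check_arity(len(groups))
    lengths = {g.size for g in groups}
    if test in ("ttest", "wilcoxon") and len(lengths) != 1:
        raise ValueError("paired tests require the same admitted sites in both samples")
    if any(g.size == 0 for g in groups):
        return 1.0

    if test == "ttest":
        d = groups[0] - groups[1]
        if np.allclose(d, d[0]) and np.isclose(d[0], 0):
            return 1.0  # all paired differences zero
        if np.allclose(d, d.mean()):
            return 0.0 if d.size > 1 else 1.0  # constant nonzero shift
        return float(sps.ttest_rel(groups[0], groups[1]).pvalue)
    if test == "wilcoxon":
        d = groups[0] - groups[1]
        if np.allclose(d, 0):
            return 1.0
        method = "exact" if d.size <= 25 else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on zero-differences/ties
            return float(sps.wilcoxon(groups[0], groups[1], method=method).pvalue)
    # anova / kruskal
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return 1.0  # zero variance in every group
    if test == "anova":
        if all(np.allclose(g, g.mean()) for g in groups):
            return 0.0  # between-group variance only
        return float(sps.f_oneway(*groups).pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.kruskal(*groups).pvalue)


def counts_test(meth_sums: Sequence[int], unmeth_sums: Sequence[int], test: str) -> float:
    """Dispatch a count test on pooled per-sample (meth, unmeth) sums."""
    if len(meth_sums) != 2:
        raise ValueError("count tests compare exactly two samples")
    table = [[int(meth_sums[0]), int(unmeth_sums[0])], [int(meth_sums[1]), int(unmeth_sums[1])]]
    return fisher_exact_2x2(table) if test == "fisher" else chisq_2x2(table)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, in the input order.

    With m p values sorted ascending, q(i) = min_{j >= i} (m * p(j) / j),
    capped at 1; this guarantees q >= p and monotonicity along the sorted
    order. An empty input returns an empty array.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
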