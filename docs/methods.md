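# Methods

## Model and procedure

`dmrscan` treats DMR detection as a screen over a dense tiling of
fixed-width windows rather than an explicit segmentation model. The
quantity of interest at a cytosine in one sample is the methylation level
m/(m+u), the binomial proportion of methylated read observations. Without
biological replicates there is no between-individual variance estimate, so
evidence for a region-level difference must come either from the pooled
read counts (count tests) or from treating the per-site levels within a
window as repeated observations of the regional level (level tests). Both
routes are offered; their assumptions differ and are worth stating:

- **Fisher exact / χ²** pool the meth/unmeth counts over a window's
  admitted sites into one 2×2 table per window. This treats reads as
  exchangeable within the window and is sensitive at high coverage; it is
  the default for two samples.
- **Paired t / Wilcoxon signed-rank** use the per-site level differences
  across the matched site set (sites are shared between samples by
  construction, since admission requires depth in every sample). Pairing
  removes between-site level variance — substantial in a bimodal methylome
  — from the error term.
- **One-way ANOVA / Kruskal–Wallis** treat each sample's per-site levels
  as one group and so extend to any number of samples; ANOVA is the
  default for three or more.

All tests are two-sided: hyper- and hypo-methylation are symmetric
discoveries. The per-window p values are adjusted with Benjamini–Hochberg
over exactly the windows that were tested (those passing admission), not
over all generated windows; testing only admissible windows and adjusting
across that family is the literal workflow the screen implements.

### Window admission

A window enters testing only if (a) every used cytosine has depth ≥
`min_depth` in every sample, (b) at least `min_sites` cytosines survive,
and (c) the window mean levels of the extreme samples differ by ≥
`min_diff` absolutely and ≥ `min_fold` as a ratio. All thresholds are
inclusive (≥) by default with a strict (>) mode available. The window mean
is the unweighted mean of per-site levels, making it robust to per-site
depth variation; a depth-pooled alternative (`level_mode="pooled"`) is
provided. Sites absent from one sample carry depth 0 there and can never be
admitted; the admission depth is floored at one read so per-site levels are
always defined.

### Merge-and-retest extension

Windows with q below the FDR cutoff (potential DMRs) are merged
left-to-right: while the next potential on the same chromosome is within
`max_gap` (overlap always qualifies), the selected test is re-run from
scratch — admitted sites recomputed — on the union span; the union is
accepted only if its re-tested p stays below `p_cutoff`. A failed union is
discarded (never emitted), the current region is finalised, and the next
potential seeds a new extension. Finalised regions are re-tested on their
own span, BH-adjusted a second time across the final regions, optionally
re-checked against the admission criteria on the merged span (on by
default, so merging can never dilute a region below the effect-size
thresholds), and labelled candidate when p and q clear the cutoffs.

Two reconstruction choices deserve note. First, FDR is applied twice —
across tested windows to define potentials, and across final merged regions
to attach a defensible q to each candidate; the second pass is conservative
and changes nothing when merging is idle. Second, a rejected union between
*overlapping* potentials would otherwise leave two overlapping final
regions; the later region's start is clipped to the earlier region's end +
1 so the candidate set is always disjoint. The situation requires two
overlapping windows whose union is less significant than either part
(opposite-direction signal within one window width) and is vanishingly rare
in practice.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` | 1000 bp | width of the sliding window |
| `step_size` | 100 bp | window advance; w/s = 10 overlapping tiles per base |
| `min_depth` | 4 reads | per-site, per-sample admission depth (suited to ~30X data) |
| `min_sites` | 5 | admitted CpGs per window |
| `min_fold` | 1.5 | extreme-sample mean-level ratio |
| `min_diff` | 0.2 | extreme-sample mean-level difference |
| `p_cutoff` | 0.01 | window/union/candidate p threshold |
| `fdr_cutoff` | 0.01 | BH q threshold (potentials and candidates) |
| `max_gap` | = step | merge eligibility distance; below one step, two potentials reflect the same signal |

The fold change is undefined when the least methylated sample's mean is
exactly 0; both means are floored at ε = 0.001 for the ratio only (a 0.5
vs 0.0 window folds to 500 and passes any threshold; two zeros fold to 1).
The difference criterion never sees the floor.

Trailing windows at a chromosome end are clipped, not dropped, and still
face `min_sites`. Coordinates are 1-based inclusive throughout (matching
Bismark input); only BED output converts to 0-based half-open. Symmetric
CpG dyads are *not* merged by default — each input row is one site — with
`collapse_cpg_dyads` available as an opt-in preprocessing step.

## Synthetic methylomes

The simulator emulates the statistical shape of a mammalian WGBS
comparison, not its sequence context: CpG positions with geometric spacing
(mean 50 bp, minimum 2), per-site true levels drawn once from an
equal-weight Beta(0.5, 8) / Beta(8, 0.5) mixture — the strongly U-shaped
marginal of real methylomes — and **shared across samples**, so that outside
planted regions every between-sample difference is pure binomial sampling
noise at Poisson(30) depth (truncated at one read). Planted DMRs override
the per-sample true levels on their span; `plant_random_dmrs` draws lengths
uniformly from 1–3 kb and a between-sample level range uniformly from
0.3–0.6 around a uniform midpoint, shuffling sample assignment so no
sample is systematically hyper-methylated, with ≥ 5 kb separation so calls
cannot bridge two truths.

What this does **not** model: read-level artefacts (incomplete bisulfite
conversion, mapping bias), strand structure, CpG-island clustering,
copy-number variation, or genuinely replicate-level biological variance.
Passing recovery tests on these simulations therefore demonstrates the
statistical machinery — admission, testing, FDR, merging — under a clean
null and clean plants, not robustness to real-data artefacts.

## Verification and problem sizes

Core numerics are verified against independent brute-force oracles: the
Fisher p against full hypergeometric enumeration in exact rational
arithmetic (agreement to < 1e-9 over random tables), BH against the literal
step-up definition, window summaries against a naive per-record loop,
annotation against an O(n·m) all-pairs scan, and complete-linkage heights
against a naive agglomeration. End-to-end behaviour is checked on seeded
simulations: 2 Mb nulls across 20 seeds for false-positive control and
5 Mb genomes with 20 planted DMRs for recovery — sizes chosen so the whole
verification suite completes in well under a minute while each run still
contains ~10⁵ CpGs and ~5×10⁴ windows. The vectorised chromosome scan
(prefix sums over admitted sites; O(1) per window) is asserted equal to the
naive per-window route.

## Known limitations

- **Boundary resolution.** A candidate's span is the union of the 1 kb
  windows that passed admission and FDR. A window overlapping a true DMR
  edge passes whenever roughly `min_diff`/Δ of its admitted sites lie
  inside a region of level difference Δ, so calls systematically overhang
  true boundaries by up to `window_size · (1 − min_diff/Δ)` bp per side
  (a few hundred bp at typical Δ). On planted-truth simulations this caps
  base-level precision near 0.7 even when every region is recovered
  exactly at region level; base-level recall is unaffected. Shrinking
  `window_size` sharpens boundaries at the cost of per-window site counts.
- Count tests assume read exchangeability within a window; overdispersion
  between sites inflates significance relative to a beta-binomial
  treatment. The level tests are the conservative alternative.
- No smoothing, no dispersion shrinkage, no HMM segmentation: single-site
  noise is handled only through windowing and depth filters.
- Enrichment is per-base binomial, length-aware but ignoring the spatial
  autocorrelation of DMR placement; its p values are anti-conservative for
  few, long DMRs and are best read descriptively alongside the ratio.
- The clustering observation matrix uses only sites with coverage in every
  retained sample (complete rows) and subsamples uniformly (seeded) above
  100,000 rows.
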