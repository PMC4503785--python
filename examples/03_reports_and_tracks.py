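"""Summarise a DMR set: length histogram, sample clustering, boxplot
statistics, a flanking methylation profile and a WIG browser track.

Simulates a three-sample methylome (one sample drifted inside four planted
regions), calls DMRs with one-way ANOVA, then runs every reporting utility
on the result.
"""

import tempfile
from pathlib import Path

from dmrscan import (
    SimParams,
    cluster_samples,
    dmr_profile,
    length_distribution,
    level_summary,
    plant_random_dmrs,
    run_pipeline,
    simulate_methylomes,
    write_wig,
)

params = plant_random_dmrs(
    SimParams(genome_length=1_000_000, n_samples=3, seed=11), n_dmrs=4
)
methylomes, truth = simulate_methylomes(params)
result = run_pipeline(methylomes)
dmrs = result.candidates
print(f"{len(dmrs)} candidate DMRs called with {result.summary['test']}")

print("\nlength distribution (bp bins):")
print(length_distribution(dmrs).to_string(index=False))

clust = cluster_samples(dmrs, methylomes)
print("\ncomplete-linkage merges (left, right, height, size):")
for row in clust["linkage"]:
    print("  ", [round(float(x), 3) for x in row])
# heights are Euclidean distances between sample level vectors over DMR
# sites; the first merge joins the two most similar samples.

print("\nper-sample five-number summary of DMR methylation:")
print(level_summary(dmrs, methylomes).round(3).to_string(index=False))

profile = dmr_profile(dmrs[0], methylomes, flank_bp=2000)
inside = profile["in_dmr"].sum()
print(f"\nprofile of {dmrs[0].chrom}:{dmrs[0].start}-{dmrs[0].end}: "
      f"{len(profile)} sites in span, {inside} inside the DMR")
print(profile.head(3).round(3).to_string(index=False))

with tempfile.TemporaryDirectory() as tmp:
    wig = Path(tmp) / "sample1.wig"
    write_wig(methylomes.sample_levels("sample1"), wig, track_name="sample1")
    head = wig.read_text().splitlines()[:4]
print("\nWIG track head (variableStep, level per CpG):")
print("\n".join(head))
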