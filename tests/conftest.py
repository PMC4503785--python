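import numpy as np
import pytest

from dmrscan.io import ChromArrays, MethylomeSet


def make_methylome(sites_by_sample, chrom_sizes=None):
    """Build a MethylomeSet from {sample: [(chrom, pos, meth, unmeth), ...]}."""
    per_sample = {}
    chrom_order = []
    for name, sites in sites_by_sample.items():
        by_chrom = {}
        for chrom, pos, m, u in sites:
            by_chrom.setdefault(chrom, {})[pos] = (m, u)
            if chrom not in chrom_order:
                chrom_order.append(chrom)
        per_sample[name] = by_chrom
    samples = list(sites_by_sample)
    chroms = {}
    for chrom in chrom_order:
        union = sorted({p for s in samples for p in per_sample[s].get(chrom, {})})
        positions = np.array(union, dtype=np.int64)
        meth = np.zeros((len(samples), len(union)), dtype=np.int64)
        unmeth = np.zeros_like(meth)
        for si, s in enumerate(samples):
            for pi, pos in enumerate(union):
                if pos in per_sample[s].get(chrom, {}):
                    meth[si, pi], unmeth[si, pi] = per_sample[s][chrom][pos]
        chroms[chrom] = ChromArrays(positions, meth, unmeth, np.full(len(union), "CG", dtype="U7"))
    return MethylomeSet(samples=samples, chroms=chroms, chrom_sizes=chrom_sizes)


def uniform_region_sites(chrom, start, end, spacing, meth, unmeth):
    """Evenly spaced sites with constant counts over [start, end]."""
    return [(chrom, pos, meth, unmeth) for pos in range(start, end + 1, spacing)]


@pytest.fixture
def two_sample_planted():
    """Deterministic two-sample methylome: 0.9 vs 0.1 over chr1:1001-3000,
    flat 0.5 vs 0.5 background elsewhere, sites every 50 bp, depth 20."""
    background_a = uniform_region_sites("chr1", 1, 1000, 50, 10, 10)
    background_b = uniform_region_sites("chr1", 3001, 5000, 50, 10, 10)
    plant_hi = uniform_region_sites("chr1", 1001, 3000, 50, 18, 2)
    plant_lo = uniform_region_sites("chr1", 1001, 3000, 50, 2, 18)
    return make_methylome(
        {
            "hyper": background_a + plant_hi + background_b,
            "hypo": background_a + plant_lo + background_b,
        },
        chrom_sizes={"chr1": 5000},
    )
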