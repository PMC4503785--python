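"""Annotation of DMRs against gene models and feature enrichment.

A :class:`FeatureModel` holds typed genomic intervals (gene, exon, CDS,
5-UTR, 3-UTR, intron, promoter, upstream, downstream) read from GFF3/GTF/BED.
Features the annotation does not spell out are derived: introns are the gene
span minus its exons; the promoter is the strand-aware interval from 1300 bp
upstream to 200 bp downstream of the TSS; upstream/downstream flanks default
to 2 kb beyond the gene (the upstream flank excludes the promoter interval so
the two types do not double-count bases in enrichment).

DMR-feature intersection uses an interval-tree index and is verified against
a brute-force all-pairs scan in the test suite. Enrichment compares the
fraction of DMR bases falling in a feature type with the fraction of the
genome that type occupies, with a two-sided binomial test per type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binomtest

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "type", "gene_id"]

#: promoter extent around the TSS, strand-aware
PROMOTER_UPSTREAM = 1300
PROMOTER_DOWNSTREAM = 200


def promoter_interval(
    tss: int,
    strand: str,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_size: int | None = None,
) -> tuple[int, int]:
    """Strand-aware promoter [start, end] (1-based inclusive) around a TSS.

    A + strand gene with TSS t gets [t - upstream, t + downstream]; a −
    strand gene the mirror image [t - downstream, t + upstream]. Clipped at
    position 1 and, when known, the chromosome end.
    """
    if strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        start, end = tss - upstream, tss + downstream
    start = max(1, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return start, end


@dataclass
class FeatureModel:
    """Typed feature intervals plus a per-chromosome interval index."""

    features: pd.DataFrame  # FEATURE_COLUMNS, 1-based inclusive coordinates
    chrom_sizes: dict[str, int] | None = None
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.features = self.features.reset_index(drop=True)
        for chrom, sub in self.features.groupby("chrom", sort=False):
            tree = IntervalTree()
            for row_i, start, end in zip(sub.index, sub["start"], sub["end"]):
                tree.addi(int(start), int(end) + 1, row_i)  # half-open internally
            self._index[chrom] = tree

    @property
    def types(self) -> list[str]:
        return sorted(self.features["type"].unique())

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """All features overlapping [start, end] by >= 1 bp."""
        tree = self._index.get(chrom)
        if tree is None:
            return self.features.iloc[0:0]
        hits = sorted(iv.data for iv in tree.overlap(start, end + 1))
        return self.features.loc[hits]

    def type_bp(self, feature_type: str) -> int:
        """Bases covered by a feature type (union of its intervals, clipped)."""
        sub = self.features[self.features["type"] == feature_type]
        total = 0
        for chrom, group in sub.groupby("chrom", sort=False):
            size = (self.chrom_sizes or {}).get(chrom)
            iv = [(int(s), int(e)) for s, e in zip(group["start"], group["end"])]
            total += _union_bp(iv, size)
        return total


def _union_bp(intervals: Sequence[tuple[int, int]], chrom_size: int | None = None) -> int:
    """Total bases in the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    clipped = []
    for s, e in intervals:
        s = max(1, s)
        if chrom_size is not None:
            e = min(e, chrom_size)
        if e >= s:
            clipped.append((s, e))
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(clipped):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# building the model from GFF/GTF/BED
# ---------------------------------------------------------------------------

_UTR5 = {"five_prime_utr", "five_prime_UTR", "5UTR", "5'-UTR", "5-UTR"}
_UTR3 = {"three_prime_utr", "three_prime_UTR", "3UTR", "3'-UTR", "3-UTR"}


def build_feature_model(
    annotation_path: str | Path,
    fmt: str | None = None,
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    chrom_sizes: Mapping[str, int] | None = None,
) -> FeatureModel:
    """Read a gene annotation and derive the full feature catalogue.

    ``fmt`` defaults from the file extension (gff/gff3/gtf/bed). For GFF/GTF
    the gene/transcript/exon hierarchy is resolved with gffutils; introns,
    promoters and up/downstream flanks are derived from it. Promoters are
    taken per transcript TSS and deduplicated per gene; genes without a
    strand get no promoter (with a warning). BED input yields untyped
    ``region`` features (name column as gene_id) plus derived promoters and
    flanks when a strand column is present.
    """
    path = Path(annotation_path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"gff": "gff", "gff3": "gff", "gtf": "gtf", "bed": "bed"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}; pass fmt=")
    sizes = dict(chrom_sizes) if chrom_sizes else None

    if fmt == "bed":
        rows = _read_bed_features(path)
    else:
        rows = _read_gxf_features(path, fmt)

    derived = _derive_features(
        rows, upstream_bp, downstream_bp, promoter_upstream, promoter_downstream, sizes
    )
    features = pd.DataFrame(rows + derived, columns=FEATURE_COLUMNS)
    features = features.sort_values(["chrom", "start", "end", "type"], kind="stable")
    return FeatureModel(features=features, chrom_sizes=sizes)


def _read_bed_features(path: Path) -> list[dict]:
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least chrom/start/end columns")
    bed = raw.iloc[:, : min(6, raw.shape[1])]
    bed.columns = ["chrom", "start", "end", "name", "score", "strand"][: bed.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in bed.columns:
            bed[col] = default
    rows = []
    for rec in bed.itertuples(index=False):
        strand = rec.strand if rec.strand in ("+", "-") else "."
        rows.append(
            dict(chrom=str(rec.chrom), start=int(rec.start) + 1, end=int(rec.end),
                 strand=strand, type="region", gene_id=str(rec.name))
        )
    return rows


def _read_gxf_features(path: Path, fmt: str) -> list[dict]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=False,
        disable_infer_transcripts=False,
    )
    rows: list[dict] = []

    def gene_id_of(feat):
        for key in ("gene_id", "ID", "Name", "gene_name"):
            if key in feat.attributes:
                return feat.attributes[key][0]
        return feat.id

    type_map = {"exon": "exon", "CDS": "CDS"}
    for t in _UTR5:
        type_map[t] = "5-UTR"
    for t in _UTR3:
        type_map[t] = "3-UTR"

    for gene in db.features_of_type("gene"):
        gid = gene_id_of(gene)
        rows.append(dict(chrom=gene.seqid, start=gene.start, end=gene.end,
                         strand=gene.strand or ".", type="gene", gene_id=gid))
        exons = []
        for child in db.children(gene):
            ftype = type_map.get(child.featuretype)
            if ftype is None:
                continue
            rows.append(dict(chrom=child.seqid, start=child.start, end=child.end,
                             strand=child.strand or ".", type=ftype, gene_id=gid))
            if ftype == "exon":
                exons.append((child.start, child.end))
        for intron in _introns_of(gene.start, gene.end, exons):
            rows.append(dict(chrom=gene.seqid, start=intron[0], end=intron[1],
                             strand=gene.strand or ".", type="intron", gene_id=gid))
    return rows


def _introns_of(gene_start: int, gene_end: int, exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gene span minus exons (only defined when exons exist)."""
    if not exons:
        return []
    introns = []
    cursor = gene_start
    for s, e in _merge_intervals(exons):
        if s > cursor:
            introns.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= gene_end:
        introns.append((cursor, gene_end))
    return introns


def _derive_features(
    rows: list[dict],
    upstream_bp: int,
    downstream_bp: int,
    promoter_upstream: int,
    promoter_downstream: int,
    sizes: Mapping[str, int] | None,
) -> list[dict]:
    """Promoters and up/downstream flanks for every stranded gene/region."""
    derived: list[dict] = []
    seen_promoters: set[tuple] = set()
    anchor_types = {"gene", "region"}
    for row in rows:
        if row["type"] not in anchor_types:
            continue
        strand = row["strand"]
        if strand not in ("+", "-"):
            warnings.warn(f"feature {row['gene_id']} has no strand; promoter skipped", stacklevel=2)
            continue
        size = (sizes or {}).get(row["chrom"])
        tss = row["start"] if strand == "+" else row["end"]
        tes = row["end"] if strand == "+" else row["start"]
        prom = promoter_interval(tss, strand, promoter_upstream, promoter_downstream, size)
        key = (row["chrom"], row["gene_id"], prom)
        if key not in seen_promoters:
            seen_promoters.add(key)
            derived.append(dict(chrom=row["chrom"], start=prom[0], end=prom[1],
                                strand=strand, type="promoter", gene_id=row["gene_id"]))
        # upstream flank: the stretch 5' of the promoter, so the two types
        # never claim the same base
        if strand == "+":
            up = (tss - upstream_bp, min(tss - 1, tss - promoter_upstream - 1))
            down = (tes + 1, tes + downstream_bp)
        else:
            up = (max(tss + 1, tss + promoter_upstream + 1), tss + upstream_bp)
            down = (tes - downstream_bp, tes - 1)
        for ftype, (s, e) in (("upstream", up), ("downstream", down)):
            s = max(1, s)
            if size is not None:
                e = min(e, size)
            if e >= s:
                derived.append(dict(chrom=row["chrom"], start=s, end=e,
                                    strand=strand, type=ftype, gene_id=row["gene_id"]))
    return derived


# ---------------------------------------------------------------------------
# DMR annotation and enrichment
# ---------------------------------------------------------------------------


def _dmr_intervals(dmrs) -> list[tuple[str, int, int]]:
    if isinstance(dmrs, pd.DataFrame):
        if dmrs.empty:
            return []
        return [(str(c), int(s), int(e)) for c, s, e in zip(dmrs["chrom"], dmrs["start"], dmrs["end"])]
    return [(str(d.chrom), int(d.start), int(d.end)) for d in dmrs]


def annotate_dmrs(dmrs, model: FeatureModel) -> pd.DataFrame:
    """Overlap every DMR with every feature it touches (>= 1 bp).

    Returns one row per (DMR, feature) pair with the overlap width; a DMR
    overlapping nothing contributes no rows. Chromosomes present in the DMR
    set but absent from the annotation trigger one summary warning.
    """
    intervals = _dmr_intervals(dmrs)
    missing = sorted({c for c, _, _ in intervals} - set(model._index))
    if missing:
        warnings.warn(f"chromosomes absent from the annotation: {', '.join(missing)}", stacklevel=2)
    rows = []
    for k, (chrom, start, end) in enumerate(intervals, start=1):
        for feat in model.overlapping(chrom, start, end).itertuples(index=False):
            ov = min(end, feat.end) - max(start, feat.start) + 1
            rows.append(
                dict(dmr_id=f"DMR_{k}", chrom=chrom, dmr_start=start, dmr_end=end,
                     feature_type=feat.type, gene_id=feat.gene_id,
                     feature_start=feat.start, feature_end=feat.end, overlap_bp=int(ov))
            )
    return pd.DataFrame(
        rows, columns=["dmr_id", "chrom", "dmr_start", "dmr_end", "feature_type",
                       "gene_id", "feature_start", "feature_end", "overlap_bp"],
    )


def genes_with_promoter_dmrs(annotations: pd.DataFrame) -> pd.DataFrame:
    """Genes whose promoter overlaps at least one DMR, with the DMR ids."""
    prom = annotations[annotations["feature_type"] == "promoter"]
    if prom.empty:
        return pd.DataFrame(columns=["gene_id", "n_dmrs", "dmr_ids"])
    grouped = prom.groupby("gene_id")["dmr_id"].agg(lambda ids: sorted(set(ids)))
    return pd.DataFrame(
        {"gene_id": grouped.index, "n_dmrs": grouped.map(len).values,
         "dmr_ids": grouped.map(",".join).values}
    ).reset_index(drop=True)


def feature_enrichment(
    dmrs,
    model: FeatureModel,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Observed/expected base-level enrichment of DMRs per feature type.

    For each type: observed = fraction of DMR bases overlapping the type's
    interval union; expected = fraction of the genome the type covers;
    ratio = observed / expected; p from a two-sided binomial test of the
    observed DMR bases against the expected proportion. Types with zero
    genomic bases are skipped.
    """
    sizes = dict(chrom_sizes or model.chrom_sizes or {})
    if not sizes:
        raise ValueError("chromosome sizes are required for enrichment")
    genome_bp = sum(sizes.values())
    intervals = _dmr_intervals(dmrs)
    dmr_bp = sum(e - s + 1 for _, s, e in intervals)

    rows = []
    for ftype in model.types:
        f_bp = model.type_bp(ftype)
        if f_bp == 0:
            continue
        sub = model.features[model.features["type"] == ftype]
        observed = 0
        for chrom, group in sub.groupby("chrom", sort=False):
            merged = _merge_intervals(zip(group["start"].astype(int), group["end"].astype(int)))
            for c, s, e in intervals:
                if c != chrom:
                    continue
                for fs, fe in merged:
                    observed += max(0, min(e, fe) - max(s, fs) + 1)
        expected_frac = f_bp / genome_bp
        observed_frac = observed / dmr_bp if dmr_bp else np.nan
        ratio = observed_frac / expected_frac if dmr_bp else np.nan
        p = binomtest(observed, dmr_bp, expected_frac).pvalue if dmr_bp else np.nan
        rows.append(
            dict(feature_type=ftype, feature_bp=f_bp, dmr_bp=dmr_bp, observed_bp=observed,
                 observed_frac=observed_frac, expected_frac=expected_frac, ratio=ratio, p_value=p)
        )
    return pd.DataFrame(
        rows, columns=["feature_type", "feature_bp", "dmr_bp", "observed_bp",
                       "observed_frac", "expected_frac", "ratio", "p_value"],
    )
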