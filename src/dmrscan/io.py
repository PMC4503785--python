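"""Input/output for per-cytosine methylation tables and browser tracks.

Readers stream :class:`CytosineRecord` rows from generic tab-separated
methylation tables and from Bismark coverage / cytosine-report files.
:class:`MethylomeSet` aligns several samples on a shared coordinate system
(sites absent in a sample are carried with zero depth). Writers emit
variableStep WIG tracks, BED6 DMR tracks and round-trippable TSV tables.

Coordinate conventions: all input and in-memory coordinates are 1-based and
intervals are inclusive ``[start, end]``; BED output converts to 0-based
half-open, as the format requires.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

VALID_CONTEXTS = ("CG", "CHG", "CHH")
UNKNOWN = "unknown"

#: default column order of the generic methylation TSV
DEFAULT_COLUMNS = ("chrom", "pos", "strand", "context", "meth_count", "unmeth_count")


class ParseError(ValueError):
    """Raised when a methylation table row cannot be interpreted."""


class CytosineRecord(NamedTuple):
    """One cytosine in one sample: coordinate, sequence context and read counts.

    ``meth_count`` counts reads supporting a methylated C (read as C after
    bisulfite conversion); ``unmeth_count`` counts converted reads (read as T).
    ``depth`` is their sum and ``level`` = meth_count / depth is defined only
    for depth > 0.
    """

    chrom: str
    pos: int
    context: str
    strand: str
    meth_count: int
    unmeth_count: int

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float:
        d = self.depth
        if d == 0:
            raise ValueError(f"methylation level undefined at depth 0 ({self.chrom}:{self.pos})")
        return self.meth_count / d


def _check_record(rec: CytosineRecord, lineno: int, path) -> CytosineRecord:
    if rec.meth_count < 0 or rec.unmeth_count < 0:
        raise ParseError(f"{path}:{lineno}: negative count")
    if rec.pos < 1:
        raise ParseError(f"{path}:{lineno}: position must be >= 1, got {rec.pos}")
    return rec


def read_cytosine_table(
    path,
    sample_name: str = "",
    context_filter: Sequence[str] | None = ("CG",),
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> Iterator[CytosineRecord]:
    """Stream records from a generic tab-separated methylation table.

    Parameters
    ----------
    path
        TSV with one cytosine per row. Column order is configurable via
        ``columns`` (names from ``chrom, pos, strand, context, meth_count,
        unmeth_count``; unused input columns may be named ``-``).
    context_filter
        Contexts to keep (subset of CG/CHG/CHH); ``None`` keeps everything.
    """
    colidx = {name: i for i, name in enumerate(columns) if name != "-"}
    for required in ("chrom", "pos", "meth_count", "unmeth_count"):
        if required not in colidx:
            raise ValueError(f"column map must include {required!r}")
    keep = None if context_filter is None else frozenset(context_filter)
    nrows = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#") or row[0] == "track":
                continue
            if len(row) < len(columns):
                raise ParseError(f"{path}:{lineno}: expected {len(columns)} columns, got {len(row)}")
            nrows += 1
            context = row[colidx["context"]].strip() if "context" in colidx else UNKNOWN
            if context not in VALID_CONTEXTS and context != UNKNOWN:
                raise ParseError(f"{path}:{lineno}: unknown cytosine context {context!r}")
            if keep is not None and context not in keep:
                continue
            try:
                rec = CytosineRecord(
                    chrom=row[colidx["chrom"]].strip(),
                    pos=int(row[colidx["pos"]]),
                    context=context,
                    strand=row[colidx["strand"]].strip() if "strand" in colidx else UNKNOWN,
                    meth_count=int(row[colidx["meth_count"]]),
                    unmeth_count=int(row[colidx["unmeth_count"]]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            yield _check_record(rec, lineno, path)
    if nrows == 0:
        warnings.warn(f"{path}: empty methylation table", stacklevel=2)


def read_bismark_cov(path, sample_name: str = "") -> Iterator[CytosineRecord]:
    """Stream records from a Bismark coverage file.

    Columns: chrom, start, end, methylation percentage, count methylated,
    count unmethylated; start == end, 1-based. The percentage column is
    redundant and ignored in favour of the counts; a discrepancy larger than
    0.5 percentage points triggers a warning (counts win). Sequence context is
    not present in this dialect, so records carry context ``unknown``.
    """
    nrows = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(row)}")
            nrows += 1
            try:
                pos = int(row[1])
                pct = float(row[3])
                meth = int(row[4])
                unmeth = int(row[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            depth = meth + unmeth
            if depth > 0 and abs(100.0 * meth / depth - pct) > 0.5:
                warnings.warn(
                    f"{path}:{lineno}: percentage column ({pct}) inconsistent with "
                    f"counts ({meth}/{depth}); using counts",
                    stacklevel=2,
                )
            rec = CytosineRecord(row[0].strip(), pos, UNKNOWN, UNKNOWN, meth, unmeth)
            yield _check_record(rec, lineno, path)
    if nrows == 0:
        warnings.warn(f"{path}: empty Bismark coverage file", stacklevel=2)


def read_cytosine_report(
    path,
    sample_name: str = "",
    context_filter: Sequence[str] | None = ("CG",),
) -> Iterator[CytosineRecord]:
    """Stream records from a Bismark genome-wide cytosine report.

    Columns: chrom, pos, strand, count methylated, count unmethylated,
    context, trinucleotide. Unlike the coverage dialect this carries the
    cytosine context, so context filtering applies.
    """
    return read_cytosine_table(
        path,
        sample_name,
        context_filter=context_filter,
        columns=("chrom", "pos", "strand", "meth_count", "unmeth_count", "context"),
    )


def collapse_cpg_dyads(records: Iterable[CytosineRecord]) -> Iterator[CytosineRecord]:
    """Optionally merge symmetric CpG pairs (+ strand pos p, − strand pos p+1).

    Counts are summed onto the + strand coordinate. Input must be sorted by
    (chrom, pos). Off by default in the pipeline: each input row is normally
    one site.
    """
    pending: CytosineRecord | None = None
    for rec in records:
        if (
            pending is not None
            and rec.chrom == pending.chrom
            and rec.pos == pending.pos + 1
            and pending.strand == "+"
            and rec.strand == "-"
            and pending.context == rec.context == "CG"
        ):
            yield pending._replace(
                meth_count=pending.meth_count + rec.meth_count,
                unmeth_count=pending.unmeth_count + rec.unmeth_count,
            )
            pending = None
            continue
        if pending is not None:
            yield pending
        pending = rec
    if pending is not None:
        yield pending


@dataclass
class ChromArrays:
    """Aligned per-chromosome arrays for one MethylomeSet.

    ``positions`` is sorted and shared by all samples; ``meth``/``unmeth``
    have shape (n_samples, n_sites). A site missing from a sample simply has
    zero counts there (depth 0), so it can never satisfy a depth criterion.
    """

    positions: np.ndarray  # (n,) int64, sorted ascending
    meth: np.ndarray  # (S, n) int64
    unmeth: np.ndarray  # (S, n) int64
    context: np.ndarray  # (n,) unicode

    @property
    def depth(self) -> np.ndarray:
        return self.meth + self.unmeth

    def levels(self) -> np.ndarray:
        """Per-site methylation level per sample; NaN where depth is 0."""
        d = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = np.where(d > 0, self.meth / np.maximum(d, 1), np.nan)
        return lev


@dataclass
class MethylomeSet:
    """Multi-sample collection of cytosine records on a shared coordinate system."""

    samples: list[str]
    chroms: dict[str, ChromArrays] = field(default_factory=dict)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self):
        if len(self.samples) < 2:
            raise ValueError("a MethylomeSet requires at least two samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")

    @classmethod
    def from_records(
        cls,
        records_by_sample: Mapping[str, Iterable[CytosineRecord]],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> "MethylomeSet":
        """Align per-sample record streams on the union of their coordinates."""
        samples = list(records_by_sample)
        per_sample: list[dict[str, dict[int, tuple[int, int, str]]]] = []
        chrom_order: list[str] = []
        for name in samples:
            by_chrom: dict[str, dict[int, tuple[int, int, str]]] = {}
            for rec in records_by_sample[name]:
                sites = by_chrom.setdefault(rec.chrom, {})
                if rec.chrom not in chrom_order:
                    chrom_order.append(rec.chrom)
                if rec.pos in sites:
                    raise ValueError(f"duplicate site {rec.chrom}:{rec.pos} in sample {name}")
                sites[rec.pos] = (rec.meth_count, rec.unmeth_count, rec.context)
            per_sample.append(by_chrom)

        chroms: dict[str, ChromArrays] = {}
        for chrom in chrom_order:
            union: set[int] = set()
            for by_chrom in per_sample:
                union.update(by_chrom.get(chrom, ()))
            positions = np.array(sorted(union), dtype=np.int64)
            n = positions.size
            meth = np.zeros((len(samples), n), dtype=np.int64)
            unmeth = np.zeros((len(samples), n), dtype=np.int64)
            context = np.full(n, UNKNOWN, dtype="U7")
            index = {int(p): i for i, p in enumerate(positions)}
            for s, by_chrom in enumerate(per_sample):
                for pos, (m, u, ctx) in by_chrom.get(chrom, {}).items():
                    i = index[pos]
                    meth[s, i] = m
                    unmeth[s, i] = u
                    if ctx != UNKNOWN:
                        context[i] = ctx
            chroms[chrom] = ChromArrays(positions, meth, unmeth, context)
        return cls(samples=samples, chroms=chroms, chrom_sizes=dict(chrom_sizes) if chrom_sizes else None)

    def chrom_length(self, chrom: str) -> int:
        """Declared chromosome size, or the last covered position as fallback."""
        if self.chrom_sizes and chrom in self.chrom_sizes:
            return self.chrom_sizes[chrom]
        arr = self.chroms[chrom]
        return int(arr.positions[-1]) if arr.positions.size else 0

    def iter_records(self, sample: str) -> Iterator[CytosineRecord]:
        """Yield one sample's sites (depth > 0 only) sorted by (chrom, pos)."""
        s = self.samples.index(sample)
        for chrom, arr in self.chroms.items():
            depth = arr.meth[s] + arr.unmeth[s]
            for i in np.nonzero(depth > 0)[0]:
                yield CytosineRecord(
                    chrom, int(arr.positions[i]), str(arr.context[i]), UNKNOWN,
                    int(arr.meth[s, i]), int(arr.unmeth[s, i]),
                )

    def sample_levels(self, sample: str) -> Iterator[tuple[str, int, float]]:
        """Yield (chrom, pos, level) for one sample's covered sites, sorted."""
        s = self.samples.index(sample)
        for chrom, arr in self.chroms.items():
            depth = arr.meth[s] + arr.unmeth[s]
            covered = np.nonzero(depth > 0)[0]
            lev = arr.meth[s, covered] / depth[covered]
            for i, l in zip(covered, lev):
                yield chrom, int(arr.positions[i]), float(l)


def write_cytosine_table(records: Iterable[CytosineRecord], path) -> None:
    """Write records as the generic TSV dialect (round-trips through
    :func:`read_cytosine_table`)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.context}\t{rec.meth_count}\t{rec.unmeth_count}\n"
            )


def write_wig(levels: Iterable[tuple[str, int, float]], path, track_name: str | None = None) -> None:
    """Write per-site methylation levels as a variableStep WIG track.

    ``levels`` yields (chrom, pos, level) sorted by position within each
    chromosome; one ``variableStep chrom=<chrom> span=1`` block is opened per
    chromosome in input order. Values are written on the 0-1 scale with four
    decimal places. Unsorted input raises: sorting is the caller's job, which
    keeps the writer single-pass.
    """
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        current: str | None = None
        last_pos = 0
        for chrom, pos, level in levels:
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"methylation level out of [0,1] at {chrom}:{pos}: {level}")
            if chrom != current:
                fh.write(f"variableStep chrom={chrom} span=1\n")
                current = chrom
                last_pos = 0
            if pos <= last_pos:
                raise ValueError(f"unsorted WIG input at {chrom}:{pos} (previous {last_pos})")
            fh.write(f"{pos} {level:.4f}\n")
            last_pos = pos


def read_wig(path) -> Iterator[tuple[str, int, float]]:
    """Minimal variableStep WIG reader (round-trip checks and small utilities)."""
    chrom = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                continue
            pos, value = line.split()
            yield chrom, int(pos), float(value)


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as a BED6 track (0-based half-open).

    Score encodes significance as ``min(1000, round(-10*log10(p)))``, name is
    ``DMR_<k>``, strand is '.'.
    """
    with open(path, "w") as fh:
        for k, dmr in enumerate(dmrs, start=1):
            p = dmr.p_value
            if p is None or p <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * np.log10(p))))
            fh.write(f"{dmr.chrom}\t{dmr.start - 1}\t{dmr.end}\tDMR_{k}\t{score}\t.\n")
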