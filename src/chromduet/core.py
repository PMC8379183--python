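"""Coordinate conventions, interval algebra, and on-disk formats.

Everything in this package uses 0-based, half-open coordinates (the BED and
bedGraph convention): an interval [start, end) covers the base pairs
start, start+1, ..., end-1.  A single reference genome is assumed per run.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_genes_tsv",
    "write_genes_tsv",
    "merge_intervals",
    "overlaps",
    "overlap_length",
    "tss_window",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor on ties."""
        return (self.start + self.end) // 2


@dataclass
class Peak:
    """A called peak: an interval plus its signal mass (AUC = sum of
    coverage x width) and peak height, tagged with the source track
    (e.g. an antibody label)."""

    interval: GenomicInterval
    auc: float = 0.0
    max_signal: float = 0.0
    source: str | None = None

    def __post_init__(self) -> None:
        if self.auc < 0 or self.max_signal < 0:
            raise ValueError("auc and max_signal must be non-negative")


@dataclass
class GeneModel:
    """One transcript model per gene: strand, transcript span and exon blocks.

    TSS and TTS are strand-derived: on the + strand the TSS is ``tx_start``;
    on the - strand it is ``tx_end - 1`` (the last covered base is the 5'
    end under half-open coordinates).  ``cds_start``/``cds_end`` are optional
    and only needed to resolve UTR categories during annotation.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"invalid transcript span for {self.gene_id}")
        if not self.exons:
            self.exons = [GenomicInterval(self.chrom, self.tx_start, self.tx_end)]
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon chrom mismatch in {self.gene_id}")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"exon outside transcript span in {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


class CoverageTrack:
    """Sparse per-chromosome coverage: sorted, non-overlapping runs of
    strictly positive value.  Zero-value runs are dropped on construction
    (the canonical sparse form), and adjacent runs with equal value are
    merged."""

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(runs):
            starts, ends, values = (np.asarray(a) for a in runs[chrom])
            starts = starts.astype(np.int64)
            ends = ends.astype(np.int64)
            values = values.astype(np.float64)
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite coverage value on {chrom}")
            if np.any(values < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted run on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            keep = values > 0
            starts, ends, values = starts[keep], ends[keep], values[keep]
            if starts.size:
                starts, ends, values = _merge_equal_adjacent(starts, ends, values)
                self._runs[chrom] = (starts, ends, values)
        self._library_size: float | None = None

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._runs:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._runs[chrom]

    @property
    def library_size(self) -> float:
        """Total signal mass: sum of value x width over all runs."""
        if self._library_size is None:
            self._library_size = float(
                sum(((e - s) * v).sum() for s, e, v in self._runs.values())
            )
        return self._library_size

    def scaled(self, factor: float) -> "CoverageTrack":
        """A new track with every value multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return CoverageTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._runs.items()}
        )

    def region_mass(self, interval: GenomicInterval) -> float:
        """Signal mass (value x overlapped width) inside ``interval``."""
        s, e, v = self.runs(interval.chrom)
        if s.size == 0:
            return 0.0
        lo = np.searchsorted(e, interval.start, side="right")
        hi = np.searchsorted(s, interval.end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(e[lo:hi], interval.end) - np.maximum(s[lo:hi], interval.start)
        return float((ov * v[lo:hi]).sum())

    def binned_means(
        self, chrom: str, start: int, end: int, bin_bp: int
    ) -> np.ndarray:
        """Mean coverage per ``bin_bp`` bin over [start, end).

        Bins extending past the chromosome origin or beyond recorded runs
        read as zero coverage.
        """
        if (end - start) % bin_bp != 0:
            raise ValueError("window width must be divisible by bin_bp")
        edges = np.arange(start, end + bin_bp, bin_bp, dtype=np.int64)
        mass = self._cumulative_mass(chrom, edges)
        return np.diff(mass) / bin_bp

    def _cumulative_mass(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Mass accumulated in [-inf, pos) at each query position."""
        s, e, v = self.runs(chrom)
        if s.size == 0:
            return np.zeros(len(positions))
        run_mass = (e - s) * v
        cum = np.concatenate([[0.0], np.cumsum(run_mass)])
        idx = np.searchsorted(s, positions, side="right")  # runs starting before pos
        out = cum[idx]
        # subtract the part of the current run at or beyond pos
        has_run = idx > 0
        j = idx[has_run] - 1
        trailing = np.clip(e[j] - positions[has_run], 0, e[j] - s[j]) * v[j]
        out[has_run] -= trailing
        return out


def _merge_equal_adjacent(starts, ends, values):
    if starts.size < 2:
        return starts, ends, values
    joinable = (starts[1:] == ends[:-1]) & (values[1:] == values[:-1])
    first = np.concatenate([[True], ~joinable])  # first run of each group
    idx = np.flatnonzero(first)
    out_s = starts[idx]
    out_e = ends[np.concatenate([idx[1:] - 1, [len(ends) - 1]])]
    out_v = values[idx]
    return out_s, out_e, out_v


# ---------------------------------------------------------------------------
# interval algebra


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the intervals share at least ``min_bp`` base pairs."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``min_gap`` base pairs.

    At ``min_gap=0`` abutting half-open intervals ([a,b) and [b,c)) merge,
    matching bedtools-merge semantics.  Output is coordinate-sorted and
    pairwise disjoint; its base-pair union equals the input's union.
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in items:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= min_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def tss_window(
    gene: GeneModel, upstream_bp: int, downstream_bp: int
) -> GenomicInterval:
    """Strand-aware window around the TSS, clipped at the chromosome origin.

    On the + strand the window is [tss - upstream, tss + downstream); on the
    - strand it mirrors to [tss - downstream + 1, tss + upstream + 1).  A
    zero-width request degenerates to the single TSS base [tss, tss + 1).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be non-negative")
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp
    else:
        start, end = tss - downstream_bp + 1, tss + upstream_bp + 1
    start = max(0, start)
    if start >= end:
        start, end = tss, tss + 1
    return GenomicInterval(gene.chrom, start, end)


# ---------------------------------------------------------------------------
# readers / writers (tab-separated, UTF-8, LF)


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED5 into Peaks (col 4 -> source, col 5 -> auc)."""
    peaks: list[Peak] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            source = cols[3] if len(cols) > 3 and cols[3] != "." else None
            auc = float(cols[4]) if len(cols) > 4 else 0.0
            peaks.append(Peak(iv, auc=auc, source=source))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.source or '.'}\t{p.auc:g}\n"
            )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack.

    Runs are validated (non-negative values, no overlaps) and canonicalised:
    sorted, zero runs dropped, adjacent equal-value runs merged.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed bedGraph {path}: {exc}") from exc
    if df.empty:
        return CoverageTrack({})
    if df["value"].lt(0).any():
        bad = df.index[df["value"] < 0][0] + 1
        raise ValueError(f"{path}: negative value at data line {bad}")
    runs = {
        chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
        for chrom, g in df.groupby("chrom", sort=True)
    }
    return CoverageTrack(runs)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    buf = io.StringIO()
    for chrom in track.chroms:
        s, e, v = track.runs(chrom)
        for i in range(len(s)):
            buf.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


_GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "exon_starts",
    "exon_ends",
]


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read the canonical gene-model TSV (exon_starts/ends as comma lists;
    optional cds_start/cds_end columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes: list[GeneModel] = []
    has_cds = "cds_start" in df.columns and "cds_end" in df.columns
    for row in df.itertuples(index=False):
        ex_s = [int(x) for x in str(row.exon_starts).split(",") if x != ""]
        ex_e = [int(x) for x in str(row.exon_ends).split(",") if x != ""]
        if len(ex_s) != len(ex_e):
            raise ValueError(f"{path}: exon list length mismatch for {row.gene_id}")
        exons = [GenomicInterval(row.chrom, a, b) for a, b in zip(ex_s, ex_e)]
        cds_start = cds_end = None
        if has_cds and not pd.isna(getattr(row, "cds_start")):
            cds_start = int(getattr(row, "cds_start"))
            cds_end = int(getattr(row, "cds_end"))
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
                "cds_start": "" if g.cds_start is None else g.cds_start,
                "cds_end": "" if g.cds_end is None else g.cds_end,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
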