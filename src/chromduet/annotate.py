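"""Peak-to-region and peak-to-gene annotation.

Region categories follow the HOMER annotatePeaks convention: the peak's
anchor (integer midpoint) is tested against feature windows in priority
order promoter-TSS > TTS > 5' UTR > 3' UTR > exon > intron > intergenic,
with a promoter window of -1000/+100 bp and a TTS window of -100/+1000 bp,
both gene-oriented.  UTR categories require a CDS span on the gene model
and are otherwise unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import GeneModel, GenomicInterval, Peak, overlaps, tss_window

__all__ = [
    "RegionAnnotation",
    "CATEGORIES",
    "annotate_region",
    "assign_gene",
    "genes_with_peak_near_tss",
    "region_distribution",
]

CATEGORIES = ("promoter-TSS", "5UTR", "exon", "intron", "3UTR", "TTS", "intergenic")

PROMOTER_UP, PROMOTER_DOWN = 1000, 100
TTS_UP, TTS_DOWN = 100, 1000


@dataclass
class RegionAnnotation:
    category: str
    gene_id: str | None
    distance_to_tss: int | None  # signed, negative = upstream in gene orientation


def _oriented_window(pos: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Closed genomic window [lo, hi] extending ``up`` bp upstream and
    ``down`` bp downstream of ``pos`` in gene orientation."""
    if strand == "+":
        return pos - up, pos + down
    return pos - down, pos + up


def _signed_tss_distance(anchor: int, gene: GeneModel) -> int:
    return anchor - gene.tss if gene.strand == "+" else gene.tss - anchor


def annotate_region(
    peak: Peak | GenomicInterval, genes: Sequence[GeneModel]
) -> RegionAnnotation:
    """Annotate one peak by its midpoint anchor (exactly one category)."""
    iv = peak.interval if isinstance(peak, Peak) else peak
    anchor = iv.midpoint
    candidates = [g for g in genes if g.chrom == iv.chrom]

    def _nearest(matching: list[GeneModel]) -> GeneModel:
        return min(
            matching,
            key=lambda g: (abs(_signed_tss_distance(anchor, g)), g.tss, g.gene_id),
        )

    checks: list[tuple[str, callable]] = [
        ("promoter-TSS", _in_promoter),
        ("TTS", _in_tts),
        ("5UTR", _in_5utr),
        ("3UTR", _in_3utr),
        ("exon", _in_exon),
        ("intron", _in_intron),
    ]
    for category, pred in checks:
        matching = [g for g in candidates if pred(anchor, g)]
        if matching:
            g = _nearest(matching)
            return RegionAnnotation(category, g.gene_id, _signed_tss_distance(anchor, g))
    return RegionAnnotation("intergenic", None, None)


def _in_promoter(anchor: int, g: GeneModel) -> bool:
    lo, hi = _oriented_window(g.tss, g.strand, PROMOTER_UP, PROMOTER_DOWN)
    return lo <= anchor <= hi


def _in_tts(anchor: int, g: GeneModel) -> bool:
    lo, hi = _oriented_window(g.tts, g.strand, TTS_UP, TTS_DOWN)
    return lo <= anchor <= hi


def _in_exon(anchor: int, g: GeneModel) -> bool:
    return any(e.start <= anchor < e.end for e in g.exons)


def _in_intron(anchor: int, g: GeneModel) -> bool:
    return g.tx_start <= anchor < g.tx_end and not _in_exon(anchor, g)


def _in_5utr(anchor: int, g: GeneModel) -> bool:
    if g.cds_start is None or not _in_exon(anchor, g):
        return False
    return anchor < g.cds_start if g.strand == "+" else anchor >= g.cds_end


def _in_3utr(anchor: int, g: GeneModel) -> bool:
    if g.cds_start is None or not _in_exon(anchor, g):
        return False
    return anchor >= g.cds_end if g.strand == "+" else anchor < g.cds_start


def assign_gene(
    locus: GenomicInterval, genes: Sequence[GeneModel]
) -> str | None:
    """Gene with the TSS nearest the locus midpoint; ties break to the
    smaller TSS coordinate, then to the lexicographically smaller gene id.
    None when the locus's chromosome carries no gene."""
    candidates = [g for g in genes if g.chrom == locus.chrom]
    if not candidates:
        return None
    mid = locus.midpoint
    best = min(candidates, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))
    return best.gene_id


def genes_with_peak_near_tss(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = 15000,
    downstream: int = 10000,
) -> dict[str, list[Peak]]:
    """Genes with >=1 peak overlapping their gene-oriented TSS window
    (default -15 kb / +10 kb).  Returns the gene -> overlapping peaks map."""
    out: dict[str, list[Peak]] = {}
    for g in genes:
        window = tss_window(g, upstream, downstream)
        hits = [p for p in peaks if overlaps(p.interval, window)]
        if hits:
            out[g.gene_id] = hits
    return out


def region_distribution(
    annotations: Iterable[RegionAnnotation],
) -> dict[str, float]:
    """Fraction of annotations per category (sums to 1)."""
    counts: dict[str, int] = {}
    total = 0
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no annotations given")
    return {cat: counts[cat] / total for cat in CATEGORIES if cat in counts}
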