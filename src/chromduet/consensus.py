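"""Multi-antibody consensus: k-of-n replicate/antibody voting on peak sets.

A consensus locus is the merged footprint (transitive base-pair union, as in
bedtools merge) of overlapping peaks from several labelled sources, retained
when at least k distinct sources contribute a peak.  Support is counted per
source, not per peak, so two peaks from the same antibody count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import GeneModel, GenomicInterval, Peak, overlaps

__all__ = [
    "ConsensusLocus",
    "consensus_loci",
    "shared_peaks",
    "exclusive_loci",
    "loci_to_genes",
]


@dataclass
class ConsensusLocus:
    interval: GenomicInterval
    support: frozenset[str]

    @property
    def n_support(self) -> int:
        return len(self.support)


def _as_labelled(
    peaksets: Mapping[str, Sequence[Peak]] | Sequence[tuple[str, Sequence[Peak]]],
) -> list[tuple[str, Sequence[Peak]]]:
    items = list(peaksets.items()) if isinstance(peaksets, Mapping) else list(peaksets)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate source labels: {labels}")
    return items


def consensus_loci(
    peaksets: Mapping[str, Sequence[Peak]] | Sequence[tuple[str, Sequence[Peak]]],
    k: int,
) -> list[ConsensusLocus]:
    """Merge all peaks transitively into maximal loci and keep those
    supported by at least ``k`` of the n sources, sorted by coordinate."""
    items = _as_labelled(peaksets)
    n = len(items)
    if not 1 <= k <= n:
        raise ValueError(f"require 1 <= k <= {n}, got k={k}")
    tagged = [
        (p.interval, lab) for lab, peaks in items for p in peaks
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[ConsensusLocus] = []
    cur: GenomicInterval | None = None
    cur_support: set[str] = set()
    for iv, lab in tagged:
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
            cur_support.add(lab)
        else:
            if cur is not None:
                out.append(ConsensusLocus(cur, frozenset(cur_support)))
            cur, cur_support = iv, {lab}
    if cur is not None:
        out.append(ConsensusLocus(cur, frozenset(cur_support)))
    return [loc for loc in out if loc.n_support >= k]


def shared_peaks(
    set_a: Sequence[Peak], set_b: Sequence[Peak], labels: tuple[str, str] = ("A", "B")
) -> list[ConsensusLocus]:
    """Loci supported by both of two labelled peak sets (pairwise sharing)."""
    return consensus_loci([(labels[0], set_a), (labels[1], set_b)], k=2)


def exclusive_loci(
    factor_a_sets: Sequence[Sequence[Peak]],
    factor_b_sets: Sequence[Sequence[Peak]],
    consensus: Sequence[ConsensusLocus],
) -> tuple[list[ConsensusLocus], list[ConsensusLocus]]:
    """Factor-exclusive loci: shared by both of one factor's antibodies but
    overlapping no k-of-n consensus locus."""
    if len(factor_a_sets) != 2 or len(factor_b_sets) != 2:
        raise ValueError("each factor needs exactly two peak sets")

    def _exclusive(pair: Sequence[Sequence[Peak]]) -> list[ConsensusLocus]:
        shared = shared_peaks(pair[0], pair[1])
        return [
            loc
            for loc in shared
            if not any(overlaps(loc.interval, c.interval) for c in consensus)
        ]

    return _exclusive(factor_a_sets), _exclusive(factor_b_sets)


def loci_to_genes(
    loci: Sequence[ConsensusLocus], genes: Sequence[GeneModel]
) -> dict[str, list[ConsensusLocus]]:
    """Assign each locus to its nearest-TSS gene; return the de-duplicated
    gene -> loci map (unassignable loci, on gene-free chromosomes, drop)."""
    from .annotate import assign_gene

    out: dict[str, list[ConsensusLocus]] = {}
    for loc in loci:
        gid = assign_gene(loc.interval, genes)
        if gid is not None:
            out.setdefault(gid, []).append(loc)
    return out
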