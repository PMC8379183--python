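"""Overlays, read-density summaries, and preranked gene-set enrichment.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum of
GSEA-preranked with weight exponent 1: walking down the ranked list, a gene
in the set moves the sum up in proportion to |score| (normalised by the
total |score| of set genes), a gene outside it moves the sum down by
1/(N - n_hits); the enrichment score (ES) is the extremum of the running
sum.  The null is built by resampling random gene sets of the same size
from the ranked list (a desk-scale approximation of the tool's default
permutation scheme); NES divides the ES by the mean |null ES| of the same
sign and the p-value is the same-sign null tail fraction.  Mirroring the
tool's run condition, the statistic is only evaluated when ranked list and
gene set share at least ``min_overlap`` genes (default 15).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval

__all__ = [
    "OverlaySet",
    "EnrichmentResult",
    "overlay",
    "build_signature",
    "read_density_matrix",
    "average_profile",
    "preranked_enrichment",
]


@dataclass
class OverlaySet:
    """An intersection of two gene sets, with provenance."""

    name: str
    gene_ids: frozenset[str]
    parents: tuple[str, str]
    rule: str = "intersection"

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_overlap: int
    evaluated: bool = True


def overlay(
    gene_set_a: Iterable[str],
    gene_set_b: Iterable[str],
    name: str,
    parents: tuple[str, str] = ("a", "b"),
) -> OverlaySet:
    """Exact, deterministic set intersection of two gene-id sets."""
    return OverlaySet(name, frozenset(gene_set_a) & frozenset(gene_set_b), parents)


def build_signature(
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    de_records: pd.DataFrame,
) -> pd.Series:
    """Signed ranked signature: the union of the up and down gene sets,
    scored by the DE log2 ratio and sorted descending (ties break
    lexicographically by gene id).  The two inputs must be disjoint."""
    up, down = set(up_genes), set(down_genes)
    both = up & down
    if both:
        raise ValueError(f"genes in both overlays: {sorted(both)[:5]}")
    wanted = up | down
    scores = de_records.set_index("gene_id")["log2_ratio"]
    missing = wanted - set(scores.index)
    if missing:
        raise ValueError(f"genes without a log2 ratio: {sorted(missing)[:5]}")
    sig = scores.loc[sorted(wanted)]
    return sig.sort_values(ascending=False, kind="stable")


def read_density_matrix(
    track: CoverageTrack,
    loci: Sequence[GenomicInterval],
    flank_bp: int,
    bin_bp: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus binned coverage around locus centers, CPM-normalised.

    Row i holds the mean coverage per ``bin_bp`` bin over
    [center_i - flank, center_i + flank); rows are returned sorted by row
    sum descending, together with the sort order into ``loci``.  Windows
    running past the chromosome origin read as zero.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    nbins = 2 * flank_bp // bin_bp
    factor = 1e6 / track.library_size if track.library_size > 0 else 0.0
    mat = np.zeros((len(loci), nbins))
    for i, locus in enumerate(loci):
        center = locus.midpoint
        mat[i] = track.binned_means(
            locus.chrom, center - flank_bp, center + flank_bp, bin_bp
        )
    mat *= factor
    order = np.argsort(-mat.sum(axis=1), kind="stable")
    return mat[order], order


def average_profile(
    track: CoverageTrack,
    loci: Sequence[GenomicInterval],
    flank_bp: int = 5000,
    bin_bp: int = 100,
) -> np.ndarray:
    """Column mean of the read-density matrix (the metaplot profile)."""
    mat, _ = read_density_matrix(track, loci, flank_bp, bin_bp)
    if mat.shape[0] == 0:
        return np.zeros(2 * flank_bp // bin_bp)
    return mat.mean(axis=0)


def _running_es(abs_scores: np.ndarray, hit: np.ndarray) -> float:
    """ES of one hit pattern over a descending-ranked score vector."""
    n = len(abs_scores)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    hit_w = abs_scores * hit
    total = hit_w.sum()
    if total == 0:  # all set genes carry score 0: fall back to equal weights
        hit_cdf = np.cumsum(hit) / n_hit
    else:
        hit_cdf = np.cumsum(hit_w) / total
    miss_cdf = np.cumsum(~hit) / (n - n_hit)
    run = hit_cdf - miss_cdf
    return float(run[np.argmax(np.abs(run))])


def preranked_enrichment(
    ranked: pd.Series | dict[str, float],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    min_overlap: int = 15,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Preranked enrichment of ``gene_set`` in a descending score ranking."""
    if isinstance(ranked, dict):
        ranked = pd.Series(ranked)
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    scores = ranked.to_numpy(dtype=float)
    if np.any(~np.isfinite(scores)):
        raise ValueError("non-finite scores in ranked list")
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    names = ranked.index.to_numpy()[order]
    members = frozenset(gene_set)
    hit = np.fromiter((g in members for g in names), dtype=bool, count=len(names))
    n_overlap = int(hit.sum())
    if n_overlap < min_overlap:
        return EnrichmentResult(np.nan, np.nan, np.nan, n_overlap, evaluated=False)

    abs_scores = np.abs(scores)
    es = _running_es(abs_scores, hit)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(scores)
    null_es = np.empty(n_perm)
    pattern = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        pattern[:] = False
        pattern[rng.choice(n, size=n_overlap, replace=False)] = True
        null_es[i] = _running_es(abs_scores, pattern)
    same_sign = null_es * np.sign(es) > 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(null_es[same_sign]).mean()
        p = float((np.abs(null_es[same_sign]) >= abs(es)).sum() / n_same)
    return EnrichmentResult(es, float(nes), p, n_overlap)
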