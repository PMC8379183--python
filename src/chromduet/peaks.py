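"""Peak calling on coverage tracks.

Two callers are provided.  ``call_peaks`` follows the sparse-enrichment
(SEACR-style) contract used for CUT&RUN: decompose each track into maximal
blocks of strictly positive signal, scale the control to the treatment's
library size, and keep treatment blocks whose signal mass (AUC) exceeds a
threshold derived from the control's block AUCs — the maximum in stringent
mode, the 90th percentile in relaxed mode.  ``call_differential_peaks``
follows the region-count contract used for differential H3K27ac: per
candidate region, compare library-normalised counts between two conditions
with a fold cutoff and a Poisson tail test.

The fragment-size selection applied upstream of CUT&RUN coverage (only
fragments <= 120 bp) is an input assumption of the bedGraphs fed to this
module, not an operation performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import CoverageTrack, GenomicInterval, Peak, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "SignalBlock",
    "DifferentialPeak",
    "call_blocks",
    "call_peaks",
    "call_differential_peaks",
    "union_candidate_regions",
]


@dataclass
class SignalBlock:
    """A maximal run of strictly positive coverage."""

    interval: GenomicInterval
    auc: float
    max_signal: float


@dataclass
class DifferentialPeak:
    interval: GenomicInterval
    signal_a: float
    signal_b: float
    fold: float
    p_value: float
    status: Literal["gained", "lost", "unchanged"]


def call_blocks(track: CoverageTrack) -> list[SignalBlock]:
    """Decompose a track into maximal positive-signal blocks.

    Blocks are groups of abutting positive runs; the AUCs of all blocks sum
    to the track's library size.
    """
    blocks: list[SignalBlock] = []
    for chrom in track.chroms:
        s, e, v = track.runs(chrom)
        if s.size == 0:
            continue
        breaks = np.flatnonzero(s[1:] != e[:-1]) + 1
        bounds = np.concatenate([[0], breaks, [len(s)]])
        widths = (e - s).astype(float)
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            auc = float((widths[lo:hi] * v[lo:hi]).sum())
            blocks.append(
                SignalBlock(
                    GenomicInterval(chrom, int(s[lo]), int(e[hi - 1])),
                    auc=auc,
                    max_signal=float(v[lo:hi].max()),
                )
            )
    return blocks


def call_peaks(
    treatment: CoverageTrack,
    control: CoverageTrack,
    mode: Literal["relaxed", "stringent"] = "relaxed",
) -> list[Peak]:
    """Threshold treatment signal blocks against a negative-control track.

    The control is scaled to the treatment's library size; the AUC threshold
    is the maximum control-block AUC in ``stringent`` mode or the 90th
    percentile of control-block AUCs in ``relaxed`` mode.  A control without
    signal yields threshold 0 (all treatment blocks pass, with a warning).
    """
    if mode not in ("relaxed", "stringent"):
        raise ValueError(f"unknown mode {mode!r}")
    t_blocks = call_blocks(treatment)
    if control.library_size > 0 and treatment.library_size > 0:
        scaled_control = control.scaled(treatment.library_size / control.library_size)
    else:
        scaled_control = control
    c_aucs = np.array([b.auc for b in call_blocks(scaled_control)])
    if c_aucs.size == 0:
        logger.warning("control track has no signal blocks; all treatment blocks pass")
        tau = 0.0
    elif mode == "stringent":
        tau = float(c_aucs.max())
    else:
        tau = float(np.percentile(c_aucs, 90))
    return [
        Peak(b.interval, auc=b.auc, max_signal=b.max_signal)
        for b in t_blocks
        if b.auc > tau
    ]


def _poisson_tail(k: float, lam: float) -> float:
    """P(X >= round(k)) for X ~ Poisson(lam)."""
    return float(stats.poisson.sf(int(round(k)) - 1, lam))


def call_differential_peaks(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    regions: Sequence[GenomicInterval],
    min_fold: float = 4.0,
    max_p: float = 1e-4,
    pseudocount: float = 1.0,
) -> list[DifferentialPeak]:
    """Classify candidate regions as gained / lost / unchanged in B vs A.

    Per region, each track's signal mass is normalised to counts per million
    of library mass.  The region is ``gained`` when
    (B + pc) / (A + pc) >= min_fold and the Poisson tail
    P(X >= B | lambda = A + pc) < max_p; ``lost`` symmetrically.  Regions
    outside a track's recorded span read as zero signal.  Swapping the two
    tracks maps gained <-> lost exactly.
    """
    fa = 1e6 / track_a.library_size if track_a.library_size > 0 else 0.0
    fb = 1e6 / track_b.library_size if track_b.library_size > 0 else 0.0
    out: list[DifferentialPeak] = []
    for region in regions:
        a = track_a.region_mass(region) * fa
        b = track_b.region_mass(region) * fb
        fold = (b + pseudocount) / (a + pseudocount)
        p_gain = _poisson_tail(b, a + pseudocount)
        p_loss = _poisson_tail(a, b + pseudocount)
        if fold >= min_fold and p_gain < max_p:
            status, p = "gained", p_gain
        elif 1.0 / fold >= min_fold and p_loss < max_p:
            status, p = "lost", p_loss
        else:
            status, p = "unchanged", p_gain if fold >= 1 else p_loss
        out.append(DifferentialPeak(region, a, b, fold, p, status))
    return out


def union_candidate_regions(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    control: CoverageTrack | None = None,
    mode: Literal["relaxed", "stringent"] = "relaxed",
) -> list[GenomicInterval]:
    """Candidate regions for differential testing: the merged union of peaks
    called in each condition.

    With an input/control track each condition is called against it.  Without
    one, each condition's blocks are thresholded at the 90th percentile of
    the two conditions' pooled block AUCs (after scaling B's blocks to A's
    library size) — the practical stand-in for a flat background reference.
    """
    if control is not None:
        peaks = call_peaks(track_a, control, mode) + call_peaks(track_b, control, mode)
        return merge_intervals([p.interval for p in peaks])
    blocks_a = call_blocks(track_a)
    blocks_b = call_blocks(track_b)
    scale = (
        track_a.library_size / track_b.library_size
        if track_a.library_size > 0 and track_b.library_size > 0
        else 1.0
    )
    pooled = np.array([b.auc for b in blocks_a] + [b.auc * scale for b in blocks_b])
    if pooled.size == 0:
        return []
    tau = float(np.percentile(pooled, 90))
    kept = [b.interval for b in blocks_a if b.auc > tau]
    kept += [b.interval for b in blocks_b if b.auc * scale > tau]
    return merge_intervals(kept)
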