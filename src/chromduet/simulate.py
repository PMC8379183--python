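"""Synthetic miniature dataset with a ground-truth ledger.

The generator emulates the data structure of a two-factor co-binding study:

* a small genome with one transcript model per gene;
* four antibody CUT&RUN coverage tracks (two antibodies per factor) plus a
  negative-control track, with planted co-bound and factor-exclusive loci,
  per-antibody detection efficiencies, and epitope masking (a detectable
  locus invisible to exactly one antibody);
* two-condition H3K27ac tracks (control vs knockdown) plus a background
  input track, with acetylation gains and losses planted at co-bound loci;
* a two-condition replicate count table whose differential expression is
  coupled to the planted acetylation changes.

Coverage is piecewise-constant Poisson noise around a sparse background,
multiplied by a constant enrichment across each planted locus (rectangular
peaks).  Counts follow a gamma-Poisson (negative-binomial-like) model.
Every draw derives from the config seed, so a fixed config reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    write_bedgraph,
    write_genes_tsv,
)

__all__ = [
    "SimulationConfig",
    "LocusTruth",
    "GroundTruth",
    "simulate_gene_models",
    "simulate_truth",
    "simulate_counts",
    "simulate_dataset",
]

FACTOR_A_ANTIBODIES = (0, 1)
FACTOR_B_ANTIBODIES = (2, 3)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    ``background_rate`` is the mean coverage per ``bin_bp`` bin (CUT&RUN
    background is sparse); ``peak_height`` is the enrichment multiple over
    background inside a planted locus.  Antibody sensitivities default to a
    validated/new antibody pair per factor.
    """

    seed: int = 7
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_genes: int = 300
    n_shared_loci: int = 60
    n_factor_a_only: int = 30
    n_factor_b_only: int = 30
    antibody_labels: tuple[str, str, str, str] = ("A1", "A2", "B1", "B2")
    antibody_sensitivities: tuple[float, float, float, float] = (
        0.98,
        0.95,
        0.98,
        0.95,
    )
    epitope_mask_rate: float = 0.05
    peak_width_mean: float = 600.0
    peak_width_sd: float = 100.0
    background_rate: float = 0.05
    peak_height: float = 400.0
    bin_bp: int = 100
    frac_targets_gaining_ac: float = 0.6
    frac_targets_losing_ac: float = 0.35
    frac_gaining_ac_upregulated: float = 0.8
    frac_losing_ac_downregulated: float = 0.9
    n_replicates: int = 3
    de_log2fc: float = 1.5
    dispersion: float = 0.005
    count_mean: float = 300.0
    count_spread: float = 0.6
    count_mean_min: float = 100.0
    tss_offset_bp: int = 2000

    def __post_init__(self) -> None:
        probs = (
            *self.antibody_sensitivities,
            self.epitope_mask_rate,
            self.frac_targets_gaining_ac,
            self.frac_targets_losing_ac,
            self.frac_gaining_ac_upregulated,
            self.frac_losing_ac_downregulated,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.frac_targets_gaining_ac + self.frac_targets_losing_ac > 1:
            raise ValueError("acetylation gain+loss fractions exceed 1")
        positive = (
            self.n_chroms,
            self.chrom_length_bp,
            self.n_genes,
            self.n_replicates,
            self.bin_bp,
            self.peak_width_mean,
        )
        if any(x <= 0 for x in positive):
            raise ValueError("counts and sizes must be positive")
        if self.dispersion < 0 or self.background_rate < 0 or self.peak_height < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class LocusTruth:
    locus_id: str
    interval: GenomicInterval
    locus_class: str  # shared | A_only | B_only
    visible_to: frozenset[str]
    ac_change: str  # gain | loss | none
    target_gene: str
    expression_effect: str  # up | down | none


@dataclass
class GroundTruth:
    """The simulator's ledger of planted loci and their downstream effects."""

    loci: list[LocusTruth]
    gene_ids: list[str]

    def loci_of_class(self, locus_class: str) -> list[LocusTruth]:
        return [l for l in self.loci if l.locus_class == locus_class]

    def genes_with_effect(self, effect: str) -> set[str]:
        return {l.target_gene for l in self.loci if l.expression_effect == effect}

    @property
    def invasive_genes(self) -> set[str]:
        """Planted up-regulated genes (the derepressed, invasive-like set)."""
        return self.genes_with_effect("up")

    @property
    def proliferative_genes(self) -> set[str]:
        """Planted down-regulated genes (the differentiation-like set)."""
        return self.genes_with_effect("down")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "chrom": [l.interval.chrom for l in self.loci],
                "start": [l.interval.start for l in self.loci],
                "end": [l.interval.end for l in self.loci],
                "class": [l.locus_class for l in self.loci],
                "visible_to": [",".join(sorted(l.visible_to)) for l in self.loci],
                "ac_change": [l.ac_change for l in self.loci],
                "target_gene": [l.target_gene for l in self.loci],
                "expression_effect": [l.expression_effect for l in self.loci],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_ids: Sequence[str]) -> "GroundTruth":
        loci = [
            LocusTruth(
                locus_id=rec["locus_id"],
                interval=GenomicInterval(rec["chrom"], int(rec["start"]), int(rec["end"])),
                locus_class=rec["class"],
                visible_to=frozenset(
                    x for x in str(rec["visible_to"]).split(",") if x and x != "nan"
                ),
                ac_change=rec["ac_change"],
                target_gene=rec["target_gene"],
                expression_effect=rec["expression_effect"],
            )
            for rec in df.to_dict(orient="records")
        ]
        return cls(loci, list(gene_ids))


def _chrom_names(cfg: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chroms)]


def simulate_gene_models(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[GeneModel]:
    """Evenly spaced, jittered single-transcript gene models."""
    chroms = _chrom_names(cfg)
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        spacing = cfg.chrom_length_bp / (n + 1)
        max_tx = min(15_000, int(spacing * 0.4))
        jitter = int(spacing * 0.1)
        for j in range(n):
            gi += 1
            anchor = int((j + 1) * spacing) + int(rng.integers(-jitter, jitter + 1))
            lo_tx = min(2_000, max(200, max_tx // 3))
            tx_len = int(rng.integers(lo_tx, max(lo_tx + 1, max_tx + 1)))
            tx_start = max(0, min(anchor, cfg.chrom_length_bp - tx_len - 1))
            tx_end = tx_start + tx_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(1, tx_len), 2 * n_exons - 2, False))
            bounds = np.concatenate([[0], cuts, [tx_len]])
            exons = [
                GenomicInterval(chrom, tx_start + int(bounds[2 * k]), tx_start + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            ]
            genes.append(
                GeneModel(f"gene{gi:04d}", chrom, strand, tx_start, tx_end, exons)
            )
    return genes


def _sample_visibility(
    cfg: SimulationConfig, rng: np.random.Generator, locus_class: str
) -> frozenset[str]:
    """Antibody visibility of one locus.

    Each relevant antibody detects independently with its sensitivity; a
    bound factor is guaranteed visible to at least one of its two antibodies
    before masking (the more sensitive one backstops).  With probability
    ``epitope_mask_rate`` one uniformly chosen visible antibody is then
    masked (epitope hidden in the protein complex at that locus).
    """
    labels = cfg.antibody_labels
    sens = cfg.antibody_sensitivities
    factors = []
    if locus_class in ("shared", "A_only"):
        factors.append(FACTOR_A_ANTIBODIES)
    if locus_class in ("shared", "B_only"):
        factors.append(FACTOR_B_ANTIBODIES)
    visible: set[str] = set()
    for pair in factors:
        hits = [i for i in pair if rng.random() < sens[i]]
        if not hits:
            hits = [max(pair, key=lambda i: sens[i])]
        visible.update(labels[i] for i in hits)
    if visible and rng.random() < cfg.epitope_mask_rate:
        masked = sorted(visible)[rng.integers(len(visible))]
        visible.discard(masked)
    return frozenset(visible)


def simulate_truth(
    cfg: SimulationConfig, rng: np.random.Generator, genes: Sequence[GeneModel]
) -> GroundTruth:
    """Plant loci near gene TSSs and draw visibility, acetylation change and
    expression effect per locus (one gene per locus)."""
    n_loci = cfg.n_shared_loci + cfg.n_factor_a_only + cfg.n_factor_b_only
    if n_loci > len(genes):
        raise ValueError("more planted loci than genes; raise n_genes")
    classes = (
        ["shared"] * cfg.n_shared_loci
        + ["A_only"] * cfg.n_factor_a_only
        + ["B_only"] * cfg.n_factor_b_only
    )
    target_idx = rng.choice(len(genes), size=n_loci, replace=False)
    loci: list[LocusTruth] = []
    for k, (cls, gidx) in enumerate(zip(classes, target_idx)):
        gene = genes[gidx]
        width = max(200, int(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
        offset = int(rng.integers(-cfg.tss_offset_bp, cfg.tss_offset_bp + 1))
        center = int(np.clip(gene.tss + offset, width, cfg.chrom_length_bp - width))
        interval = GenomicInterval(gene.chrom, center - width // 2, center + (width + 1) // 2)
        visible = _sample_visibility(cfg, rng, cls)
        ac_change = "none"
        if cls == "shared":
            u = rng.random()
            if u < cfg.frac_targets_gaining_ac:
                ac_change = "gain"
            elif u < cfg.frac_targets_gaining_ac + cfg.frac_targets_losing_ac:
                ac_change = "loss"
        effect = "none"
        if ac_change == "gain" and rng.random() < cfg.frac_gaining_ac_upregulated:
            effect = "up"
        elif ac_change == "loss" and rng.random() < cfg.frac_losing_ac_downregulated:
            effect = "down"
        loci.append(
            LocusTruth(f"locus{k + 1:04d}", interval, cls, visible, ac_change, gene.gene_id, effect)
        )

    min_sep = 2 * cfg.peak_width_mean
    by_pos = sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start))
    for a, b in zip(by_pos, by_pos[1:]):
        if a.interval.chrom == b.interval.chrom and (
            b.interval.start - a.interval.end < min_sep
        ):
            raise ValueError(
                "planted loci closer than twice the mean peak width; "
                "use a larger genome or fewer loci"
            )
    return GroundTruth(loci, [g.gene_id for g in genes])


def _poisson_track(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    peak_intervals: Sequence[GenomicInterval],
) -> CoverageTrack:
    """Binned Poisson background with rectangular enrichment over peaks."""
    nbins = -(-cfg.chrom_length_bp // cfg.bin_bp)
    peak_rate = cfg.background_rate * cfg.peak_height
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peak_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in _chrom_names(cfg):
        rate = np.full(nbins, float(cfg.background_rate))
        for iv in by_chrom.get(chrom, []):
            lo = iv.start // cfg.bin_bp
            hi = -(-iv.end // cfg.bin_bp)
            rate[lo:hi] = peak_rate
        values = rng.poisson(rate).astype(float)
        nz = np.flatnonzero(values)
        if nz.size == 0:
            continue
        starts = nz.astype(np.int64) * cfg.bin_bp
        ends = np.minimum(starts + cfg.bin_bp, cfg.chrom_length_bp)
        runs[chrom] = (starts, ends, values[nz])
    return CoverageTrack(runs)


def simulate_counts(
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gamma-Poisson count table (genes x 2*n_replicates samples).

    Genes with a planted "up" effect have a condition-B mean of
    mu * 2**de_log2fc, "down" symmetrically.  At dispersion 0 the table is
    the noise-free limit: counts equal rounded means.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    effects = {l.target_gene: l.expression_effect for l in truth.loci}
    genes = truth.gene_ids
    mu = np.clip(
        rng.lognormal(np.log(cfg.count_mean), cfg.count_spread, len(genes)),
        cfg.count_mean_min,
        None,
    )
    shift = np.array(
        [
            {"up": cfg.de_log2fc, "down": -cfg.de_log2fc}.get(effects.get(g, "none"), 0.0)
            for g in genes
        ]
    )
    mu_b = mu * np.power(2.0, shift)
    n = cfg.n_replicates
    cols = [f"ctrl_{i + 1}" for i in range(n)] + [f"kd_{i + 1}" for i in range(n)]
    means = np.column_stack([np.repeat(mu[:, None], n, axis=1), np.repeat(mu_b[:, None], n, axis=1)])
    if cfg.dispersion == 0:
        counts = np.rint(means).astype(np.int64)
    else:
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, means * cfg.dispersion)
        counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=cols)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_dataset(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the full dataset on disk and return (paths, ground truth).

    Files written: ``genes.tsv``, one bedGraph per antibody plus
    ``control.bedgraph``, two-condition ``h3k27ac_{ctrl,kd}.bedgraph`` with a
    background ``h3k27ac_input.bedgraph``, ``counts.tsv``, ``truth.tsv`` and
    a ``manifest.json`` echoing the config with SHA-256 file hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = simulate_gene_models(cfg, rng)
    truth = simulate_truth(cfg, rng, genes)

    paths: dict[str, Path] = {}
    paths["genes"] = outdir / "genes.tsv"
    write_genes_tsv(genes, paths["genes"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")

    for label in cfg.antibody_labels:
        visible = [l.interval for l in truth.loci if label in l.visible_to]
        track = _poisson_track(cfg, rng, visible)
        paths[label] = outdir / f"cutrun_{label}.bedgraph"
        write_bedgraph(track, paths[label])
    control = _poisson_track(cfg, rng, [])
    paths["control"] = outdir / "cutrun_control.bedgraph"
    write_bedgraph(control, paths["control"])

    ac_ctrl_peaks = [l.interval for l in truth.loci if l.ac_change in ("loss", "none")]
    ac_kd_peaks = [l.interval for l in truth.loci if l.ac_change in ("gain", "none")]
    for name, peaks in [
        ("h3k27ac_ctrl", ac_ctrl_peaks),
        ("h3k27ac_kd", ac_kd_peaks),
        ("h3k27ac_input", []),
    ]:
        track = _poisson_track(cfg, rng, peaks)
        paths[name] = outdir / f"{name}.bedgraph"
        write_bedgraph(track, paths[name])

    counts = simulate_counts(truth, cfg, rng)
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", lineterminator="\n")

    manifest = {
        "config": asdict(cfg),
        "version": __version__,
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths, truth
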