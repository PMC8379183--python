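"""Config-driven orchestration of the full analysis chain.

One run goes: (simulated or provided) inputs -> per-antibody peak calling
against the negative control -> pairwise shared and k-of-n consensus loci
-> factor-exclusive loci -> gene assignment -> differential H3K27ac over
candidate regions -> TSS-window gained/lost gene sets -> differential
expression filtering -> overlays -> signed ranked signature -> preranked
enrichment against the invasive/proliferative sets.  The run emits every
intermediate as BED/TSV plus a machine-readable ``report.json`` whose
counts mirror the study-style count chain (peaks per antibody, pairwise
shared, consensus loci and genes, up/down genes, gained/lost genes,
overlay sizes, enrichment statistics).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import genes_with_peak_near_tss
from .consensus import consensus_loci, exclusive_loci, loci_to_genes, shared_peaks
from .core import Peak, read_bed, read_bedgraph, read_genes_tsv, write_bed
from .diffexpr import DE_COLUMNS, PRESETS, filter_de, simple_de
from .integrate import build_signature, overlay, preranked_enrichment
from .peaks import call_differential_peaks, call_peaks, union_candidate_regions
from .simulate import GroundTruth, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 7
    simulate: SimulationConfig | None = None
    input_paths: dict[str, str] = field(default_factory=dict)
    preset: str = "human_sisall4"
    consensus_k: int = 3
    tss_upstream: int = 15_000
    tss_downstream: int = 10_000
    peak_mode: str = "relaxed"
    min_fold: float = 4.0
    max_p: float = 1e-4
    n_perm: int = 1000
    min_overlap: int = 15

    def validate(self) -> None:
        n_antibodies = 4
        if not 1 <= self.consensus_k <= n_antibodies:
            raise ValueError(
                f"consensus_k must lie in [1, {n_antibodies}], got {self.consensus_k}"
            )
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.peak_mode not in ("relaxed", "stringent"):
            raise ValueError(f"unknown peak mode {self.peak_mode!r}")
        if self.simulate is None:
            required = {
                "genes",
                "A1",
                "A2",
                "B1",
                "B2",
                "control",
                "h3k27ac_ctrl",
                "h3k27ac_kd",
                "counts",
            }
            missing = required - set(self.input_paths)
            if missing:
                raise ValueError(f"missing input paths: {sorted(missing)}")
            for key, p in self.input_paths.items():
                if not Path(p).exists():
                    raise ValueError(f"input file for {key!r} not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            sim = dict(sim)
            for key in ("antibody_labels", "antibody_sensitivities"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimulationConfig(**sim)
        return cfg


@dataclass
class RunReport:
    seed: int
    config: dict[str, Any]
    counts: dict[str, int]
    overlays: dict[str, int]
    enrichment: dict[str, dict[str, float]]
    file_hashes: dict[str, str]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_gene_set(genes: set[str], path: Path) -> None:
    path.write_text("\n".join(sorted(genes)) + ("\n" if genes else ""), encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    if config.simulate is not None:
        logger.info("stage simulate: generating synthetic dataset")
        sim_paths, truth = simulate_dataset(config.simulate, outdir / "inputs")
        paths = {k: Path(p) for k, p in sim_paths.items()}
    else:
        paths = {k: Path(p) for k, p in config.input_paths.items()}

    genes = read_genes_tsv(paths["genes"])
    labels = ("A1", "A2", "B1", "B2")
    control = read_bedgraph(paths["control"])

    logger.info("stage peaks: calling CUT&RUN peaks per antibody")
    peaksets: dict[str, list[Peak]] = {}
    counts: dict[str, int] = {}
    written: dict[str, Path] = {}
    for label in labels:
        track = read_bedgraph(paths[label])
        called = call_peaks(track, control, config.peak_mode)
        for p in called:
            p.source = label
        peaksets[label] = called
        counts[f"peaks_{label}"] = len(called)
        bed = outdir / f"peaks_{label}.bed"
        write_bed(called, bed)
        written[f"peaks_{label}"] = bed

    logger.info("stage consensus: pairwise shared and %d-of-4 voting", config.consensus_k)
    shared_a = shared_peaks(peaksets["A1"], peaksets["A2"], ("A1", "A2"))
    shared_b = shared_peaks(peaksets["B1"], peaksets["B2"], ("B1", "B2"))
    consensus = consensus_loci(peaksets, k=config.consensus_k)
    a_only, b_only = exclusive_loci(
        (peaksets["A1"], peaksets["A2"]), (peaksets["B1"], peaksets["B2"]), consensus
    )
    counts["shared_A"] = len(shared_a)
    counts["shared_B"] = len(shared_b)
    counts["consensus_loci"] = len(consensus)
    counts["a_only_loci"] = len(a_only)
    counts["b_only_loci"] = len(b_only)
    for name, loci in [
        ("shared_A", shared_a),
        ("shared_B", shared_b),
        ("consensus", consensus),
        ("a_only", a_only),
        ("b_only", b_only),
    ]:
        bed = outdir / f"{name}.bed"
        write_bed(
            [Peak(l.interval, source=",".join(sorted(l.support))) for l in loci], bed
        )
        written[name] = bed

    gene_map = loci_to_genes(consensus, genes)
    consensus_genes = set(gene_map)
    counts["consensus_genes"] = len(consensus_genes)
    _write_gene_set(consensus_genes, outdir / "consensus_genes.txt")
    written["consensus_genes"] = outdir / "consensus_genes.txt"

    logger.info("stage differential acetylation")
    ac_ctrl = read_bedgraph(paths["h3k27ac_ctrl"])
    ac_kd = read_bedgraph(paths["h3k27ac_kd"])
    ac_input = (
        read_bedgraph(paths["h3k27ac_input"]) if "h3k27ac_input" in paths else None
    )
    if "h3k27ac_regions" in paths:
        regions = [p.interval for p in read_bed(paths["h3k27ac_regions"])]
    else:
        regions = union_candidate_regions(ac_ctrl, ac_kd, ac_input, config.peak_mode)
    diff = call_differential_peaks(
        ac_ctrl, ac_kd, regions, config.min_fold, config.max_p
    )
    diff_df = pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in diff],
            "start": [d.interval.start for d in diff],
            "end": [d.interval.end for d in diff],
            "signal_ctrl": [d.signal_a for d in diff],
            "signal_kd": [d.signal_b for d in diff],
            "fold": [d.fold for d in diff],
            "p_value": [d.p_value for d in diff],
            "status": [d.status for d in diff],
        }
    )
    diff_df.to_csv(outdir / "diff_acetylation.tsv", sep="\t", index=False, lineterminator="\n")
    written["diff_acetylation"] = outdir / "diff_acetylation.tsv"
    gained = [Peak(d.interval) for d in diff if d.status == "gained"]
    lost = [Peak(d.interval) for d in diff if d.status == "lost"]
    counts["gained_ac_peaks"] = len(gained)
    counts["lost_ac_peaks"] = len(lost)

    gained_genes = set(
        genes_with_peak_near_tss(gained, genes, config.tss_upstream, config.tss_downstream)
    )
    lost_genes = set(
        genes_with_peak_near_tss(lost, genes, config.tss_upstream, config.tss_downstream)
    )
    counts["gained_ac_genes"] = len(gained_genes)
    counts["lost_ac_genes"] = len(lost_genes)
    _write_gene_set(gained_genes, outdir / "gained_genes.txt")
    _write_gene_set(lost_genes, outdir / "lost_genes.txt")
    written["gained_genes"] = outdir / "gained_genes.txt"
    written["lost_genes"] = outdir / "lost_genes.txt"

    logger.info("stage expression: stand-in DE test and cutoff filtering")
    counts_df = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    groups = ["ctrl" if c.startswith("ctrl") else "kd" for c in counts_df.columns]
    de = simple_de(counts_df, groups)
    de[DE_COLUMNS].to_csv(outdir / "de.tsv", sep="\t", index=False, lineterminator="\n")
    written["de"] = outdir / "de.tsv"
    up, down = filter_de(de, config.preset)
    counts["up_genes"] = len(up)
    counts["down_genes"] = len(down)

    logger.info("stage overlays")
    overlays = {
        "direct_up": overlay(up, consensus_genes, "direct_up", ("up", "consensus_genes")),
        "gained_up": overlay(up, gained_genes, "gained_up", ("up", "gained_ac_genes")),
        "lost_down": overlay(down, lost_genes, "lost_down", ("down", "lost_ac_genes")),
    }
    overlays["direct_gained_up"] = overlay(
        overlays["direct_up"].gene_ids,
        gained_genes,
        "direct_gained_up",
        ("direct_up", "gained_ac_genes"),
    )
    overlay_sizes = {name: len(o) for name, o in overlays.items()}
    for name, o in overlays.items():
        _write_gene_set(set(o.gene_ids), outdir / f"overlay_{name}.txt")
        written[f"overlay_{name}"] = outdir / f"overlay_{name}.txt"

    signature = build_signature(
        overlays["gained_up"].gene_ids, overlays["lost_down"].gene_ids, de
    )
    signature.rename("log2_ratio").to_csv(
        outdir / "signature.tsv", sep="\t", lineterminator="\n"
    )
    written["signature"] = outdir / "signature.tsv"

    logger.info("stage enrichment")
    enrichment: dict[str, dict[str, float]] = {}
    gene_sets: dict[str, set[str]] = {}
    if truth is not None:
        gene_sets["invasive"] = truth.invasive_genes
        gene_sets["proliferative"] = truth.proliferative_genes
    for key in ("invasive_set", "proliferative_set"):
        if key in paths:
            name = key.removesuffix("_set")
            gene_sets[name] = set(
                Path(paths[key]).read_text(encoding="utf-8").split()
            )
    rng = np.random.default_rng(config.seed)
    full_ranking = de.set_index("gene_id")["log2_ratio"].sort_values(ascending=False)
    for name, members in gene_sets.items():
        res = preranked_enrichment(
            full_ranking, members, config.n_perm, config.min_overlap, rng
        )
        enrichment[name] = {
            "es": res.es,
            "nes": res.nes,
            "p_value": res.p_value,
            "n_overlap": res.n_overlap,
            "evaluated": res.evaluated,
        }

    report = RunReport(
        seed=config.seed,
        config=_config_dict(config),
        counts=counts,
        overlays=overlay_sizes,
        enrichment=enrichment,
        file_hashes={k: _sha256(p) for k, p in sorted(written.items())},
    )
    (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = asdict(config)
    if config.simulate is not None:
        d["simulate"] = asdict(config.simulate)
    return d
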