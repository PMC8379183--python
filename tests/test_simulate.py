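"""Synthetic dataset generator: determinism, planted structure, count model."""

import dataclasses
import hashlib

import numpy as np
import pandas as pd
import pytest

from chromduet.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_counts,
    simulate_dataset,
    simulate_gene_models,
    simulate_truth,
)

SMALL = SimulationConfig(
    seed=5,
    n_chroms=1,
    chrom_length_bp=2_000_000,
    n_genes=80,
    n_shared_loci=15,
    n_factor_a_only=8,
    n_factor_b_only=8,
)


def file_hashes(paths):
    return {
        k: hashlib.sha256(p.read_bytes()).hexdigest()
        for k, p in paths.items()
        if k != "manifest"
    }


class TestDeterminism:
    def test_identical_seed_byte_identical_files(self, tmp_path):
        p1, _ = simulate_dataset(SMALL, tmp_path / "a")
        p2, _ = simulate_dataset(SMALL, tmp_path / "b")
        assert file_hashes(p1) == file_hashes(p2)

    def test_different_seed_differs(self, tmp_path):
        p1, _ = simulate_dataset(SMALL, tmp_path / "a")
        p2, _ = simulate_dataset(dataclasses.replace(SMALL, seed=6), tmp_path / "b")
        assert file_hashes(p1) != file_hashes(p2)


class TestTruthStructure:
    def test_degenerate_probabilities_full_visibility(self, tmp_path):
        cfg = dataclasses.replace(
            SMALL, antibody_sensitivities=(1.0, 1.0, 1.0, 1.0), epitope_mask_rate=0.0
        )
        _, truth = simulate_dataset(cfg, tmp_path)
        for locus in truth.loci_of_class("shared"):
            assert locus.visible_to == frozenset(cfg.antibody_labels)

    def test_exclusive_loci_invisible_to_other_factor(self, tmp_path):
        _, truth = simulate_dataset(SMALL, tmp_path)
        for locus in truth.loci_of_class("A_only"):
            assert locus.visible_to <= {"A1", "A2"} and locus.visible_to
        for locus in truth.loci_of_class("B_only"):
            assert locus.visible_to <= {"B1", "B2"} and locus.visible_to

    def test_acetylation_change_only_at_shared_loci(self, tmp_path):
        _, truth = simulate_dataset(SMALL, tmp_path)
        for locus in truth.loci:
            if locus.locus_class != "shared":
                assert locus.ac_change == "none"
            if locus.expression_effect == "up":
                assert locus.ac_change == "gain"
            if locus.expression_effect == "down":
                assert locus.ac_change == "loss"

    def test_one_gene_per_locus(self, tmp_path):
        _, truth = simulate_dataset(SMALL, tmp_path)
        targets = [l.target_gene for l in truth.loci]
        assert len(targets) == len(set(targets))

    def test_truth_round_trip_via_tsv(self, tmp_path):
        paths, truth = simulate_dataset(SMALL, tmp_path)
        back = GroundTruth.from_frame(
            pd.read_csv(paths["truth"], sep="\t"), truth.gene_ids
        )
        assert [(l.locus_id, l.interval, l.visible_to) for l in back.loci] == [
            (l.locus_id, l.interval, l.visible_to) for l in truth.loci
        ]

    def test_visibility_fraction_matches_closed_form(self):
        """With sensitivities (1, 1, 0.9, 0.9) and mask rate 0.1 the expected
        fraction of shared loci visible to >= 3 antibodies is
        1 - P(exactly 3 visible) * P(mask hits a visible antibody) = 0.981:
        factor A is always fully visible; factor B contributes one antibody
        with probability 2*0.9*0.1 + (backstop) 0.01 = 0.19, and such a
        3-visible locus drops to 2 only when masked (rate 0.1)."""
        cfg = dataclasses.replace(
            SMALL,
            n_chroms=4,
            chrom_length_bp=10_000_000,
            n_genes=600,
            n_shared_loci=500,
            n_factor_a_only=0,
            n_factor_b_only=0,
            antibody_sensitivities=(1.0, 1.0, 0.9, 0.9),
            epitope_mask_rate=0.1,
        )
        rng = np.random.default_rng(21)
        genes = simulate_gene_models(cfg, rng)
        truth = simulate_truth(cfg, rng, genes)
        frac = np.mean([len(l.visible_to) >= 3 for l in truth.loci])
        expected = 1 - 0.19 * 0.1
        se = np.sqrt(expected * (1 - expected) / 500)
        assert abs(frac - expected) < 4 * se

    def test_overcrowded_genome_rejected(self):
        cfg = dataclasses.replace(
            SMALL, chrom_length_bp=100_000, n_genes=80, n_shared_loci=60
        )
        rng = np.random.default_rng(0)
        genes = simulate_gene_models(cfg, rng)
        with pytest.raises(ValueError, match="larger genome|loci"):
            simulate_truth(cfg, rng, genes)


class TestTracks:
    def test_zero_background_empty_control(self, tmp_path):
        from chromduet.core import read_bedgraph

        cfg = dataclasses.replace(SMALL, background_rate=0.0)
        paths, _ = simulate_dataset(cfg, tmp_path)
        assert read_bedgraph(paths["control"]).library_size == 0

    def test_planted_loci_enriched_in_visible_tracks(self, tmp_path):
        from chromduet.core import read_bedgraph

        paths, truth = simulate_dataset(SMALL, tmp_path)
        track = read_bedgraph(paths["A1"])
        # peak depth = background * enrichment; a quarter of it separates
        # enriched from background coverage with huge margin
        threshold = SMALL.background_rate * SMALL.peak_height / 4
        for locus in truth.loci:
            mean_cov = track.region_mass(locus.interval) / locus.interval.length
            if "A1" in locus.visible_to:
                assert mean_cov > threshold
            else:
                assert mean_cov < threshold


class TestCounts:
    def truth_with(self, genes, effects):
        from chromduet.core import GenomicInterval
        from chromduet.simulate import LocusTruth

        loci = [
            LocusTruth(
                f"l{i}",
                GenomicInterval("chr1", 1000 + 5000 * i, 1500 + 5000 * i),
                "shared",
                frozenset({"A1", "A2", "B1"}),
                {"up": "gain", "down": "loss"}.get(eff, "none"),
                g,
                eff,
            )
            for i, (g, eff) in enumerate(effects.items())
        ]
        return GroundTruth(loci, genes)

    def test_null_effect_mean_ratio_near_zero(self):
        """Monte-Carlo: with no planted effect the empirical mean log2 ratio
        over 1,000 genes stays within +/-0.05 of zero."""
        genes = [f"g{i}" for i in range(1000)]
        cfg = dataclasses.replace(SMALL, de_log2fc=0.0)
        counts = simulate_counts(
            self.truth_with(genes, {}), cfg, np.random.default_rng(22)
        )
        ratio = np.log2(counts.iloc[:, 3:].mean(axis=1) + 1) - np.log2(
            counts.iloc[:, :3].mean(axis=1) + 1
        )
        assert abs(ratio.mean()) < 0.05

    def test_zero_dispersion_noise_free_limit(self):
        genes = [f"g{i}" for i in range(20)]
        cfg = dataclasses.replace(SMALL, dispersion=0.0)
        counts = simulate_counts(
            self.truth_with(genes, {}), cfg, np.random.default_rng(23)
        )
        assert (counts.nunique(axis=1) == 1).all()

    def test_planted_twofold_observed_ratio(self):
        """Planted log2 fold change of 1 at mu = 500, n = 3 yields an
        observed median log2 ratio in [0.8, 1.2]."""
        genes = [f"g{i}" for i in range(300)]
        effects = {g: "up" for g in genes}
        cfg = dataclasses.replace(
            SMALL, de_log2fc=1.0, count_mean=500.0, count_spread=0.0, count_mean_min=1.0
        )
        counts = simulate_counts(
            self.truth_with(genes, effects), cfg, np.random.default_rng(24)
        )
        ratio = np.log2(counts.iloc[:, 3:].mean(axis=1)) - np.log2(
            counts.iloc[:, :3].mean(axis=1)
        )
        assert 0.8 <= ratio.median() <= 1.2

    def test_down_effect_symmetric(self):
        genes = [f"g{i}" for i in range(300)]
        effects = {g: "down" for g in genes}
        cfg = dataclasses.replace(
            SMALL, de_log2fc=1.0, count_mean=500.0, count_spread=0.0, count_mean_min=1.0
        )
        counts = simulate_counts(
            self.truth_with(genes, effects), cfg, np.random.default_rng(25)
        )
        ratio = np.log2(counts.iloc[:, 3:].mean(axis=1)) - np.log2(
            counts.iloc[:, :3].mean(axis=1)
        )
        assert -1.2 <= ratio.median() <= -0.8


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"antibody_sensitivities": (1.1, 1, 1, 1)},
            {"epitope_mask_rate": -0.2},
            {"frac_targets_gaining_ac": 0.8, "frac_targets_losing_ac": 0.5},
            {"n_genes": 0},
            {"dispersion": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dataclasses.replace(SMALL, **kwargs)
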