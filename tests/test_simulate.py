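"""The synthetic generators must honour their stated statistical models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneukit.core import Karyotype, aneuploid_panel
from aneukit.simulate import (
    REFERENCE_CT,
    ActivatedSet,
    SimulationConfig,
    simulate_counts,
    simulate_decay,
    simulate_genome,
    simulate_qpcr,
    simulate_variants,
    simulate_wgs_depth,
)


class TestGenome:
    def test_size_and_invariants(self):
        ann = simulate_genome(16, 10, (300, 3000), seed=1)
        assert len(ann) == 160
        assert ann["gene_id"].is_unique
        assert (ann["cds_start"] <= ann["cds_end"]).all()
        assert (ann["cds_length_bp"] == ann["cds_end"] - ann["cds_start"] + 1).all()
        assert (ann["cds_length_bp"] % 3 == 0).all()
        assert ann["cds_length_bp"].between(300 - 2, 3000).all()

    def test_non_overlapping_within_chromosome(self):
        ann = simulate_genome(4, 30, seed=2)
        for _, sub in ann.groupby("chromosome"):
            sub = sub.sort_values("cds_start")
            assert (sub["cds_start"].to_numpy()[1:] > sub["cds_end"].to_numpy()[:-1]).all()

    def test_deterministic_and_seed_sensitive(self):
        a = simulate_genome(16, 10, seed=1)
        b = simulate_genome(16, 10, seed=1)
        c = simulate_genome(16, 10, seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert not a["cds_length_bp"].equals(c["cds_length_bp"])

    def test_mito_appended_on_request(self):
        ann = simulate_genome(2, 5, seed=0, include_mito=True, mito_genes=3)
        assert (ann["chromosome"] == "chrMito").sum() == 3

    @pytest.mark.parametrize("kwargs", [
        {"n_chromosomes": 0}, {"length_range": (2, 100)}, {"length_range": (500, 400)},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            simulate_genome(**{"n_chromosomes": 4, "genes_per_chromosome": 3,
                               "seed": 0, **kwargs})


class TestCounts:
    def test_poisson_limit_ratio_two(self, wt):
        """With no compensation, a second chromosome copy doubles mean counts."""
        ann = simulate_genome(2, 150, seed=3)
        kary = Karyotype.disome("dis", ["chrI"], ["chrI", "chrII"])
        cfg = SimulationConfig(library_size=2_000_000, nb_dispersion=0.0, seed=3)
        c_a = simulate_counts(ann, kary, cfg)["dis_1"]
        c_w = simulate_counts(ann, Karyotype.euploid("eu", ["chrI", "chrII"]), cfg)["eu_1"]
        dup = ann.loc[ann["chromosome"] == "chrI", "gene_id"]
        nondup = ann.loc[ann["chromosome"] == "chrII", "gene_id"]
        # compare library-composition-corrected per-gene ratios
        ratio_dup = (c_a[dup] / c_a.sum()).sum() / (c_w[dup] / c_w.sum()).sum()
        ratio_non = (c_a[nondup] / c_a.sum()).sum() / (c_w[nondup] / c_w.sum()).sum()
        assert ratio_dup / ratio_non == pytest.approx(2.0, rel=0.02)

    def test_full_compensation_ratio_one(self):
        ann = simulate_genome(2, 150, seed=4)
        kary = Karyotype.disome("dis", ["chrI"], ["chrI", "chrII"])
        eu = Karyotype.euploid("eu", ["chrI", "chrII"])
        cfg = SimulationConfig(library_size=2_000_000, nb_dispersion=0.0,
                               compensation_fraction=1.0, seed=4)
        c_a = simulate_counts(ann, kary, cfg)["dis_1"]
        c_w = simulate_counts(ann, eu, cfg)["eu_1"]
        dup = ann.loc[ann["chromosome"] == "chrI", "gene_id"]
        non = ann.loc[ann["chromosome"] == "chrII", "gene_id"]
        ratio = ((c_a[dup].sum() / c_a[non].sum())
                 / (c_w[dup].sum() / c_w[non].sum()))
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_activated_set_doubles_members(self, wt):
        ann = simulate_genome(4, 100, seed=5)
        members = set(ann["gene_id"][:120])
        cfg_on = SimulationConfig(library_size=4_000_000, nb_dispersion=0.0, seed=5,
                                  activated_sets=[ActivatedSet(members, 1.0)])
        cfg_off = SimulationConfig(library_size=4_000_000, nb_dispersion=0.0, seed=5)
        eu = Karyotype.euploid("eu", sorted(ann["chromosome"].unique()))
        on = simulate_counts(ann, eu, cfg_on)["eu_1"]
        off = simulate_counts(ann, eu, cfg_off)["eu_1"]
        rest = set(ann["gene_id"]) - members
        ratio = ((on[list(members)].sum() / on[list(rest)].sum())
                 / (off[list(members)].sum() / off[list(rest)].sum()))
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_column_sums_near_library_size(self, annotation, d2):
        ann = simulate_genome(16, 125, seed=6)
        for seed in (0, 1, 2):
            cfg = SimulationConfig(seed=seed, n_replicates=2)
            counts = simulate_counts(ann, d2, cfg, "FP")
            assert np.allclose(counts.sum(axis=0), cfg.library_size, rtol=0.02)

    def test_missing_chromosome_rejected(self, annotation):
        tiny = Karyotype("bad", {"chrI": 1})
        with pytest.raises(ValueError, match="lacks chromosomes"):
            simulate_counts(annotation, tiny, SimulationConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(compensation_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(nb_dispersion=-0.1)


class TestQpcr:
    def test_noiseless_duplicated_one_cycle_early(self, d2):
        tab = simulate_qpcr(d2, ct_sd=0.0, seed=0)
        chr2 = tab[tab["chromosome"] == "chrII"]["ct"]
        others = tab[tab["chromosome"] != "chrII"]["ct"]
        assert (chr2 == REFERENCE_CT - 1.0).all()
        assert (others == REFERENCE_CT).all()

    def test_three_replicates_both_arms(self, d2):
        tab = simulate_qpcr(d2, ct_sd=0.1, seed=1)
        counts = tab.groupby(["chromosome", "arm"]).size()
        assert (counts == 3).all()
        assert set(tab["arm"]) == {"L", "R"}


class TestWgsDepth:
    def test_noiseless_ratio_exactly_two(self, d2, wt):
        a = simulate_wgs_depth(d2, 20, depth_noise_cv=0.0, seed=0)
        w = simulate_wgs_depth(wt, 20, depth_noise_cv=0.0, seed=0)
        merged = a.merge(w, on=["chromosome", "window_start", "window_end"])
        ratio = merged["rpkm_x"] / merged["rpkm_y"]
        assert (ratio[merged["chromosome"] == "chrII"] == 2.0).all()
        assert (ratio[merged["chromosome"] != "chrII"] == 1.0).all()

    def test_window_coordinates(self, wt):
        tab = simulate_wgs_depth(wt, 3, seed=0)
        one = tab[tab["chromosome"] == "chrI"]
        assert list(one["window_start"]) == [1, 1001, 2001]
        assert (one["window_end"] - one["window_start"] == 999).all()


class TestVariants:
    def test_frequency_strata(self, annotation, d2):
        tab = simulate_variants(annotation, d2, n_true=30, n_noise=30, seed=1)
        true = tab[tab["is_true"]]
        dup = true[true["chromosome"] == "chrII"]
        hap = true[true["chromosome"] != "chrII"]
        assert (hap["frequency"] >= 0.9).all()
        assert dup["frequency"].between(0.40, 0.60).all()
        noise = tab[~tab["is_true"]]
        fails = (
            (noise["frequency"] < 0.3)
            | (noise["base_quality"] < 15)
            | (noise["mapping_quality"] < 15)
        )
        assert fails.all()

    def test_positions_unique_and_inside_genome(self, annotation, d2):
        tab = simulate_variants(annotation, d2, 25, 25, seed=2)
        assert not tab.duplicated(["chromosome", "position"]).any()
        assert (tab["position"] >= 1).all()


class TestDecay:
    def test_noiseless_half_life(self):
        tab = simulate_decay(30.0, [0, 15, 30, 60], noise_sd=0.0, n_replicates=2, seed=0)
        assert tab.loc[0].eq(100.0).all()
        assert tab.loc[30].eq(50.0).all()
        assert tab.loc[60].eq(25.0).all()

    def test_floored_at_zero(self):
        tab = simulate_decay(5.0, [0, 200], noise_sd=20.0, n_replicates=5, seed=3)
        assert (tab.to_numpy() >= 0).all()


@settings(deadline=None, max_examples=15, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_fixed_seed_bit_identical(seed):
    """Every simulator is a pure function of its seed."""
    kary = aneuploid_panel()["D1/8"]
    ann = simulate_genome(3, 4, seed=seed)
    pd.testing.assert_frame_equal(ann, simulate_genome(3, 4, seed=seed))
    q = simulate_qpcr(kary, 0.2, seed=seed)
    pd.testing.assert_frame_equal(q, simulate_qpcr(kary, 0.2, seed=seed))
    w = simulate_wgs_depth(kary, 5, 0.3, seed=seed)
    pd.testing.assert_frame_equal(w, simulate_wgs_depth(kary, 5, 0.3, seed=seed))
    d = simulate_decay(20.0, [0, 10], 3.0, 2, seed=seed)
    pd.testing.assert_frame_equal(d, simulate_decay(20.0, [0, 10], 3.0, 2, seed=seed))
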