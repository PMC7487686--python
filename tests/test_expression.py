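"""RPKM, euploid-anchored median-ratio normalization, and dosage summaries."""

import numpy as np
import pandas as pd
import pytest

from aneukit.core import Karyotype
from aneukit.expression import (
    chromosome_dosage_summary,
    compute_rpkm,
    log2_fold_changes,
    normalize_to_euploid,
    ribosome_density,
)
from aneukit.simulate import ActivatedSet, SimulationConfig, simulate_counts, simulate_genome


def _toy_annotation():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "m1"],
            "chromosome": ["chrI", "chrII", "chrMito"],
            "cds_start": [1, 1, 1],
            "cds_end": [1000, 500, 300],
            "strand": ["+", "+", "+"],
            "cds_length_bp": [1000, 500, 300],
        }
    )


class TestRpkm:
    def test_direct_formula(self):
        """count 10, 1 kb CDS, 1e6 nuclear total -> RPKM 10."""
        ann = _toy_annotation()
        counts = pd.DataFrame(
            {"s1": [10, 999_990, 5000]}, index=pd.Index(["g1", "g2", "m1"], name="gene_id")
        )
        rpkm = compute_rpkm(counts, ann)
        assert rpkm.loc["g1", "s1"] == pytest.approx(10.0)
        # mito genes are excluded from the result and from the totals
        assert "m1" not in rpkm.index
        assert rpkm.loc["g2", "s1"] == pytest.approx(999_990 / 0.5 / 1.0)

    def test_zero_count_zero_rpkm_and_scale_invariance(self):
        ann = _toy_annotation()
        counts = pd.DataFrame({"s1": [0, 100, 7]}, index=["g1", "g2", "m1"])
        rpkm = compute_rpkm(counts, ann)
        assert rpkm.loc["g1", "s1"] == 0.0
        doubled = compute_rpkm(counts * 2, ann)
        pd.testing.assert_frame_equal(rpkm, doubled)

    def test_zero_total_sample_rejected(self):
        ann = _toy_annotation()
        counts = pd.DataFrame({"s1": [0, 0, 50]}, index=["g1", "g2", "m1"])
        with pytest.raises(ValueError, match="zero-total"):
            compute_rpkm(counts, ann)


class TestNormalization:
    def test_identity(self, annotation, d2):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.uniform(1, 100, len(annotation)),
                         index=annotation["gene_id"])
        scale, normed = normalize_to_euploid(vals, vals, d2, annotation)
        assert scale == pytest.approx(1.0)
        pd.testing.assert_series_equal(normed, vals)

    def test_constant_threefold_shift(self, annotation, d2):
        rng = np.random.default_rng(1)
        eu = pd.Series(rng.uniform(1, 100, len(annotation)), index=annotation["gene_id"])
        scale, normed = normalize_to_euploid(3.0 * eu, eu, d2, annotation)
        assert scale == pytest.approx(3.0)
        assert np.allclose(normed / eu, 1.0)

    def test_median_ratio_pinned_to_one(self, annotation, d2, d2_fold_changes):
        """Post-normalization nonduplicated median ratio is 1 to 1e-12."""
        normed, eu = d2_fold_changes["normalized"], d2_fold_changes["rpkm_w"]
        nondup = annotation.loc[
            ~annotation["chromosome"].isin(d2.duplicated | {"chrMito"}), "gene_id"
        ]
        ratios = (normed[nondup] / eu[nondup]).dropna()
        ratios = ratios[eu[nondup] > 0]
        assert abs(ratios.median() - 1.0) < 1e-12

    def test_idempotent(self, annotation, d2, d2_fold_changes):
        normed, eu = d2_fold_changes["normalized"], d2_fold_changes["rpkm_w"]
        scale2, normed2 = normalize_to_euploid(normed, eu, d2, annotation)
        assert scale2 == pytest.approx(1.0)
        pd.testing.assert_series_equal(normed2, normed)

    def test_no_eligible_genes_rejected(self, annotation, d2):
        eu = pd.Series(0.0, index=annotation["gene_id"])
        aneu = pd.Series(1.0, index=annotation["gene_id"])
        with pytest.raises(ValueError, match="eligible"):
            normalize_to_euploid(aneu, eu, d2, annotation)


class TestFoldChanges:
    def test_basic_values_and_missing_flags(self):
        aneu = pd.Series({"a": 2.0, "b": 5.0, "c": 1.0, "d": 0.0})
        eu = pd.Series({"a": 2.0, "b": 2.5, "c": 0.0, "d": 3.0})
        fc = log2_fold_changes(aneu, eu)
        assert fc["a"] == 0.0
        assert fc["b"] == pytest.approx(1.0)
        assert np.isnan(fc["c"]) and np.isnan(fc["d"])


class TestRibosomeDensity:
    def test_identity_and_algebraic_link(self):
        idx = ["a", "b", "c"]
        mrna = pd.Series([1.0, 2.0, 0.0], index=idx)
        fp = pd.Series([1.0, 4.0, 3.0], index=idx)
        fc_m = pd.Series([0.5, 1.0, np.nan], index=idx)
        fc_f = pd.Series([0.5, 2.0, 1.0], index=idx)
        rd = ribosome_density(fp, mrna, fc_f, fc_m)
        assert rd.loc["a", "rd"] == 1.0
        assert rd.loc["b", "rd"] == 2.0
        assert np.isnan(rd.loc["c", "rd"])
        assert rd.loc["a", "rd_log2_fc"] == 0.0
        assert rd.loc["b", "rd_log2_fc"] == pytest.approx(1.0)
        assert np.isnan(rd.loc["c", "rd_log2_fc"])

    def test_fp_only_activation_shifts_rd(self, annotation, wt):
        """A translation-only program shows up in ribosome density, not mRNA."""
        members = frozenset(
            annotation.loc[annotation["chromosome"] == "chrIII", "gene_id"]
        )
        cfg_base = dict(library_size=4_000_000, nb_dispersion=0.005, seed=9)
        cfg_on = SimulationConfig(
            activated_sets=[ActivatedSet(members, 1.0, assays=("FP",))], **cfg_base
        )
        cfg_off = SimulationConfig(**cfg_base)
        eu2 = Karyotype.euploid("eu2")
        fp_a = compute_rpkm(simulate_counts(annotation, wt, cfg_on, "FP"), annotation)["WT_1"]
        fp_w = compute_rpkm(simulate_counts(annotation, eu2, cfg_off, "FP"), annotation)["eu2_1"]
        m_a = compute_rpkm(simulate_counts(annotation, wt, cfg_on, "mRNA"), annotation)["WT_1"]
        m_w = compute_rpkm(simulate_counts(annotation, eu2, cfg_off, "mRNA"), annotation)["eu2_1"]
        _, fp_n = normalize_to_euploid(fp_a, fp_w, wt, annotation)
        _, m_n = normalize_to_euploid(m_a, m_w, wt, annotation)
        rd = ribosome_density(fp_n, m_n, log2_fold_changes(fp_n, fp_w),
                              log2_fold_changes(m_n, m_w))
        assert rd.loc[list(members), "rd_log2_fc"].mean() == pytest.approx(1.0, abs=0.15)


class TestDosageSummary:
    def test_euploid_vs_euploid_all_zero_expectation(self, annotation, wt):
        fc = pd.Series(0.0, index=annotation["gene_id"])
        summ = chromosome_dosage_summary(fc, annotation, wt)
        assert all(s.expected_log2_fc == 0.0 for s in summ)
        assert all(abs(s.deviation) < 1e-12 for s in summ)
        assert not any(s.compensated for s in summ)

    def test_uncompensated_disome(self, annotation, d2, d2_fold_changes):
        summ = {s.chromosome: s for s in
                chromosome_dosage_summary(d2_fold_changes["fc"], annotation, d2)}
        assert summ["chrII"].expected_log2_fc == pytest.approx(1.0)
        assert abs(summ["chrII"].deviation) < 0.3
        assert not summ["chrII"].compensated

    def test_full_compensation_flagged(self, annotation, d2, wt):
        cfg = SimulationConfig(seed=10, compensation_fraction=1.0)
        rp_a = compute_rpkm(simulate_counts(annotation, d2, cfg), annotation)["D2_1"]
        rp_w = compute_rpkm(simulate_counts(annotation, wt, cfg), annotation)["WT_1"]
        _, normed = normalize_to_euploid(rp_a, rp_w, d2, annotation)
        fc = log2_fold_changes(normed, rp_w)
        summ = {s.chromosome: s for s in chromosome_dosage_summary(fc, annotation, d2)}
        assert summ["chrII"].compensated
        assert abs(summ["chrII"].median_log2_fc) < 0.3


@pytest.mark.parametrize("compensation", [0.0, 0.5, 1.0])
def test_dosage_recovery_tracks_compensation(compensation, d2, wt):
    """Duplicated-chromosome median log2 FC ~ (1 - compensation) * log2(2)."""
    ann = simulate_genome(16, 60, seed=20)
    dup_genes = ann.loc[ann["chromosome"] == "chrII", "gene_id"]
    for seed in range(5):
        cfg = SimulationConfig(seed=30 + seed, compensation_fraction=compensation)
        rp_a = compute_rpkm(simulate_counts(ann, d2, cfg), ann)["D2_1"]
        rp_w = compute_rpkm(simulate_counts(ann, wt, cfg), ann)["WT_1"]
        _, normed = normalize_to_euploid(rp_a, rp_w, d2, ann)
        fc = log2_fold_changes(normed, rp_w)
        assert fc[dup_genes].median() == pytest.approx(1.0 - compensation, abs=0.1)
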