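"""Bootstrap model comparison, meta-combination, FDR calling."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from isopharm import (
    BootstrapPlan,
    ModelFit,
    SensitivityTable,
    bootstrap_ci,
    call_biomarkers,
    compare_models,
    meta_combine,
)
from conftest import tiny_expression


class TestBootstrapPlan:
    def test_resamples_reproducible_and_oob_nonempty(self):
        plan = BootstrapPlan(n_boot=10, seed=3)
        a = plan.draw(30)
        b = BootstrapPlan(n_boot=10, seed=3).draw(30)
        for (ia, oa), (ib, ob) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)
            np.testing.assert_array_equal(oa, ob)
            assert oa.size > 0
            assert np.setdiff1d(oa, np.setdiff1d(np.arange(30), ia)).size == 0

    def test_rejects_tiny_plan(self):
        with pytest.raises(ValueError):
            BootstrapPlan(n_boot=1)


def _study(n=100, beta=0.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(3, 1, n)
    y = np.clip(0.5 + 0.1 * (beta * (x - x.mean()) / x.std() + rng.normal(0, noise, n)), 0, 1)
    expr = tiny_expression([x])
    sens = SensitivityTable(
        pd.DataFrame({"cell_line": expr.cell_lines, "drug": "d", "aac": y, "study_id": "s1"})
    )
    return expr, sens


class TestBootstrapCI:
    def test_noise_feature_gives_chance_level_ci(self):
        medians = []
        for seed in range(20):
            expr, sens = _study(n=100, beta=0.0, seed=seed)
            ci, null_ci = bootstrap_ci(expr, sens, "d", "g0.t0", BootstrapPlan(50, seed=seed))
            medians.append(np.nanmedian(ci))
        assert abs(np.median(medians) - 0.5) < 0.05

    def test_planted_signal_gives_high_ci(self):
        hits = 0
        for seed in range(20):
            expr, sens = _study(n=100, beta=0.8, noise=0.3, seed=seed)
            ci, _ = bootstrap_ci(expr, sens, "d", "g0.t0", BootstrapPlan(50, seed=seed))
            hits += np.nanmedian(ci) > 0.55
        assert hits >= 19

    def test_minimal_plan_deterministic(self):
        expr, sens = _study(n=40, seed=1)
        plan = BootstrapPlan(n_boot=2, seed=9)
        a = bootstrap_ci(expr, sens, "d", "g0.t0", plan)
        b = bootstrap_ci(expr, sens, "d", "g0.t0", plan)
        assert a[0].shape == (2,)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestCompareModels:
    def test_uniformly_better_model_tiny_p(self):
        null = np.full(100, 0.5)
        model = np.linspace(0.6, 0.9, 100)
        res = compare_models(model, null)
        assert res.p_vs_null < 1e-15

    def test_identical_vectors_give_p_one(self):
        v = np.linspace(0.4, 0.6, 50)
        assert compare_models(v, v.copy()).p_vs_null == 1.0

    def test_small_sample_exact_signed_rank(self):
        # diffs (0.1, 0.15, 0.15) all positive: one-sided exact p = 1/2^3
        res = compare_models(
            np.array([0.6, 0.7, 0.65]), np.array([0.5, 0.55, 0.5]), min_pairs=3
        )
        assert res.p_vs_null == pytest.approx(0.125)

    def test_too_few_pairs_not_evaluable(self):
        res = compare_models(np.array([0.6] * 5), np.array([0.5] * 5))
        assert np.isnan(res.p_vs_null)

    def test_pairing_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(7)
        model = rng.uniform(0.4, 0.9, 60)
        null = rng.uniform(0.4, 0.6, 60)
        p0 = compare_models(model, null).p_vs_null
        perm = rng.permutation(60)
        assert compare_models(model[perm], null[perm]).p_vs_null == pytest.approx(p0)

    def test_missing_bootstraps_excluded_pairwise(self):
        model = np.linspace(0.6, 0.9, 40)
        null = np.full(40, 0.5)
        model[::7] = np.nan
        res = compare_models(model, null)
        assert res.p_vs_null < 1e-5


class TestMetaCombine:
    def test_equal_weight_mean(self):
        m = meta_combine(ModelFit(0.4, 0.02, 50), ModelFit(0.6, 0.02, 50))
        assert m.beta == pytest.approx(0.5)

    def test_weighted_p_hand_value(self):
        m = meta_combine(ModelFit(0.3, 0.01, 100), ModelFit(0.3, 0.04, 50))
        assert m.p_value == pytest.approx(0.02)
        assert m.n == 150

    def test_idempotent_on_identical_studies(self):
        f = ModelFit(0.37, 0.013, 80)
        m = meta_combine(f, ModelFit(0.37, 0.013, 80))
        assert m.beta == pytest.approx(f.beta) and m.p_value == pytest.approx(f.p_value)

    def test_symmetric(self):
        a, b = ModelFit(0.2, 0.03, 70), ModelFit(-0.1, 0.5, 30)
        m1, m2 = meta_combine(a, b), meta_combine(b, a)
        assert m1.beta == pytest.approx(m2.beta) and m1.p_value == pytest.approx(m2.p_value)

    def test_single_study_passthrough_flagged(self):
        f = ModelFit(0.4, 0.01, 60)
        m = meta_combine(f, None)
        assert m.single_study and m.beta == f.beta and m.n == 60

    def test_sign_conflict_flagged_not_error(self):
        m = meta_combine(ModelFit(0.4, 0.01, 50), ModelFit(-0.4, 0.01, 50))
        assert m.sign_conflict
        assert m.beta == pytest.approx(0.0)


def make_records(**cols):
    base = dict(
        gene_id=["g1"], best_isoform_id=["g1.t0"], drug=["d"],
        meta_beta_gene=[0.5], meta_p_gene=[1e-6], meta_beta_isoform=[0.5],
        meta_p_isoform=[1e-6], ci_gene=[0.7], ci_isoform=[0.7],
        wilcoxon_p_gene=[1e-4], wilcoxon_p_isoform=[1e-4],
    )
    base.update(cols)
    return pd.DataFrame(base)


class TestCallBiomarkers:
    def test_bh_adjustment_hand_values(self):
        p = [0.001, 0.008, 0.039, 0.041]
        rec = make_records(
            gene_id=[f"g{i}" for i in range(4)], best_isoform_id=[None] * 4,
            drug=["d"] * 4, meta_beta_gene=[0.5] * 4, meta_p_gene=p,
            meta_beta_isoform=[np.nan] * 4, meta_p_isoform=[np.nan] * 4,
            ci_gene=[0.7] * 4, ci_isoform=[np.nan] * 4,
            wilcoxon_p_gene=[1e-4] * 4, wilcoxon_p_isoform=[np.nan] * 4,
        )
        out = call_biomarkers(rec, fdr_threshold=0.05)
        np.testing.assert_allclose(out["fdr_gene"], [0.004, 0.016, 0.041, 0.041], atol=1e-12)

    def test_bh_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for m in (3, 17, 200, 1000):
            p = rng.uniform(size=m)
            rec = make_records(
                gene_id=[f"g{i}" for i in range(m)], best_isoform_id=[None] * m,
                drug=["d"] * m, meta_beta_gene=[0.5] * m, meta_p_gene=p,
                meta_beta_isoform=[np.nan] * m, meta_p_isoform=[np.nan] * m,
                ci_gene=[0.7] * m, ci_isoform=[np.nan] * m,
                wilcoxon_p_gene=[1e-4] * m, wilcoxon_p_isoform=[np.nan] * m,
            )
            out = call_biomarkers(rec)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(out["fdr_gene"], ref, atol=1e-12)

    @pytest.mark.parametrize(
        "gene_ok,iso_ok,expected",
        [(True, True, "common"), (True, False, "gene_specific"),
         (False, True, "isoform_specific"), (False, False, "none")],
    )
    def test_category_rule(self, gene_ok, iso_ok, expected):
        rec = make_records(
            meta_p_gene=[1e-6 if gene_ok else 0.5],
            meta_p_isoform=[1e-6 if iso_ok else 0.5],
        )
        out = call_biomarkers(rec)
        assert out["category"].iloc[0] == expected

    def test_ci_filter_blocks_significant_p(self):
        rec = make_records(ci_gene=[0.52], ci_isoform=[0.52])
        assert call_biomarkers(rec)["category"].iloc[0] == "none"

    def test_wilcoxon_filter_blocks(self):
        rec = make_records(wilcoxon_p_gene=[0.4], wilcoxon_p_isoform=[0.4])
        assert call_biomarkers(rec)["category"].iloc[0] == "none"

    def test_empty_records_empty_output(self):
        out = call_biomarkers(pd.DataFrame(columns=make_records().columns))
        assert out.empty and "category" in out.columns
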