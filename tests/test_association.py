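"""Nested linear models, concordance index, best-isoform selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from isopharm import (
    ModelFit,
    SensitivityTable,
    batch_association,
    concordance_index,
    fit_models,
    select_best_isoform,
    tissue_codes,
)
from conftest import tiny_expression


def brute_force_ci(pred, obs):
    """Quadratic pair enumeration oracle for the concordance index."""
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(i + 1, n):
            if obs[i] == obs[j]:
                continue
            den += 1
            if pred[i] == pred[j]:
                num += 0.5
            elif (pred[i] < pred[j]) == (obs[i] < obs[j]):
                num += 1
    return num / den if den else float("nan")


class TestConcordanceIndex:
    @pytest.mark.parametrize(
        "pred,obs,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([4, 3, 2, 1], [1, 2, 3, 4], 0.0),
            ([0.1, 0.4, 0.35, 0.8], [0.0, 0.3, 0.4, 0.9], 5 / 6),
            ([1, 1, 1], [1, 2, 3], 0.5),  # all-tied predictions
        ],
    )
    def test_known_values(self, pred, obs, expected):
        assert concordance_index(pred, obs) == pytest.approx(expected)

    def test_all_tied_observations_not_evaluable(self):
        assert np.isnan(concordance_index([1, 2, 3], [5, 5, 5]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1, 2, 3])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        pred = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # force ties
        obs = np.round(rng.uniform(size=n), 1)
        got = concordance_index(pred, obs)
        want = brute_force_ci(pred, obs)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


def make_sens(y, cells, drug="d", study="s1"):
    return SensitivityTable(
        pd.DataFrame({"cell_line": cells, "drug": drug, "aac": y, "study_id": study})
    )


class TestFitModels:
    def test_perfect_association_single_tissue(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 1, 40)
        expr = tiny_expression([x])
        y = (x - x.mean()) / x.std(ddof=1)
        y = 0.5 + 0.1 * y  # AAC scale
        sens = make_sens(y, expr.cell_lines)
        _, fit = fit_models(expr, sens, "d", "g0.t0")
        assert fit.beta == pytest.approx(1.0, abs=1e-9)
        assert fit.p_value < 1e-30

    def test_matches_statsmodels_ols_with_tissue(self):
        rng = np.random.default_rng(1)
        n = 60
        x = rng.normal(size=n)
        tis = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        y = 0.4 * x + rng.normal(size=n) + np.repeat([0.0, 0.5, -0.3], 20)
        codes, levels = tissue_codes(pd.Series(tis, index=range(n)))
        beta, p = batch_association(x[None, :], y, codes, len(levels))

        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        design = pd.get_dummies(pd.Series(tis), dtype=float).to_numpy()
        res = sm.OLS(ys, np.column_stack([design, xs])).fit()
        assert beta[0] == pytest.approx(res.params[-1], abs=1e-10)
        assert p[0] == pytest.approx(res.pvalues[-1], abs=1e-10)

    def test_tissue_means_only_leave_no_expression_signal(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        tis = ["a"] * 30 + ["b"] * 30
        y = np.repeat([0.3, 0.7], 30)  # Y is exactly tissue means
        codes, levels = tissue_codes(pd.Series(tis, index=range(n)))
        beta, p = batch_association(x[None, :], y, codes, len(levels))
        assert abs(beta[0]) < 1e-10

    def test_type_one_error_calibrated_under_null(self):
        # many independent noise features vs one response: p ~ Uniform(0,1)
        rng = np.random.default_rng(3)
        n, reps = 100, 1000
        y = rng.normal(size=n)
        X = rng.normal(size=(reps, n))
        codes = np.zeros(n, dtype=np.intp)
        _, p = batch_association(X, y, codes, 1)
        frac = np.mean(p < 0.05)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(4)
        n = 50
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        codes = np.zeros(n, dtype=np.intp)
        b1, p1 = batch_association(x[None, :], y, codes, 1)
        b2, p2 = batch_association(-x[None, :], y, codes, 1)
        assert b2[0] == pytest.approx(-b1[0], abs=1e-12)
        assert p2[0] == pytest.approx(p1[0], abs=1e-12)

    def test_too_few_cells_rejected(self):
        expr = tiny_expression([np.arange(5.0)])
        sens = make_sens(np.linspace(0.1, 0.9, 5), expr.cell_lines)
        with pytest.raises(ValueError, match="cell lines"):
            fit_models(expr, sens, "d", "g0.t0")

    def test_constant_feature_rejected(self):
        expr = tiny_expression([np.full(25, 2.0)])
        sens = make_sens(np.linspace(0.1, 0.9, 25), expr.cell_lines)
        with pytest.raises(ValueError, match="constant"):
            fit_models(expr, sens, "d", "g0.t0")

    def test_singleton_tissue_merged(self):
        tis = pd.Series(["a"] * 10 + ["b"] * 10 + ["solo"], index=range(21))
        codes, levels = tissue_codes(tis)
        assert "other" in levels
        assert "solo" not in levels


class TestSelectBestIsoform:
    def test_bonferroni_selection_hand_values(self):
        fits = {
            f"iso{i}": ModelFit(beta=b, p_value=p, n=50)
            for i, (b, p) in enumerate([(0.2, 0.01), (0.5, 0.002), (0.1, 0.2), (0.3, 0.5)])
        }
        iso, p_corr = select_best_isoform("g", fits)
        assert iso == "iso1"
        assert p_corr == pytest.approx(0.008)

    def test_single_isoform_passes_through(self):
        iso, p_corr = select_best_isoform("g", {"only": ModelFit(0.3, 0.03, 40)})
        assert iso == "only" and p_corr == pytest.approx(0.03)

    def test_corrected_p_capped_at_one(self):
        fits = {f"i{k}": ModelFit(0.1, 0.6, 40) for k in range(4)}
        _, p_corr = select_best_isoform("g", fits)
        assert p_corr == 1.0

    def test_tie_breaks_on_beta_then_id(self):
        fits = {
            "b_iso": ModelFit(beta=0.2, p_value=0.01, n=40),
            "a_iso": ModelFit(beta=0.5, p_value=0.01, n=40),
        }
        assert select_best_isoform("g", fits)[0] == "a_iso"
        fits_equal = {
            "z_iso": ModelFit(beta=0.4, p_value=0.01, n=40),
            "a_iso": ModelFit(beta=0.4, p_value=0.01, n=40),
        }
        assert select_best_isoform("g", fits_equal)[0] == "a_iso"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        fits = {
            f"iso{i}": ModelFit(beta=rng.normal(), p_value=rng.uniform(), n=40)
            for i in range(6)
        }
        ref = select_best_isoform("g", fits)
        for _ in range(5):
            keys = list(fits)
            rng.shuffle(keys)
            assert select_best_isoform("g", {k: fits[k] for k in keys}) == ref
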