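"""Tissue-adjusted linear association models and the concordance index.

For each (feature, drug, study) triple three nested ordinary-least-squares
models are considered:

    M0: Y ~ tissue                      (null: in-vitro sensitivity is tissue specific)
    M1: Y ~ tissue + gene expression
    M2: Y ~ tissue + isoform expression

Y (AAC) and the expression predictor are z-scored over the cell lines
entering the fit, so the expression coefficient is a standardized effect
size; its two-sided t-test p-value measures significance. Tissue enters
as cell-means (one indicator per tissue level, intercept absorbed), which
spans the same column space as intercept-plus-dummies and leaves the
expression coefficient and its test unchanged.

The fitting core is vectorized over features via Frisch-Waugh-Lovell
residualization: y and every feature row are centered within tissue, and
the expression coefficient is the simple regression of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset, SensitivityTable

__all__ = [
    "ModelFit",
    "tissue_codes",
    "batch_association",
    "fit_models",
    "concordance_index",
    "select_best_isoform",
]

N_MIN_DEFAULT = 20  # minimum cell lines per (drug, study) fit


@dataclass
class ModelFit:
    """Standardized coefficient and test for the expression term of one model.

    For the tissue-only null model ``beta`` and ``p_value`` are NaN.
    """

    beta: float
    p_value: float
    n: int

    @property
    def sign(self) -> int:
        if not np.isfinite(self.beta) or self.beta == 0:
            return 0
        return 1 if self.beta > 0 else -1

    @property
    def evaluable(self) -> bool:
        return bool(np.isfinite(self.beta) and np.isfinite(self.p_value))


def tissue_codes(
    tissues: pd.Series, min_per_level: int = 2
) -> tuple[np.ndarray, list[str]]:
    """Integer-code tissue labels, merging singleton tissues into ``other``.

    Tissues with fewer than ``min_per_level`` cell lines cannot support their
    own mean and are collapsed into a shared ``other`` level so the design
    stays full rank. Levels are ordered by decreasing frequency (ties broken
    alphabetically), so code 0 is the most frequent tissue.
    """
    labels = tissues.astype(str)
    counts = labels.value_counts()
    small = counts[counts < min_per_level].index
    if len(small):
        labels = labels.where(~labels.isin(set(small)), other="other")
        counts = labels.value_counts()
    levels = sorted(counts.index, key=lambda t: (-counts[t], t))
    lookup = {t: i for i, t in enumerate(levels)}
    return labels.map(lookup).to_numpy(dtype=np.intp), levels


def _zscore_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-score; returns (standardized matrix, constant-row mask)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / safe, const


def _group_means(X: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-level row means of X (features x cells); empty levels get 0."""
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    sums = np.zeros((X.shape[0], n_levels))
    np.add.at(sums.T, codes, X.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[:, counts == 0] = 0.0
    return means


def batch_association(
    X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized coefficient and p-value for many features against one response.

    Parameters
    ----------
    X : (n_features, n_cells) expression matrix (raw scale; z-scored internally)
    y : (n_cells,) response (z-scored internally)
    codes, n_levels : integer tissue coding from :func:`tissue_codes`

    Returns
    -------
    beta, p : arrays of length n_features; NaN for constant features or when
        the residual degrees of freedom n - n_levels - 1 < 1.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = y.size
    df = n - n_levels - 1
    beta = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    if df < 1 or y.std(ddof=1) == 0:
        return beta, p

    ys = (y - y.mean()) / y.std(ddof=1)
    Xs, const = _zscore_rows(X)
    yr = ys - _group_means(ys[None, :], codes, n_levels)[0][codes]
    Xr = Xs - _group_means(Xs, codes, n_levels)[:, codes]

    sxx = np.einsum("ij,ij->i", Xr, Xr)
    sxy = Xr @ yr
    syy = float(yr @ yr)
    ok = (~const) & (sxx > 0)
    b = np.zeros(X.shape[0])
    b[ok] = sxy[ok] / sxx[ok]
    sse = np.maximum(syy - b * sxy, 0.0)
    sigma2 = sse / df
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 / sxx)
        t = b / se
    # a perfect fit gives se == 0: the t statistic diverges, p -> 0
    diverged = np.where(np.sign(b) >= 0, np.inf, -np.inf)
    t = np.where((se == 0) & ok, diverged, t)
    p_ok = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    beta[ok] = b[ok]
    p[ok] = np.minimum(np.maximum(p_ok, np.finfo(float).tiny), 1.0)
    return beta, p


def fit_models(
    expr: ExpressionDataset,
    sens: SensitivityTable,
    drug: str,
    feature: str,
    study_id=None,
    n_min: int = N_MIN_DEFAULT,
) -> tuple[ModelFit, ModelFit]:
    """Fit the tissue-only null model and the expression model for one feature.

    Cell lines are the intersection of expression columns and AAC entries for
    ``drug`` (and ``study_id`` if given). Returns ``(null_fit, feature_fit)``
    where the null fit carries only the sample size.

    Raises
    ------
    ValueError
        if fewer than ``n_min`` cell lines overlap, or the feature is constant
        across the fitted cell lines.
    """
    aac = sens.aac_vector(drug, study_id)
    cells = expr.cell_lines.intersection(aac.index)
    if len(cells) < n_min:
        raise ValueError(
            f"only {len(cells)} cell lines with expression and AAC for {drug!r} (need {n_min})"
        )
    y = aac.reindex(cells).to_numpy()
    x = expr.feature_values(feature).reindex(cells).to_numpy()
    if np.std(x) == 0:
        raise ValueError(f"feature {feature!r} is constant across fitted cell lines")
    codes, levels = tissue_codes(expr.tissues.reindex(cells))
    beta, p = batch_association(x[None, :], y, codes, len(levels))
    null_fit = ModelFit(beta=np.nan, p_value=np.nan, n=len(cells))
    return null_fit, ModelFit(beta=float(beta[0]), p_value=float(p[0]), n=len(cells))


def concordance_index(pred, obs) -> float:
    """Fraction of informative pairs ordered concordantly by the predictions.

    Pairs tied on the observation are excluded from the denominator;
    prediction ties count 0.5 (Harrell's convention). Returns NaN when all
    observations are tied (no evaluable pair).
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D and of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 observations")
    ci = concordance_index_rows(pred[None, :], obs)
    return float(ci[0])


def concordance_index_rows(preds: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Concordance index of each row of ``preds`` against a shared ``obs``."""
    m = obs.size
    iu, ju = np.triu_indices(m, k=1)
    s_obs = np.sign(obs[iu] - obs[ju])
    informative = s_obs != 0
    n_pairs = int(informative.sum())
    if n_pairs == 0:
        return np.full(preds.shape[0], np.nan)
    dp = preds[:, iu[informative]] - preds[:, ju[informative]]
    sp = np.sign(dp)
    score = (sp == s_obs[informative]).sum(axis=1) + 0.5 * (sp == 0).sum(axis=1)
    return score / n_pairs


def select_best_isoform(gene: str, per_isoform_fits: dict) -> tuple[str, float]:
    """Pick a gene's most significant isoform after Bonferroni correction.

    The Bonferroni factor is the number of isoforms of this gene actually
    tested (evaluable fits); corrected p-values are capped at 1. Ties on the
    corrected p-value go to the larger absolute coefficient, then to the
    lexicographically smallest isoform identifier, so the choice is invariant
    to input ordering.

    Returns ``(isoform_id, corrected_p)``.
    """
    evaluable = {iso: f for iso, f in per_isoform_fits.items() if f.evaluable}
    if not evaluable:
        raise ValueError(f"gene {gene!r} has no evaluable isoform fits")
    m = len(evaluable)
    best = min(
        evaluable.items(),
        key=lambda kv: (min(kv[1].p_value * m, 1.0), -abs(kv[1].beta), str(kv[0])),
    )
    return best[0], min(best[1].p_value * m, 1.0)
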