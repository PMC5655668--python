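"""Independent-dataset validation of candidate biomarkers.

Two flavours mirror a typical multi-stage design:

* tissue-specific pre-selection: the association models are refit using
  only cell lines of one tissue (so the tissue covariate drops out) and a
  candidate is kept when its out-of-bag concordance index exceeds a
  threshold and its training association is significant;
* validation proper: each candidate is refit on an independent dataset and
  is validated when the linear association is significant at an unadjusted
  alpha AND the coefficient has the same sign as in training.

The display effect size used for reporting is (CI - 0.5) * sign(beta):
signed distance of the concordance index from random ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    N_MIN_DEFAULT,
    batch_association,
    concordance_index,
    tissue_codes,
)
from .datasets import ExpressionDataset, SensitivityTable
from .discovery import BootstrapPlan, bootstrap_ci_batch

__all__ = [
    "ValidationRule",
    "ValidationOutcome",
    "preselect_tissue",
    "validate",
    "effect_display",
]


@dataclass
class ValidationRule:
    """Validation decision rule: significance level, sign rule, tissue adjustment."""

    alpha: float = 0.05
    require_same_sign: bool = True
    tissue_adjusted: bool = True  # True for pan-cancer, False for single-tissue sets

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ValidationOutcome:
    feature_id: str
    drug: str
    testable: bool
    validated: bool
    p_validation: float
    beta_validation: float
    sign_train: int
    sign_validation: int
    effect_display: float
    reason: str = ""


def effect_display(ci: float, beta: float) -> float:
    """Signed display effect: (CI - 0.5) * sign(beta); zero beta maps to 0."""
    if not 0 <= ci <= 1:
        raise ValueError("concordance index must lie in [0, 1]")
    return (ci - 0.5) * float(np.sign(beta))


def preselect_tissue(
    candidates: pd.DataFrame,
    expr: ExpressionDataset,
    sens: SensitivityTable,
    tissue: str,
    ci_threshold: float = 0.55,
    alpha: float = 0.05,
    plan: BootstrapPlan | None = None,
    n_min: int = N_MIN_DEFAULT,
) -> pd.DataFrame:
    """Refit candidates within one tissue and keep the predictive ones.

    ``candidates`` needs columns ``feature_id`` and ``drug``. The models are
    refit on the tissue's cell lines only (no tissue covariate), and a
    candidate survives when its median out-of-bag concordance index exceeds
    ``ci_threshold`` and its association p-value is below ``alpha``. Returns
    the surviving rows with ``beta_tissue, p_tissue, ci_tissue`` added; too
    few tissue cell lines yields an empty frame (with a warning).
    """
    plan = plan or BootstrapPlan()
    tissue_cells = expr.tissues.index[expr.tissues == tissue]
    out_cols = list(candidates.columns) + ["beta_tissue", "p_tissue", "ci_tissue"]
    rows = []
    for drug, grp in candidates.groupby("drug"):
        aac = sens.aac_vector(drug)
        cells = pd.Index(tissue_cells).intersection(expr.cell_lines).intersection(aac.index)
        if len(cells) < n_min:
            import warnings

            warnings.warn(
                f"only {len(cells)} {tissue!r} cell lines for {drug!r} (need {n_min}); "
                "no candidates preselected"
            )
            continue
        y = aac.reindex(cells).to_numpy()
        feats = grp["feature_id"].tolist()
        X = np.vstack([expr.feature_values(f).reindex(cells).to_numpy() for f in feats])
        codes = np.zeros(len(cells), dtype=np.intp)  # single tissue: intercept only
        beta, p = batch_association(X, y, codes, 1)
        ci, _ = bootstrap_ci_batch(X, y, codes, 1, plan)
        ci_med = np.nanmedian(np.where(np.isfinite(ci), ci, np.nan), axis=1)
        for i, (_, row) in enumerate(grp.iterrows()):
            if np.isfinite(beta[i]) and ci_med[i] > ci_threshold and p[i] < alpha:
                rows.append(list(row) + [beta[i], p[i], ci_med[i]])
    return pd.DataFrame(rows, columns=out_cols)


def validate(
    candidates: pd.DataFrame,
    validation_expr: ExpressionDataset,
    validation_sens: SensitivityTable,
    rule: ValidationRule | None = None,
    n_min: int = N_MIN_DEFAULT,
) -> list[ValidationOutcome]:
    """Test candidates on an independent dataset with the sign-consistency rule.

    ``candidates`` needs columns ``feature_id``, ``drug`` and ``beta_train``
    (the training coefficient whose sign must replicate). Features missing
    from the validation expression matrix or drugs absent from the validation
    sensitivity are reported as not testable, never silently dropped.
    """
    rule = rule or ValidationRule()
    outcomes: list[ValidationOutcome] = []
    for _, row in candidates.iterrows():
        feat, drug = row["feature_id"], row["drug"]
        sign_train = int(np.sign(row["beta_train"]))
        try:
            validation_expr.feature_level(feat)
        except KeyError:
            outcomes.append(
                ValidationOutcome(feat, drug, False, False, np.nan, np.nan, sign_train, 0,
                                  np.nan, reason="feature absent from validation expression")
            )
            continue
        if drug not in validation_sens.drugs:
            outcomes.append(
                ValidationOutcome(feat, drug, False, False, np.nan, np.nan, sign_train, 0,
                                  np.nan, reason="drug absent from validation sensitivity")
            )
            continue
        aac = validation_sens.aac_vector(drug)
        cells = validation_expr.cell_lines.intersection(aac.index)
        if len(cells) < n_min:
            outcomes.append(
                ValidationOutcome(feat, drug, False, False, np.nan, np.nan, sign_train, 0,
                                  np.nan, reason=f"only {len(cells)} validation cell lines")
            )
            continue
        y = aac.reindex(cells).to_numpy()
        x = validation_expr.feature_values(feat).reindex(cells).to_numpy()
        if rule.tissue_adjusted:
            codes, levels = tissue_codes(validation_expr.tissues.reindex(cells))
        else:
            codes, levels = np.zeros(len(cells), dtype=np.intp), ["all"]
        beta, p = batch_association(x[None, :], y, codes, len(levels))
        beta_v, p_v = float(beta[0]), float(p[0])
        if not np.isfinite(beta_v):
            outcomes.append(
                ValidationOutcome(feat, drug, False, False, np.nan, np.nan, sign_train, 0,
                                  np.nan, reason="constant feature in validation data")
            )
            continue
        sign_v = int(np.sign(beta_v))
        ok = p_v < rule.alpha and (not rule.require_same_sign or sign_v == sign_train)
        # in-sample CI of the fitted linear prediction, for the display statistic
        pred = _linear_prediction(x, y, codes, len(levels))
        ci = concordance_index(pred, y)
        outcomes.append(
            ValidationOutcome(
                feature_id=feat,
                drug=drug,
                testable=True,
                validated=bool(ok),
                p_validation=p_v,
                beta_validation=beta_v,
                sign_train=sign_train,
                sign_validation=sign_v,
                effect_display=effect_display(ci, beta_v) if np.isfinite(ci) else np.nan,
            )
        )
    return outcomes


def _linear_prediction(x: np.ndarray, y: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Fitted values of the tissue + expression model (standardized scale)."""
    ys = (y - y.mean()) / (y.std(ddof=1) or 1.0)
    xs = (x - x.mean()) / (x.std(ddof=1) or 1.0)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    gm_y = np.bincount(codes, weights=ys, minlength=n_levels)
    gm_x = np.bincount(codes, weights=xs, minlength=n_levels)
    seen = counts > 0
    gm_y[seen] /= counts[seen]
    gm_x[seen] /= counts[seen]
    yr = ys - gm_y[codes]
    xr = xs - gm_x[codes]
    sxx = float(xr @ xr)
    beta = float(xr @ yr) / sxx if sxx > 0 else 0.0
    return gm_y[codes] + beta * xr


def validation_rate(outcomes) -> float:
    """Validated / testable candidates; NaN when none are testable."""
    testable = [o for o in outcomes if o.testable]
    if not testable:
        return float("nan")
    return sum(o.validated for o in testable) / len(testable)


def outcomes_frame(outcomes) -> pd.DataFrame:
    return pd.DataFrame([vars(o) for o in outcomes])
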