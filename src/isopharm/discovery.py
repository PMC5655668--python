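"""Bootstrap model comparison, cross-study meta-combination and biomarker calling.

Discovery proceeds per drug:

1. full-data fits of the gene model and every isoform model in each study;
2. n-weighted meta-combination of coefficients and p-values across studies;
3. best-isoform selection per gene (smallest Bonferroni-corrected meta p);
4. bootstrap out-of-bag concordance indices for the gene, best-isoform and
   tissue-only null models — ~2/3 of cell lines train each resample, the
   out-of-bag ~1/3 are scored — with identical resamples reused across
   models so the Wilcoxon signed-rank comparison is properly paired;
5. per-drug Benjamini-Hochberg correction over the gene family and the
   best-isoform family separately, and categorical calling.

A feature is called significant at a level when its FDR is below the
threshold, the median out-of-bag concordance index exceeds the CI threshold,
and the one-sided Wilcoxon test against the null model passes. Bootstrap
resamples are drawn once per (drug, study) and shared across all features of
that drug for speed and cross-feature comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import (
    ModelFit,
    batch_association,
    concordance_index_rows,
    select_best_isoform,
    tissue_codes,
    N_MIN_DEFAULT,
)
from .datasets import ExpressionDataset, SensitivityTable

__all__ = [
    "BootstrapPlan",
    "ComparisonResult",
    "MetaFit",
    "bootstrap_ci",
    "bootstrap_ci_batch",
    "compare_models",
    "meta_combine",
    "call_biomarkers",
    "discover",
]

WILCOXON_ALPHA_DEFAULT = 0.05
MIN_PAIRS_DEFAULT = 10


@dataclass
class BootstrapPlan:
    """Resampling plan: ``n_boot`` with-replacement resamples of the cell lines.

    Each resample keeps roughly 2/3 unique cell lines in-bag; the out-of-bag
    remainder is the test set. Resamples with an empty out-of-bag set are
    redrawn. ``seed`` makes the plan reproducible.
    """

    n_boot: int = 100
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")

    def draw(self, n: int, rng=None) -> list[tuple[np.ndarray, np.ndarray]]:
        """Return ``n_boot`` (in_bag_indices, out_of_bag_indices) pairs."""
        rng = np.random.default_rng(self.seed) if rng is None else rng
        out = []
        for _ in range(self.n_boot):
            while True:
                inb = rng.integers(0, n, size=n)
                oob = np.setdiff1d(np.arange(n), inb)
                if oob.size:
                    break
            out.append((inb, oob))
        return out


@dataclass
class ComparisonResult:
    """Paired Wilcoxon signed-rank comparison of concordance-index vectors."""

    p_vs_null: float
    p_gene_vs_isoform: float = np.nan
    ci_model: np.ndarray | None = None
    ci_null: np.ndarray | None = None


def _signed_rank_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Wilcoxon signed-rank p with zero differences dropped; no evidence -> 1."""
    m = np.isfinite(x) & np.isfinite(y)
    d = x[m] - y[m]
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    return float(stats.wilcoxon(d, alternative=alternative).pvalue)


def compare_models(
    model_ci: np.ndarray,
    null_ci: np.ndarray,
    other_ci: np.ndarray | None = None,
    min_pairs: int = MIN_PAIRS_DEFAULT,
) -> ComparisonResult:
    """Compare a model's CI vector with the paired null (and optionally a rival).

    ``p_vs_null`` is the one-sided signed-rank p for model CI exceeding the
    null CI; ``p_gene_vs_isoform`` (when ``other_ci`` is given) is two-sided.
    Fewer than ``min_pairs`` non-missing pairs makes the comparison not
    evaluable (NaN p).
    """
    model_ci = np.asarray(model_ci, float)
    null_ci = np.asarray(null_ci, float)
    if model_ci.shape != null_ci.shape:
        raise ValueError("CI vectors must be paired on the same bootstrap indices")
    n_pairs = int((np.isfinite(model_ci) & np.isfinite(null_ci)).sum())
    if n_pairs < min_pairs:
        return ComparisonResult(p_vs_null=np.nan, ci_model=model_ci, ci_null=null_ci)
    p_null = _signed_rank_p(model_ci, null_ci, "greater")
    p_pair = np.nan
    if other_ci is not None:
        other_ci = np.asarray(other_ci, float)
        if int((np.isfinite(model_ci) & np.isfinite(other_ci)).sum()) >= min_pairs:
            p_pair = _signed_rank_p(model_ci, other_ci, "two-sided")
    return ComparisonResult(
        p_vs_null=p_null, p_gene_vs_isoform=p_pair, ci_model=model_ci, ci_null=null_ci
    )


@dataclass
class MetaFit:
    """Cross-study combination of two model fits by n-weighted arithmetic means."""

    beta: float
    p_value: float
    n: int
    single_study: bool = False
    sign_conflict: bool = False

    @property
    def sign(self) -> int:
        if not np.isfinite(self.beta) or self.beta == 0:
            return 0
        return 1 if self.beta > 0 else -1


def meta_combine(fit1: ModelFit | None, fit2: ModelFit | None) -> MetaFit:
    """Combine two studies' fits: coefficients and p-values averaged, weighted
    by the number of cell lines in each study.

    With only one evaluable study the fit passes through flagged
    ``single_study``. Coefficient sign disagreement between the studies is
    recorded as ``sign_conflict``, not an error. Symmetric in its arguments.
    """
    ok1 = fit1 is not None and fit1.evaluable
    ok2 = fit2 is not None and fit2.evaluable
    if not ok1 and not ok2:
        return MetaFit(beta=np.nan, p_value=np.nan, n=0, single_study=True)
    if ok1 and not ok2:
        return MetaFit(beta=fit1.beta, p_value=fit1.p_value, n=fit1.n, single_study=True)
    if ok2 and not ok1:
        return MetaFit(beta=fit2.beta, p_value=fit2.p_value, n=fit2.n, single_study=True)
    n = fit1.n + fit2.n
    beta = (fit1.n * fit1.beta + fit2.n * fit2.beta) / n
    p = (fit1.n * fit1.p_value + fit2.n * fit2.p_value) / n
    return MetaFit(
        beta=float(beta),
        p_value=float(p),
        n=n,
        sign_conflict=bool(fit1.sign * fit2.sign < 0),
    )


def bootstrap_ci_batch(
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    n_levels: int,
    plan: BootstrapPlan,
    resamples=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag concordance indices for many features and the shared null.

    For each resample the models are refit in-bag (standardization of y and
    of every feature recomputed in-bag and applied out-of-bag), and the full
    linear predictions (tissue + expression term) are scored against the raw
    out-of-bag AAC. Resamples whose out-of-bag AAC values are all tied yield
    NaN and are excluded pairwise downstream.

    Returns
    -------
    ci : (n_features, n_boot) matrix of model concordance indices
    null_ci : (n_boot,) concordance indices of the tissue-only model
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = y.size
    resamples = plan.draw(n) if resamples is None else resamples
    F = X.shape[0]
    ci = np.full((F, len(resamples)), np.nan)
    null_ci = np.full(len(resamples), np.nan)

    for b, (inb, oob) in enumerate(resamples):
        y_in = y[inb]
        sd_y = y_in.std(ddof=1)
        if sd_y == 0:
            continue
        ys = (y_in - y_in.mean()) / sd_y
        codes_in = codes[inb]
        counts = np.bincount(codes_in, minlength=n_levels).astype(float)
        gm_y = np.zeros(n_levels)
        np.add.at(gm_y, codes_in, ys)
        seen = counts > 0
        gm_y[seen] /= counts[seen]

        Xi = X[:, inb]
        mu = Xi.mean(axis=1, keepdims=True)
        sd = Xi.std(axis=1, ddof=1, keepdims=True)
        const = sd[:, 0] == 0
        safe = np.where(sd == 0, 1.0, sd)
        Xis = (Xi - mu) / safe

        gm_x = np.zeros((F, n_levels))
        np.add.at(gm_x.T, codes_in, Xis.T)
        gm_x[:, seen] /= counts[seen]

        yr = ys - gm_y[codes_in]
        Xr = Xis - gm_x[:, codes_in]
        sxx = np.einsum("ij,ij->i", Xr, Xr)
        beta = np.zeros(F)
        ok = (~const) & (sxx > 0)
        beta[ok] = (Xr[ok] @ yr) / sxx[ok]

        y_oob = y[oob]
        if np.all(y_oob == y_oob[0]):
            continue
        codes_oob = codes[oob]
        null_pred = gm_y[codes_oob]
        x_oob = (X[:, oob] - mu) / safe
        preds = null_pred[None, :] + beta[:, None] * (x_oob - gm_x[:, codes_oob])

        null_ci[b] = concordance_index_rows(null_pred[None, :], y_oob)[0]
        ci[:, b] = concordance_index_rows(preds, y_oob)
    return ci, null_ci


def bootstrap_ci(
    expr: ExpressionDataset,
    sens: SensitivityTable,
    drug: str,
    feature: str,
    plan: BootstrapPlan,
    study_id=None,
    n_min: int = N_MIN_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag CI vectors for one feature's model and the tissue-only null."""
    aac = sens.aac_vector(drug, study_id)
    cells = expr.cell_lines.intersection(aac.index)
    if len(cells) < n_min:
        raise ValueError(f"only {len(cells)} usable cell lines (need {n_min})")
    y = aac.reindex(cells).to_numpy()
    x = expr.feature_values(feature).reindex(cells).to_numpy()
    codes, levels = tissue_codes(expr.tissues.reindex(cells))
    ci, null_ci = bootstrap_ci_batch(x[None, :], y, codes, len(levels), plan)
    return ci[0], null_ci


def _bh_family(p: pd.Series, threshold: float) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values; NaN entries stay NaN."""
    adj = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.sum():
        adj.loc[mask] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    return adj


def call_biomarkers(
    records: pd.DataFrame,
    fdr_threshold: float = 0.01,
    ci_threshold: float = 0.55,
    wilcoxon_alpha: float = WILCOXON_ALPHA_DEFAULT,
) -> pd.DataFrame:
    """FDR-correct meta-combined records and assign biomarker categories.

    ``records`` holds one row per gene x drug with columns
    ``gene_id, best_isoform_id, drug, meta_beta_gene, meta_p_gene,
    meta_beta_isoform, meta_p_isoform, ci_gene, ci_isoform,
    wilcoxon_p_gene, wilcoxon_p_isoform``.

    Benjamini-Hochberg runs per drug over two separate families: all genes,
    and all selected best isoforms. A level is significant when FDR <
    ``fdr_threshold`` AND its median out-of-bag CI > ``ci_threshold`` AND its
    one-sided Wilcoxon-vs-null p < ``wilcoxon_alpha``. Categories:
    ``gene_specific`` (gene only), ``isoform_specific`` (isoform only),
    ``common`` (both), ``none``.
    """
    if records.empty:
        out = records.copy()
        for col in ("fdr_gene", "fdr_isoform", "category"):
            out[col] = pd.Series(dtype=float if col != "category" else object)
        return out
    out = records.copy()
    out["fdr_gene"] = np.nan
    out["fdr_isoform"] = np.nan
    for _, idx in out.groupby("drug").groups.items():
        out.loc[idx, "fdr_gene"] = _bh_family(out.loc[idx, "meta_p_gene"], fdr_threshold)
        out.loc[idx, "fdr_isoform"] = _bh_family(out.loc[idx, "meta_p_isoform"], fdr_threshold)

    def _sig(fdr, ci, wp):
        return (
            (fdr < fdr_threshold).fillna(False)
            & (ci > ci_threshold).fillna(False)
            & (wp < wilcoxon_alpha).fillna(False)
        )

    gene_sig = _sig(out["fdr_gene"], out["ci_gene"], out["wilcoxon_p_gene"])
    iso_sig = _sig(out["fdr_isoform"], out["ci_isoform"], out["wilcoxon_p_isoform"])
    category = np.where(
        gene_sig & iso_sig,
        "common",
        np.where(gene_sig, "gene_specific", np.where(iso_sig, "isoform_specific", "none")),
    )
    out["category"] = category
    return out


@dataclass
class DiscoveryResult:
    """Per-drug discovery output: the biomarker-call table plus run metadata."""

    calls: pd.DataFrame
    drug: str
    studies: list
    n_cells: dict = field(default_factory=dict)


def discover(
    expr: ExpressionDataset,
    sens_by_study: dict,
    drug: str,
    plan: BootstrapPlan | None = None,
    fdr_threshold: float = 0.01,
    ci_threshold: float = 0.55,
    wilcoxon_alpha: float = WILCOXON_ALPHA_DEFAULT,
    n_min: int = N_MIN_DEFAULT,
) -> DiscoveryResult:
    """Run the full discovery engine for one drug across one or two studies.

    ``sens_by_study`` maps study identifiers to :class:`SensitivityTable`
    objects sharing the expression panel (expression is profiled once, as in
    multi-study designs where one study contributes RNA-seq). The pooled
    (concatenated across studies) bootstrap CI vectors supply the median-CI
    summary and the Wilcoxon comparisons.
    """
    plan = plan or BootstrapPlan()
    studies = sorted(sens_by_study)
    if not 1 <= len(studies) <= 2:
        raise ValueError("discovery expects one or two training studies")

    gene_ids = expr.genes.index
    iso_ids = expr.isoforms.index
    iso_gene = expr.isoform_map.reindex(iso_ids)

    per_study = {}
    for s in studies:
        aac = sens_by_study[s].aac_vector(drug, study_id=None)
        cells = expr.cell_lines.intersection(aac.index)
        if len(cells) < n_min:
            continue
        y = aac.reindex(cells).to_numpy()
        codes, levels = tissue_codes(expr.tissues.reindex(cells))
        Xg = expr.genes[cells].to_numpy()
        Xi = expr.isoforms[cells].to_numpy()
        bg, pg = batch_association(Xg, y, codes, len(levels))
        bi, pi = batch_association(Xi, y, codes, len(levels))
        per_study[s] = dict(
            cells=cells, y=y, codes=codes, n_levels=len(levels),
            beta_gene=bg, p_gene=pg, beta_iso=bi, p_iso=pi, n=len(cells),
        )
    if not per_study:
        raise ValueError(f"no study has >= {n_min} cell lines for drug {drug!r}")

    def _meta(level: str, ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        fits = []
        for s in studies:
            d = per_study.get(s)
            if d is None:
                fits.append(None)
                continue
            fits.append((d[f"beta_{level}"], d[f"p_{level}"], d["n"]))
        beta = np.full(len(ids), np.nan)
        p = np.full(len(ids), np.nan)
        nn = np.zeros(len(ids), int)
        for k in range(len(ids)):
            mf = meta_combine(
                *[
                    ModelFit(beta=f[0][k], p_value=f[1][k], n=f[2]) if f is not None else None
                    for f in (fits + [None] * (2 - len(fits)))
                ][:2]
            )
            beta[k], p[k], nn[k] = mf.beta, mf.p_value, mf.n
        return beta, p, nn

    meta_beta_g, meta_p_g, meta_n_g = _meta("gene", gene_ids)
    meta_beta_i, meta_p_i, _ = _meta("iso", iso_ids)

    # best isoform per gene: smallest Bonferroni-corrected meta p-value
    iso_frame = pd.DataFrame(
        {"gene": iso_gene.to_numpy(), "beta": meta_beta_i, "p": meta_p_i}, index=iso_ids
    )
    best_iso = {}
    for g, grp in iso_frame.groupby("gene"):
        fits = {
            iso: ModelFit(beta=row.beta, p_value=row.p, n=0)
            for iso, row in grp.iterrows()
            if np.isfinite(row.beta) and np.isfinite(row.p)
        }
        if fits:
            best_iso[g] = select_best_isoform(g, fits)[0]

    genes_list = [g for g in gene_ids]
    best_list = [best_iso.get(g) for g in genes_list]

    # pooled bootstrap CI: per study, genes + best isoforms + null, shared resamples
    G = len(genes_list)
    ci_gene_chunks, ci_iso_chunks, null_chunks = [], [], []
    for si, s in enumerate(studies):
        d = per_study.get(s)
        if d is None:
            continue
        cells = d["cells"]
        Xg = expr.genes.loc[genes_list, cells].to_numpy()
        iso_rows = [b if b is not None else iso_ids[0] for b in best_list]
        Xb = expr.isoforms.loc[iso_rows, cells].to_numpy()
        X = np.vstack([Xg, Xb])
        splan = BootstrapPlan(n_boot=plan.n_boot, seed=plan.seed + 1000003 * si)
        ci, null_ci = bootstrap_ci_batch(X, d["y"], d["codes"], d["n_levels"], splan)
        ci_gene_chunks.append(ci[:G])
        ci_iso_chunks.append(ci[G:])
        null_chunks.append(null_ci)

    ci_gene = np.hstack(ci_gene_chunks)
    ci_iso = np.hstack(ci_iso_chunks)
    null_ci = np.hstack(null_chunks)

    med_gene = np.nanmedian(np.where(np.isfinite(ci_gene), ci_gene, np.nan), axis=1)
    med_iso = np.nanmedian(np.where(np.isfinite(ci_iso), ci_iso, np.nan), axis=1)
    wp_gene = np.array([compare_models(ci_gene[k], null_ci).p_vs_null for k in range(G)])
    wp_iso = np.array(
        [
            compare_models(ci_iso[k], null_ci).p_vs_null if best_list[k] is not None else np.nan
            for k in range(G)
        ]
    )

    records = pd.DataFrame(
        {
            "gene_id": genes_list,
            "best_isoform_id": best_list,
            "drug": drug,
            "meta_beta_gene": meta_beta_g,
            "meta_p_gene": meta_p_g,
            "meta_beta_isoform": [
                iso_frame.loc[b, "beta"] if b is not None else np.nan for b in best_list
            ],
            "meta_p_isoform": [
                iso_frame.loc[b, "p"] if b is not None else np.nan for b in best_list
            ],
            "n_meta": meta_n_g,
            "ci_gene": med_gene,
            "ci_isoform": np.where([b is not None for b in best_list], med_iso, np.nan),
            "wilcoxon_p_gene": wp_gene,
            "wilcoxon_p_isoform": wp_iso,
        }
    )
    calls = call_biomarkers(
        records,
        fdr_threshold=fdr_threshold,
        ci_threshold=ci_threshold,
        wilcoxon_alpha=wilcoxon_alpha,
    )
    return DiscoveryResult(
        calls=calls,
        drug=drug,
        studies=list(per_study),
        n_cells={s: per_study[s]["n"] for s in per_study},
    )
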