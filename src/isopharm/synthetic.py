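"""Synthetic multi-study pharmacogenomic data with planted associations.

The generator emulates the structure of a multi-study cell-line screen:

* an expression panel of genes with 1..k isoforms on the log2(FPKM+1)
  scale, with tissue-structured baselines and controllable within-gene
  isoform correlation (gene-level values always aggregate isoform FPKM
  additively: ``gene = log2(1 + sum(2**iso - 1))``);
* AAC drug-sensitivity values in [0, 1] built from a tissue effect plus a
  linear effect of each planted feature plus Gaussian noise, through a
  clamped affine map so planted coefficients stay interpretable in
  standardized units;
* replicate "studies" that share the linear signal but draw independent
  sensitivity noise, optionally calibrated to a target between-study
  Spearman correlation.

Isoform-specific planted signals are carried by a deliberately
low-abundance isoform whose siblings are independent high-abundance noise,
so gene-level aggregation dilutes the signal — the regime in which
isoform-level biomarkers outperform gene-level ones.

Randomness is split into named substreams derived from ``(seed, label)``
via ``numpy.random.SeedSequence``, so every output is fully determined by
the configuration (including across study identifiers) and stable across
platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DoseResponseExperiment, ExpressionDataset, SensitivityTable, aggregate_isoforms
from .dose_response import hill_viability

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_expression",
    "simulate_sensitivity",
    "simulate_study_pair",
    "simulate_plates",
]

MODES = ("gene_level", "isoform_specific", "both")

# log2(FPKM+1) baseline means: planted isoforms are minor transcripts whose
# high-abundance siblings dominate the gene-level FPKM sum
PLANTED_ISOFORM_BASELINE = 2.0
SIBLING_BASELINE = 5.0
TISSUE_EXPR_SD = 0.5
AAC_CENTER = 0.5
AAC_SCALE = 0.125  # AAC spread: +/-4 sd of the linear predictor spans [0, 1]


@dataclass(frozen=True)
class PlantedEffect:
    """One true feature-drug association planted into the simulation."""

    feature_id: str
    beta: float
    mode: str
    drug: str | None = None  # None -> the first configured drug

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not np.isfinite(self.beta):
            raise ValueError("effect size must be finite")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    ``isoforms_per_gene`` is either a fixed count or a probability mapping
    {k: weight} over isoform counts. ``inter_study_rho`` (when set) is the
    target Spearman correlation of AAC between the two study replicates and
    overrides ``noise_sd`` with a calibrated noise level; when None the
    sensitivity noise standard deviation is ``noise_sd`` in the standardized
    units of the linear predictor.
    """

    n_cell_lines: int = 100
    n_tissues: int = 4
    n_genes: int = 100
    isoforms_per_gene: int | dict = 3
    planted_effects: list = field(default_factory=list)
    noise_sd: float = 0.3
    inter_study_rho: float | None = None
    expression_noise_sd: float = 1.0
    within_gene_correlation: float = 0.3
    drugs: tuple = ("drug_1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0 or self.n_genes <= 0 or self.n_tissues <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_cell_lines < self.n_tissues:
            raise ValueError("need n_cell_lines >= n_tissues")
        if self.inter_study_rho is not None and not 0 <= self.inter_study_rho <= 1:
            raise ValueError("inter_study_rho must lie in [0, 1]")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.within_gene_correlation <= 1:
            raise ValueError("within_gene_correlation must lie in [0, 1]")
        self.planted_effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
            for e in self.planted_effects
        ]

    def rng(self, *labels) -> np.random.Generator:
        """Named, platform-stable substream of the configured seed."""
        key = [zlib.crc32(str(l).encode()) for l in labels]
        return np.random.default_rng(np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF] + key))


@dataclass
class SyntheticStudy:
    """One simulated study: expression, sensitivity and the planted truth."""

    expression: ExpressionDataset
    sensitivity: SensitivityTable
    truth: pd.DataFrame  # columns: feature_id, drug, beta, mode

    def __post_init__(self) -> None:
        missing = set(self.sensitivity.data["cell_line"]) - set(self.expression.cell_lines)
        if missing:
            raise ValueError(f"sensitivity cell lines absent from expression: {sorted(missing)[:5]}")


def _isoform_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.isoforms_per_gene
    if isinstance(spec, int):
        return np.full(config.n_genes, spec, dtype=int)
    ks = np.array(sorted(spec), dtype=int)
    w = np.array([spec[k] for k in ks], dtype=float)
    return rng.choice(ks, size=config.n_genes, p=w / w.sum())


def simulate_expression(config: SimulationConfig) -> ExpressionDataset:
    """Generate the isoform and gene expression matrices with tissue labels.

    Isoform values are baseline + per-(gene, tissue) shift + correlated cell
    noise, clipped at 0 to stay on the log2(FPKM+1) scale. Within a gene,
    isoforms share a latent cell factor with weight
    ``sqrt(within_gene_correlation)`` — except in genes carrying an
    isoform-specific planted effect, whose isoforms are mutually independent
    so that exactly one isoform carries the downstream signal.
    """
    rng = config.rng("expression")
    n = config.n_cell_lines
    cells = pd.Index([f"cl_{i:04d}" for i in range(n)], name="cell_line")
    tissue_labels = [f"tissue_{t}" for t in range(config.n_tissues)]
    assignment = np.sort(np.arange(n) % config.n_tissues)
    assignment = rng.permutation(assignment)
    tissues = pd.Series([tissue_labels[a] for a in assignment], index=cells, name="tissue")

    counts = _isoform_counts(config, rng)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    planted_iso_genes = set()
    planted_isoforms = set()
    for eff in config.planted_effects:
        if eff.mode in ("isoform_specific", "both") and "." in eff.feature_id:
            planted_isoforms.add(eff.feature_id)
            planted_iso_genes.add(eff.feature_id.split(".")[0])

    iso_ids, iso_gene, rows = [], [], []
    sd = config.expression_noise_sd
    c = config.within_gene_correlation
    for gi, g in enumerate(gene_ids):
        k = counts[gi]
        latent = rng.standard_normal(n)
        tissue_shift = rng.normal(0.0, TISSUE_EXPR_SD, size=config.n_tissues)[assignment]
        independent = g in planted_iso_genes
        for j in range(k):
            iso = f"{g}.t{j}"
            if iso in planted_isoforms:
                base = PLANTED_ISOFORM_BASELINE
            elif independent:
                base = SIBLING_BASELINE
            else:
                base = rng.uniform(2.0, 6.0)
            eps = rng.standard_normal(n)
            noise = eps if independent else np.sqrt(c) * latent + np.sqrt(1.0 - c) * eps
            rows.append(np.clip(base + tissue_shift + sd * noise, 0.0, None))
            iso_ids.append(iso)
            iso_gene.append(g)

    isoforms = pd.DataFrame(rows, index=pd.Index(iso_ids, name="isoform_id"), columns=cells)
    isoform_map = pd.Series(iso_gene, index=isoforms.index, name="gene_id")
    genes = aggregate_isoforms(isoforms, isoform_map)
    genes = genes.reindex(gene_ids)
    return ExpressionDataset(isoforms=isoforms, genes=genes, isoform_map=isoform_map, tissues=tissues)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _signal_vector(expr: ExpressionDataset, config: SimulationConfig, drug: str) -> np.ndarray:
    """Tissue effect plus planted linear signal, in standardized units."""
    cells = expr.cell_lines
    tissues = expr.tissues.reindex(cells)
    levels = sorted(tissues.unique())
    rng_t = config.rng("tissue_effect", drug)
    t_eff = dict(zip(levels, rng_t.normal(0.0, 1.0, size=len(levels))))
    signal = tissues.map(t_eff).to_numpy(dtype=float)

    first_drug = config.drugs[0]
    for eff in config.planted_effects:
        if (eff.drug or first_drug) != drug:
            continue
        terms = []
        if eff.mode in ("gene_level", "both"):
            gene = eff.feature_id.split(".")[0]
            if gene not in expr.genes.index:
                raise KeyError(f"unknown planted gene {gene!r}")
            terms.append(expr.genes.loc[gene].to_numpy())
        if eff.mode in ("isoform_specific", "both"):
            if eff.feature_id not in expr.isoforms.index:
                raise KeyError(f"unknown planted isoform {eff.feature_id!r}")
            terms.append(expr.isoforms.loc[eff.feature_id].to_numpy())
        for term in terms:
            signal = signal + eff.beta * _standardize(term)
    return signal


def _noise_sd(config: SimulationConfig, signal: np.ndarray) -> float:
    """Per-study noise level, calibrated when a target Spearman is requested.

    Two studies share ``signal`` and add independent N(0, sigma^2) noise, so
    their Pearson correlation is var(signal) / (var(signal) + sigma^2).
    The Spearman target is mapped to the Pearson scale via the bivariate
    normal relation rho_P = 2 sin(pi rho_S / 6).
    """
    if config.inter_study_rho is None:
        return config.noise_sd
    rho_s = config.inter_study_rho
    if rho_s <= 0:
        return np.inf  # signal carries no weight: callers emit pure noise
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    s_var = float(np.var(signal))
    if rho_p >= 1.0 - 1e-12 or s_var == 0.0:
        return 0.0
    return float(np.sqrt(s_var * (1.0 - rho_p) / rho_p))


def simulate_sensitivity(
    expr: ExpressionDataset, config: SimulationConfig, study_id: str
) -> SensitivityTable:
    """Generate AAC values for every configured drug in one study.

    AAC = clip(0.5 + scale * (tissue effect + sum beta * standardized feature
    + noise) / sd, 0, 1), with the standardizing ``sd`` shared between the
    study replicates so the affine map is monotone and common across studies.
    Deterministic given (config seed, study_id).
    """
    cells = expr.cell_lines
    frames = []
    for drug in config.drugs:
        signal = _signal_vector(expr, config, drug)
        sigma = _noise_sd(config, signal)
        rng = config.rng("sensitivity", study_id, drug)
        if np.isinf(sigma):  # inter_study_rho == 0: no shared component at all
            lp = rng.standard_normal(len(cells))
            scale_sd = 1.0
        else:
            noise = rng.standard_normal(len(cells)) * sigma if sigma > 0 else 0.0
            lp = signal + noise
            scale_sd = float(np.sqrt(np.var(signal) + sigma**2))
        if scale_sd == 0:
            aac = np.full(len(cells), AAC_CENTER)
        else:
            aac = np.clip(AAC_CENTER + AAC_SCALE * lp / scale_sd, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {"cell_line": cells, "drug": drug, "aac": aac, "study_id": study_id}
            )
        )
    return SensitivityTable(pd.concat(frames, ignore_index=True))


def _truth_frame(config: SimulationConfig) -> pd.DataFrame:
    first = config.drugs[0]
    return pd.DataFrame(
        [
            {"feature_id": e.feature_id, "drug": e.drug or first, "beta": e.beta, "mode": e.mode}
            for e in config.planted_effects
        ],
        columns=["feature_id", "drug", "beta", "mode"],
    )


def simulate_study_pair(
    config: SimulationConfig, study_ids: tuple = ("study_1", "study_2")
) -> tuple[SyntheticStudy, SyntheticStudy]:
    """Two studies over the same expression panel with independent AAC noise."""
    expr = simulate_expression(config)
    truth = _truth_frame(config)
    return tuple(
        SyntheticStudy(
            expression=expr,
            sensitivity=simulate_sensitivity(expr, config, s),
            truth=truth,
        )
        for s in study_ids
    )


def simulate_plates(
    hill_params: tuple,
    dose_grid,
    replicate_cv: float = 0.05,
    n_replicates: int = 3,
    cell_line: str = "cl_sim",
    drug: str = "drug_sim",
    control_signal: float = 1.0,
    blank_signal: float = 0.05,
    n_control: int = 6,
    n_blank: int = 6,
    seed: int = 0,
) -> DoseResponseExperiment:
    """Simulate a raw SRB-style plate around a Hill curve.

    ``hill_params`` is (ec50, slope, e_inf). Raw well signal is
    ``blank + control * viability`` with multiplicative replicate noise of
    coefficient of variation ``replicate_cv`` (``replicate_cv = 0`` puts the
    replicates exactly on the curve). Control and blank wells are included so
    the full SRB preprocessing path is exercised.
    """
    doses = np.asarray(dose_grid, dtype=float)
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be positive and strictly increasing")
    ec50, slope, e_inf = hill_params
    rng = np.random.default_rng(seed)
    v = hill_viability(doses, ec50, slope, e_inf)

    def jitter(shape):
        if replicate_cv > 0:
            return 1.0 + replicate_cv * rng.standard_normal(shape)
        return np.ones(shape)

    treated = blank_signal + control_signal * v[None, :] * jitter((n_replicates, doses.size))
    controls = blank_signal + control_signal * np.ones(n_control) * jitter(n_control)
    blanks = blank_signal * np.ones(n_blank)
    return DoseResponseExperiment(
        cell_line=cell_line,
        drug=drug,
        doses=doses,
        viabilities=treated,
        control_wells=np.asarray(controls, float),
        blank_wells=blanks,
    )
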