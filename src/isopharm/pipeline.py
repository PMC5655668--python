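"""End-to-end orchestration: simulate -> discover -> pre-validate -> validate.

A run is described by a :class:`RunConfig` (loadable from YAML), executes
stage by stage with per-stage logging, writes every intermediate table as
TSV, and ends with a JSON manifest listing thresholds, seeds, stage counts
and a content hash of every output file. The manifest carries no timestamps,
so re-running an identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datasets import ExpressionDataset, SensitivityTable
from .discovery import BootstrapPlan, discover
from .synthetic import SimulationConfig, simulate_expression, simulate_sensitivity
from .validation import ValidationRule, outcomes_frame, preselect_tissue, validate, validation_rate

__all__ = ["RunConfig", "run_pipeline", "filter_shared_cell_lines", "PipelineError"]

log = logging.getLogger("isopharm")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulation`` describes a synthetic run (expression shared by the
    two training studies plus an independently-noised validation study), or
    the ``*_path`` fields point at TSV inputs written in the same layout the
    simulator emits. Exactly two training studies feed meta-combination.
    """

    outdir: str = "isopharm_run"
    seed: int = 1234
    drugs: list = field(default_factory=lambda: ["drug_1"])
    training_studies: list = field(default_factory=lambda: ["study_1", "study_2"])
    validation_study: str | None = "study_val"
    fdr_threshold: float = 0.01
    ci_threshold: float = 0.55
    alpha: float = 0.05
    qc_threshold: float = 0.2
    n_boot: int = 100
    n_min: int = 20
    prevalidation_tissue: str | None = None
    simulation: SimulationConfig | None = None
    expression_dir: str | None = None
    sensitivity_paths: dict = field(default_factory=dict)  # study_id -> TSV path
    identity_table_path: str | None = None
    identity_cutoff: float = 0.80

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
            ("fdr_threshold", self.fdr_threshold, 0.0, 1.0),
            ("ci_threshold", self.ci_threshold, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("identity_cutoff", self.identity_cutoff, 0.0, 1.0),
        ):
            if not lo < v <= hi if name != "ci_threshold" else not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.qc_threshold <= 0:
            raise ValueError("qc_threshold must be positive")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if len(self.training_studies) != 2:
            raise ValueError("meta-combination requires exactly two training studies")
        if self.simulation is None and self.expression_dir is None:
            raise ValueError("either a simulation block or input paths are required")
        if self.simulation is None:
            for study in self.training_studies:
                p = self.sensitivity_paths.get(study)
                if p is None or not Path(p).exists():
                    raise ValueError(f"missing sensitivity table for study {study!r}")
            if not Path(self.expression_dir).exists():
                raise ValueError(f"expression_dir {self.expression_dir!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def filter_shared_cell_lines(
    study_tables: dict, identity_table: pd.DataFrame, cutoff: float = 0.80
) -> dict:
    """Drop cell lines whose cross-study identity concordance falls below cutoff.

    ``identity_table`` has columns ``cell_line`` and ``concordance`` in
    [0, 1] (identity fingerprinting is assumed done upstream). The cutoff is
    inclusive: concordance exactly at the cutoff is retained. After the
    identity filter the tables are restricted to the cell lines and drugs
    common to all studies; an empty intersection aborts.
    """
    bad = set(
        identity_table.loc[identity_table["concordance"] < cutoff, "cell_line"]
    )
    filtered = {s: t.subset_cells(set(t.data["cell_line"]) - bad) for s, t in study_tables.items()}
    cell_sets = [set(t.data["cell_line"]) for t in filtered.values()]
    drug_sets = [set(t.data["drug"]) for t in filtered.values()]
    cells = set.intersection(*cell_sets) if cell_sets else set()
    drugs = set.intersection(*drug_sets) if drug_sets else set()
    if not cells or not drugs:
        raise PipelineError("identity filter left no shared cell lines or drugs across studies")
    out = {}
    for s, t in filtered.items():
        keep = t.data["cell_line"].isin(cells) & t.data["drug"].isin(drugs)
        out[s] = SensitivityTable(t.data.loc[keep].reset_index(drop=True))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written as JSON).

    Stage order: load-or-simulate inputs, identity filtering, per-drug
    discovery, optional single-tissue pre-selection, validation on the
    held-out study. Any stage failure raises :class:`PipelineError` naming
    the stage; partial outputs already written are retained alongside a
    ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = BootstrapPlan(n_boot=config.n_boot, seed=config.seed)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr_threshold,
            "ci": config.ci_threshold,
            "alpha": config.alpha,
            "qc": config.qc_threshold,
            "identity_cutoff": config.identity_cutoff,
        },
        "n_boot": config.n_boot,
        "training_studies": list(config.training_studies),
        "stages": {},
        "outputs": {},
    }
    stage = "inputs"
    try:
        if config.simulation is not None:
            expr = simulate_expression(config.simulation)
            sens = {
                s: simulate_sensitivity(expr, config.simulation, s)
                for s in config.training_studies
            }
            v_expr, v_sens = None, None
            if config.validation_study:
                v_expr = expr
                v_sens = simulate_sensitivity(expr, config.simulation, config.validation_study)
            expr.to_tsv_dir(outdir / "expression")
            for s, t in sens.items():
                _write_tsv(t.data, outdir / f"sensitivity_{s}.tsv")
            drugs = list(config.simulation.drugs)
        else:
            expr = ExpressionDataset.from_tsv_dir(config.expression_dir)
            sens = {
                s: SensitivityTable.from_tsv(config.sensitivity_paths[s])
                for s in config.training_studies
            }
            v_expr = v_sens = None
            if config.validation_study and config.validation_study in config.sensitivity_paths:
                v_expr = expr
                v_sens = SensitivityTable.from_tsv(
                    config.sensitivity_paths[config.validation_study]
                )
            drugs = list(config.drugs)
        manifest["stages"]["inputs"] = {
            "cell_lines": int(len(expr.cell_lines)),
            "genes": int(expr.genes.shape[0]),
            "isoforms": int(expr.isoforms.shape[0]),
        }

        stage = "identity_filter"
        if config.identity_table_path:
            ident = pd.read_csv(config.identity_table_path, sep="\t")
            before = {s: len(t.data) for s, t in sens.items()}
            sens = filter_shared_cell_lines(sens, ident, config.identity_cutoff)
            manifest["stages"]["identity_filter"] = {
                "rows_before": before,
                "rows_after": {s: len(t.data) for s, t in sens.items()},
            }

        stage = "discover"
        all_calls = []
        for drug in drugs:
            log.info("discover: %s", drug)
            res = discover(
                expr,
                sens,
                drug,
                plan=plan,
                fdr_threshold=config.fdr_threshold,
                ci_threshold=config.ci_threshold,
                n_min=config.n_min,
            )
            all_calls.append(res.calls)
        calls = pd.concat(all_calls, ignore_index=True)
        _write_tsv(calls, outdir / "biomarker_calls.tsv")
        hits = calls[calls["category"] != "none"]
        manifest["stages"]["discover"] = {
            "drugs": drugs,
            "records": int(len(calls)),
            "calls": int(len(hits)),
            "by_category": hits["category"].value_counts().to_dict(),
        }

        stage = "prevalidate"
        candidates = _candidates_from_calls(hits)
        if config.prevalidation_tissue and not candidates.empty:
            candidates = preselect_tissue(
                candidates,
                expr,
                SensitivityTable.concat(list(sens.values())),
                tissue=config.prevalidation_tissue,
                ci_threshold=config.ci_threshold,
                alpha=config.alpha,
                plan=plan,
                n_min=config.n_min,
            )
            manifest["stages"]["prevalidate"] = {"candidates": int(len(candidates))}
        _write_tsv(candidates, outdir / "candidates.tsv")

        stage = "validate"
        if v_sens is not None and not candidates.empty:
            rule = ValidationRule(alpha=config.alpha, tissue_adjusted=True)
            outcomes = validate(candidates, v_expr, v_sens, rule, n_min=config.n_min)
            vframe = outcomes_frame(outcomes)
            _write_tsv(vframe, outdir / "validation.tsv")
            manifest["stages"]["validate"] = {
                "tested": int(vframe["testable"].sum()) if len(vframe) else 0,
                "validated": int(vframe["validated"].sum()) if len(vframe) else 0,
                "validation_rate": validation_rate(outcomes),
            }

        stage = "manifest"
        for f in sorted(outdir.rglob("*.tsv")):
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _candidates_from_calls(hits: pd.DataFrame) -> pd.DataFrame:
    """One candidate row per significant level of each biomarker call."""
    rows = []
    for _, r in hits.iterrows():
        if r["category"] in ("gene_specific", "common"):
            rows.append((r["gene_id"], "gene", r["drug"], r["meta_beta_gene"]))
        if r["category"] in ("isoform_specific", "common") and r["best_isoform_id"]:
            rows.append((r["best_isoform_id"], "isoform", r["drug"], r["meta_beta_isoform"]))
    return pd.DataFrame(rows, columns=["feature_id", "level", "drug", "beta_train"])
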