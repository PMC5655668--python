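"""Core data containers for the pharmacogenomic pipeline.

All tabular I/O is tab-separated text with a header row; cell-line
identifiers are case-sensitive exact-match keys shared across tables.
Expression values are on the log2(FPKM+1) scale throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SensitivityTable",
    "DoseResponseExperiment",
    "aggregate_isoforms",
]


def aggregate_isoforms(isoform_matrix: pd.DataFrame, isoform_map: pd.Series) -> pd.DataFrame:
    """Aggregate an isoform expression matrix to gene level.

    FPKM of a gene is the sum of the FPKM of its isoforms, so on the
    log2(FPKM+1) scale the gene value is ``log2(1 + sum(2**iso - 1))``.

    Parameters
    ----------
    isoform_matrix : DataFrame, isoforms x cell lines, log2(FPKM+1)
    isoform_map : Series mapping isoform_id -> gene_id

    Returns
    -------
    DataFrame, genes x cell lines, log2(FPKM+1)
    """
    missing = isoform_matrix.index.difference(isoform_map.index)
    if len(missing):
        raise ValueError(f"isoforms missing from map: {list(missing[:5])}")
    fpkm = np.exp2(isoform_matrix) - 1.0
    gene_fpkm = fpkm.groupby(isoform_map.reindex(isoform_matrix.index)).sum()
    gene_fpkm.index.name = "gene_id"
    return np.log2(gene_fpkm + 1.0)


@dataclass
class ExpressionDataset:
    """Isoform- and gene-level expression for a panel of cell lines.

    Attributes
    ----------
    isoforms : DataFrame, isoforms x cell lines, log2(FPKM+1)
    genes : DataFrame, genes x cell lines, log2(FPKM+1)
    isoform_map : Series, isoform_id -> gene_id (each isoform maps to one gene)
    tissues : Series, cell_line -> tissue label (no missing labels)
    """

    isoforms: pd.DataFrame
    genes: pd.DataFrame
    isoform_map: pd.Series
    tissues: pd.Series

    def __post_init__(self) -> None:
        if not self.isoforms.columns.equals(self.genes.columns):
            raise ValueError("isoform and gene matrices must share identical cell-line columns")
        unmapped = self.isoforms.index.difference(self.isoform_map.index)
        if len(unmapped):
            raise ValueError(f"unmapped isoforms: {list(unmapped[:5])}")
        missing_tissue = self.isoforms.columns.difference(self.tissues.index)
        if len(missing_tissue):
            raise ValueError(f"cell lines without tissue label: {list(missing_tissue[:5])}")
        if self.tissues.reindex(self.isoforms.columns).isna().any():
            raise ValueError("missing tissue labels")

    @property
    def cell_lines(self) -> pd.Index:
        return self.isoforms.columns

    def feature_level(self, feature_id: str) -> str:
        """Classify a feature identifier as ``gene`` or ``isoform``."""
        if feature_id in self.genes.index:
            return "gene"
        if feature_id in self.isoforms.index:
            return "isoform"
        raise KeyError(f"unknown feature: {feature_id!r}")

    def feature_values(self, feature_id: str) -> pd.Series:
        level = self.feature_level(feature_id)
        matrix = self.genes if level == "gene" else self.isoforms
        return matrix.loc[feature_id]

    def subset_cells(self, cells) -> "ExpressionDataset":
        cells = pd.Index(cells)
        return ExpressionDataset(
            isoforms=self.isoforms[cells],
            genes=self.genes[cells],
            isoform_map=self.isoform_map,
            tissues=self.tissues.reindex(cells),
        )

    def to_tsv_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.isoforms.rename_axis("isoform_id").to_csv(outdir / "isoforms.tsv", sep="\t")
        self.genes.rename_axis("gene_id").to_csv(outdir / "genes.tsv", sep="\t")
        self.isoform_map.rename_axis("isoform_id").rename("gene_id").to_csv(
            outdir / "isoform_map.tsv", sep="\t"
        )
        self.tissues.rename_axis("cell_line").rename("tissue").to_csv(
            outdir / "tissues.tsv", sep="\t"
        )

    @classmethod
    def from_tsv_dir(cls, indir) -> "ExpressionDataset":
        indir = Path(indir)
        isoforms = pd.read_csv(indir / "isoforms.tsv", sep="\t", index_col=0)
        genes = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
        isoform_map = pd.read_csv(indir / "isoform_map.tsv", sep="\t", index_col=0)["gene_id"]
        tissues = pd.read_csv(indir / "tissues.tsv", sep="\t", index_col=0)["tissue"]
        return cls(isoforms=isoforms, genes=genes, isoform_map=isoform_map, tissues=tissues)


@dataclass
class SensitivityTable:
    """Drug-sensitivity summaries: one AAC per (cell line, drug, study).

    AAC (area above the dose-response curve, 1 - AUC) lies in [0, 1];
    higher values mean higher drug sensitivity.
    """

    data: pd.DataFrame  # columns: cell_line, drug, aac, study_id

    REQUIRED = ("cell_line", "drug", "aac", "study_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sensitivity table missing columns: {missing}")
        aac = self.data["aac"].to_numpy(float)
        if np.any((aac < 0) | (aac > 1) | ~np.isfinite(aac)):
            raise ValueError("AAC values must lie in [0, 1]")
        if self.data.duplicated(["cell_line", "drug", "study_id"]).any():
            raise ValueError("duplicate (cell_line, drug, study_id) rows")

    @property
    def studies(self) -> list:
        return sorted(self.data["study_id"].unique())

    @property
    def drugs(self) -> list:
        return sorted(self.data["drug"].unique())

    def aac_vector(self, drug: str, study_id=None) -> pd.Series:
        """AAC values for one drug (optionally one study), indexed by cell line."""
        sub = self.data[self.data["drug"] == drug]
        if study_id is not None:
            sub = sub[sub["study_id"] == study_id]
        return pd.Series(sub["aac"].to_numpy(), index=pd.Index(sub["cell_line"], name="cell_line"))

    def subset_cells(self, cells) -> "SensitivityTable":
        keep = self.data["cell_line"].isin(set(cells))
        return SensitivityTable(self.data.loc[keep].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SensitivityTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def concat(cls, tables) -> "SensitivityTable":
        return cls(pd.concat([t.data for t in tables], ignore_index=True))


@dataclass
class DoseResponseExperiment:
    """One drug screened against one cell line on a dose grid.

    ``viabilities`` is a replicates x doses matrix of raw well signal
    (or normalized viability once :func:`~isopharm.dose_response.preprocess_srb`
    has run). NaN marks discarded wells/doses. Controls are untreated wells,
    blanks are cell-free (PBS) wells.
    """

    cell_line: str
    drug: str
    doses: np.ndarray
    viabilities: np.ndarray
    control_wells: np.ndarray = field(default_factory=lambda: np.array([]))
    blank_wells: np.ndarray = field(default_factory=lambda: np.array([]))
    normalized: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viabilities = np.atleast_2d(np.asarray(self.viabilities, dtype=float))
        self.control_wells = np.asarray(self.control_wells, dtype=float)
        self.blank_wells = np.asarray(self.blank_wells, dtype=float)
        if self.doses.size < 2:
            raise ValueError("need at least 2 doses")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.viabilities.shape[1] != self.doses.size:
            raise ValueError("viability matrix must have one column per dose")

    @property
    def dose_range(self) -> tuple[float, float]:
        return float(self.doses[0]), float(self.doses[-1])

    def replace(self, **kwargs) -> "DoseResponseExperiment":
        return dataclasses.replace(self, **kwargs)

    def to_long_frame(self) -> pd.DataFrame:
        """Long plate format: cell_line, drug, dose_uM, replicate, raw_signal, well_type."""
        rows = []
        for r in range(self.viabilities.shape[0]):
            for j, d in enumerate(self.doses):
                rows.append((self.cell_line, self.drug, d, r + 1, self.viabilities[r, j], "treated"))
        for r, v in enumerate(self.control_wells):
            rows.append((self.cell_line, self.drug, np.nan, r + 1, v, "control"))
        for r, v in enumerate(self.blank_wells):
            rows.append((self.cell_line, self.drug, np.nan, r + 1, v, "blank"))
        return pd.DataFrame(
            rows, columns=["cell_line", "drug", "dose_uM", "replicate", "raw_signal", "well_type"]
        )


def read_plates(path) -> list[DoseResponseExperiment]:
    """Read dose-response experiments from a long-format plate TSV."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (cl, drug), grp in df.groupby(["cell_line", "drug"], sort=True):
        treated = grp[grp["well_type"] == "treated"]
        doses = np.sort(treated["dose_uM"].unique())
        piv = treated.pivot_table(
            index="replicate", columns="dose_uM", values="raw_signal", aggfunc="first"
        ).reindex(columns=doses)
        out.append(
            DoseResponseExperiment(
                cell_line=cl,
                drug=drug,
                doses=doses,
                viabilities=piv.to_numpy(),
                control_wells=grp.loc[grp["well_type"] == "control", "raw_signal"].to_numpy(),
                blank_wells=grp.loc[grp["well_type"] == "blank", "raw_signal"].to_numpy(),
            )
        )
    return out


def write_plates(experiments, path) -> None:
    pd.concat([e.to_long_frame() for e in experiments], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
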