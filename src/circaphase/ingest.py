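"""Reading and validating expression matrices and applying the TPM filter.

Input formats: a genes x samples TPM matrix as tab-delimited text with a
header row of sample ids, and a CSV sample sheet with columns sample_id,
experiment (V1/V2), condition (18C/25C), zt_hours, replicate. Zeitgeber
times are reduced modulo 24 on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EXPERIMENTS = ("V1", "V2")
CONDITIONS = ("18C", "25C")

SAMPLESHEET_COLUMNS = ["sample_id", "experiment", "condition", "zt_hours", "replicate"]


@dataclass
class ExpressionMatrix:
    """TPM values (genes x samples) plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``samples`` is a DataFrame with one row per column of ``values``, in
    column order, carrying experiment, condition, zt_hours, replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample sheet rows must match matrix columns in order")
        self.samples = self.samples.copy()
        self.samples["zt_hours"] = self.samples["zt_hours"].astype(float) % 24.0

    @property
    def gene_ids(self):
        return self.values.index

    def subset(self, experiment: str | None = None, condition: str | None = None) -> "ExpressionMatrix":
        """Column subset by experiment and/or condition."""
        mask = pd.Series(True, index=self.samples.index)
        if experiment is not None:
            mask &= self.samples["experiment"] == experiment
        if condition is not None:
            mask &= self.samples["condition"] == condition
        sub = self.samples[mask]
        return ExpressionMatrix(self.values[sub["sample_id"].tolist()], sub.reset_index(drop=True))


def read_expression(matrix_path, samplesheet_path, min_timepoints: int = 6) -> ExpressionMatrix:
    """Load a TPM matrix (TSV) and its sample sheet (CSV) into one object.

    Every matrix column must appear in the sheet; per (experiment,
    condition) group at least ``min_timepoints`` distinct ZT values are
    required for a harmonic fit to be meaningful downstream.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    sheet = pd.read_csv(samplesheet_path, dtype={"sample_id": str})
    missing_cols = set(SAMPLESHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {sorted(missing_cols)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    sheet = sheet.set_index("sample_id", drop=False)
    unmatched = [c for c in values.columns if c not in sheet.index]
    if unmatched:
        raise ValueError(f"no metadata for sample(s): {unmatched}")
    sheet = sheet.loc[list(values.columns)].reset_index(drop=True)
    bad_exp = set(sheet["experiment"]) - set(EXPERIMENTS)
    if bad_exp:
        raise ValueError(f"unknown experiment labels: {sorted(bad_exp)}")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    mat = ExpressionMatrix(values, sheet)
    for (exp, cond), grp in mat.samples.groupby(["experiment", "condition"]):
        n_zt = grp["zt_hours"].round(9).nunique()
        if n_zt < min_timepoints:
            raise ValueError(f"({exp}, {cond}) has only {n_zt} distinct ZT values (< {min_timepoints})")
    return mat


def filter_genes(mats: dict, tpm_threshold: float = 5.0) -> list:
    """Genes expressed above the median-TPM threshold, consistently.

    ``mats`` maps (experiment, condition) -> ExpressionMatrix over a shared
    gene universe. A gene is kept iff, within EACH experiment, its median
    TPM (replicates pooled across all samples of the condition) is strictly
    greater than ``tpm_threshold`` in at least one of the two conditions.
    Gene order of the first matrix is preserved.
    """
    keys = list(mats)
    if not keys:
        raise ValueError("no matrices given")
    universe = list(mats[keys[0]].gene_ids)
    for k in keys[1:]:
        if set(mats[k].gene_ids) != set(universe):
            raise ValueError(f"gene universe of {k} differs from {keys[0]}")
    experiments = sorted({e for e, _ in keys})
    keep = pd.Series(True, index=pd.Index(universe))
    for exp in experiments:
        conds = [c for e, c in keys if e == exp]
        passing_any = pd.Series(False, index=keep.index)
        for cond in conds:
            med = mats[(exp, cond)].values.median(axis=1)
            passing_any |= med.reindex(keep.index) > tpm_threshold
        keep &= passing_any
    return [g for g in universe if keep[g]]


def write_expression(mat: ExpressionMatrix, matrix_path, samplesheet_path) -> None:
    """Write the matrix as TSV and the sample sheet as CSV."""
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    mat.values.to_csv(matrix_path, sep="\t")
    mat.samples[SAMPLESHEET_COLUMNS].to_csv(samplesheet_path, index=False)
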