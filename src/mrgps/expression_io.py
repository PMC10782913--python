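"""Reading, validation and harmonization of expression matrices and clinical tables.

Expression values must be *within-sample comparable*: a single monotone
transform (typically ``log2(x + 1)`` of TPM/FPKM) applied to every gene of a
sample. The downstream pair encoding only compares two genes inside the same
sample, so no cross-cohort normalization is performed here — that robustness
is the point of the pair representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.44

REQUIRED_CLINICAL_COLUMNS = ("sample_id", "time_months", "event", "grade")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of finite, within-sample comparable intensities."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValidationError("need at least 2 genes and 2 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class ClinicalTable:
    """Per-sample survival and phenotype annotations.

    ``data`` carries at least sample_id, time_months (>0), event (0/1) and
    grade; optional columns (age, gender, radiotherapy, ...) are preserved
    verbatim so they can enter Cox models later.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate clinical sample ids: {dupes[:5]}")
        bad_time = df.index[~(pd.to_numeric(df["time_months"], errors="coerce") > 0)]
        if len(bad_time):
            raise ValidationError(
                f"time_months must be > 0; offending rows: {bad_time.tolist()[:10]}"
            )
        ev = pd.to_numeric(df["event"], errors="coerce")
        bad_event = df.index[~ev.isin([0, 1])]
        if len(bad_event):
            raise ValidationError(
                f"event must be 0 or 1; offending rows: {bad_event.tolist()[:10]}"
            )
        df = df.copy()
        df["time_months"] = df["time_months"].astype(float)
        df["event"] = df["event"].astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time_months"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def grade(self) -> pd.Series:
        return self.data["grade"]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(df)

    def samples_with_grade(self, grade: str) -> list[str]:
        return self.data.loc[self.data["grade"] == grade, "sample_id"].tolist()


@dataclass
class CohortBundle:
    """An expression matrix with its matching clinical table."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    name: str = "cohort"

    def __post_init__(self) -> None:
        extra = set(self.clinical.sample_ids) - set(self.expression.sample_ids)
        if extra:
            raise ValidationError(
                f"clinical samples absent from expression matrix: {sorted(extra)[:5]}"
            )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def read_expression(path: str | Path, transpose_hint: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header sample ids).

    Duplicate gene rows are collapsed by their arithmetic mean. Set
    ``transpose_hint`` when the file is samples x genes.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if not transpose_hint and len(set(header)) != len(header):
        dupes = sorted(_duplicates(header))
        raise ValidationError(f"{path}: duplicate sample ids: {dupes[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if transpose_hint:
        df = df.T
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"{path}: duplicate sample ids: {dupes[:5]}")
    def _to_float(s: str) -> float:
        try:
            return float(s)  # correctly-rounded, unlike pd.to_numeric
        except (TypeError, ValueError):
            return float("nan")

    numeric = df.map(_to_float)
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    numeric.index = numeric.index.astype(str)
    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        gene_ids=numeric.index.tolist(),
        sample_ids=numeric.columns.astype(str).tolist(),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the same TSV dialect ``read_expression`` accepts.

    Values are serialized with ``repr`` so that a read/write round trip is
    bit-exact for finite doubles.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_clinical(path: str | Path, days_to_months: bool = False) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time_months, event, grade.

    With ``days_to_months`` the time column is interpreted as days and divided
    by 30.44. Extra columns are kept as optional covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if days_to_months and "time_months" in df.columns:
        df["time_months"] = pd.to_numeric(df["time_months"]) / DAYS_PER_MONTH
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index=False)


def harmonize(cohorts: list[CohortBundle]) -> list[CohortBundle]:
    """Restrict every cohort to the genes common to all, in a shared order.

    Gene order follows the first cohort. Sample sets are untouched. Idempotent.
    """
    if not cohorts:
        raise ValidationError("harmonize requires at least one cohort")
    common = set(cohorts[0].expression.gene_ids)
    for c in cohorts[1:]:
        common &= set(c.expression.gene_ids)
    if not common:
        raise ValidationError("gene intersection across cohorts is empty")
    order = [g for g in cohorts[0].expression.gene_ids if g in common]
    return [
        CohortBundle(c.expression.subset_genes(order), c.clinical, c.name)
        for c in cohorts
    ]
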