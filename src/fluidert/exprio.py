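"""Expression-matrix I/O, FPKM normalisation, log2 transform and library QC.

The common currency of the pipeline is :class:`ExpressionDataset`: a gene ×
sample matrix tagged with a measurement scale (``counts``, ``fpkm`` or
``log2``) plus per-sample metadata (patient, collection day, receptivity
stage, cycle protocol, pregnancy outcome).  Uterine-fluid RNA-seq counts are
normalised to FPKM (fragments per kilobase of transcript per million mapped
fragments) and log2-transformed with a pseudocount before any statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SCALES = ("counts", "fpkm", "log2")
STAGES = ("PR", "RE", "PO")
META_COLUMNS = ("patient_id", "day", "stage", "protocol", "outcome")

#: default QC gates; the study reports one failed validation library but no
#: explicit criterion, so the gate is loose and configurable.
DEFAULT_MIN_GENES_DETECTED = 5000
DEFAULT_MIN_TOTAL = 100_000


class DatasetError(ValueError):
    """Structural problem in an expression dataset or its metadata."""


@dataclass
class ExpressionDataset:
    """Gene × sample expression values with aligned per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    sample_meta
        DataFrame indexed by sample id with columns ``patient_id``, ``day``,
        ``stage`` (PR/RE/PO/unknown), ``protocol`` (natural/HRT) and
        ``outcome`` (pregnant/not_pregnant/unknown).
    scale
        One of ``counts``, ``fpkm``, ``log2``.
    gene_lengths
        Transcript length in bp per gene; required for the counts scale.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DatasetError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            raise DatasetError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise DatasetError("duplicate sample ids in expression matrix")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise DatasetError(f"sample metadata lacks columns: {missing}")
        matrix_samples = set(self.values.columns)
        meta_samples = set(self.sample_meta.index)
        if matrix_samples != meta_samples:
            only_matrix = sorted(matrix_samples - meta_samples)[:5]
            only_meta = sorted(meta_samples - matrix_samples)[:5]
            raise DatasetError(
                "matrix/metadata sample mismatch: "
                f"only in matrix {only_matrix}, only in metadata {only_meta}"
            )
        # keep metadata in matrix column order
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise DatasetError("non-finite expression values")
        if self.scale == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise DatasetError("counts scale requires non-negative integers")
            if self.gene_lengths is None:
                raise DatasetError("counts scale requires gene_lengths")
        if self.scale == "fpkm" and (arr < 0).any():
            raise DatasetError("negative FPKM values")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
                raise DatasetError("gene_lengths must be positive for every gene")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stages(self) -> pd.Series:
        return self.sample_meta["stage"]

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = [g for g in genes if g in self.values.index]
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return ExpressionDataset(self.values.loc[genes], self.sample_meta.copy(),
                                 self.scale, lengths)

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(self.values[samples], self.sample_meta.loc[samples],
                                 self.scale, self.gene_lengths)


@dataclass
class QCReport:
    """Per-library quality-control summary."""

    table: pd.DataFrame  # index sample_id: total, genes_detected, passed, reason
    min_genes_detected: int
    min_total: float

    @property
    def passed(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    @property
    def failed(self) -> list[str]:
        return list(self.table.index[~self.table["passed"]])

    @property
    def pass_rate(self) -> float:
        return float(self.table["passed"].mean())

    def to_json(self, path) -> None:
        payload = {
            "min_genes_detected": self.min_genes_detected,
            "min_total": self.min_total,
            "samples": {
                s: {
                    "total": float(r["total"]),
                    "genes_detected": int(r["genes_detected"]),
                    "passed": bool(r["passed"]),
                    "reason": r["reason"],
                }
                for s, r in self.table.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# -- file I/O -----------------------------------------------------------------

def read_dataset(expr_path, meta_path, scale: str,
                 lengths_path=None) -> ExpressionDataset:
    """Read a tab-separated gene × sample matrix plus sample metadata.

    The matrix has a header of sample ids and gene ids in the first column;
    metadata is a TSV with a ``sample_id`` column plus the standard fields.
    """
    try:
        values = pd.read_csv(expr_path, sep="\t", index_col=0,
                             float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise DatasetError(f"cannot parse expression matrix {expr_path}: {exc}") from exc
    non_numeric = values.columns[~values.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        raise DatasetError(f"non-numeric expression columns: {list(non_numeric)[:5]}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0].astype(float)
    values.index = values.index.astype(str)
    meta.index = meta.index.astype(str)
    return ExpressionDataset(values, meta, scale, lengths)


def write_dataset(dataset: ExpressionDataset, out_dir,
                  expr_name="expr.tsv", meta_name="meta.tsv") -> dict:
    """Write matrix, metadata and (for counts) gene lengths as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expr": out / expr_name, "meta": out / meta_name}
    dataset.values.to_csv(paths["expr"], sep="\t", float_format="%.17g",
                          index_label="gene_id")
    dataset.sample_meta.to_csv(paths["meta"], sep="\t", index_label="sample_id")
    if dataset.gene_lengths is not None:
        paths["lengths"] = out / "lengths.tsv"
        dataset.gene_lengths.rename("length_bp").to_csv(
            paths["lengths"], sep="\t", index_label="gene_id")
    return {k: str(v) for k, v in paths.items()}


# -- transforms ---------------------------------------------------------------

def fpkm(counts: ExpressionDataset) -> ExpressionDataset:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM_gs = count_gs * 1e9 / (librarysize_s * genelength_g)`` with the
    library size taken as the column sum of the count matrix.
    """
    if counts.scale != "counts":
        raise DatasetError(f"fpkm() expects counts scale, got {counts.scale}")
    if counts.gene_lengths is None:
        raise DatasetError("gene lengths required for FPKM")
    lib = counts.values.sum(axis=0).astype(float)
    zero = lib.index[lib <= 0]
    if len(zero):
        raise DatasetError(f"zero library size for samples: {list(zero)[:5]}")
    lengths = counts.gene_lengths.to_numpy(dtype=float)[:, None]
    vals = counts.values.to_numpy(dtype=float) * 1e9 / (lib.to_numpy()[None, :] * lengths)
    out = pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    return ExpressionDataset(out, counts.sample_meta.copy(), "fpkm", counts.gene_lengths)


def log2_transform(dataset: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """``value -> log2(value + pseudocount)``; zero FPKM maps to log2(pseudocount)."""
    if dataset.scale != "fpkm":
        raise DatasetError(f"log2_transform expects fpkm scale, got {dataset.scale}")
    if pseudocount <= 0:
        raise DatasetError("pseudocount must be > 0")
    arr = dataset.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise DatasetError("negative values in FPKM matrix")
    out = pd.DataFrame(np.log2(arr + pseudocount),
                       index=dataset.values.index, columns=dataset.values.columns)
    return ExpressionDataset(out, dataset.sample_meta.copy(), "log2", dataset.gene_lengths)


def qc_filter(dataset: ExpressionDataset,
              min_genes_detected: int = DEFAULT_MIN_GENES_DETECTED,
              min_total: float = DEFAULT_MIN_TOTAL) -> tuple[ExpressionDataset, QCReport]:
    """Drop libraries that detect too few genes or too few total fragments.

    ``min_total`` is only meaningful on the counts scale and is ignored
    (treated as 0) otherwise.
    """
    if min_genes_detected < 0 or min_total < 0:
        raise DatasetError("QC thresholds must be >= 0")
    arr = dataset.values.to_numpy()
    totals = arr.sum(axis=0)
    detected = (arr > 0).sum(axis=0)
    effective_min_total = min_total if dataset.scale == "counts" else 0.0
    rows = []
    for i, s in enumerate(dataset.sample_ids):
        reasons = []
        if detected[i] < min_genes_detected:
            reasons.append("genes_detected")
        if totals[i] < effective_min_total:
            reasons.append("total_fragments")
        rows.append((s, float(totals[i]), int(detected[i]),
                     not reasons, ";".join(reasons)))
    table = pd.DataFrame(rows, columns=["sample_id", "total", "genes_detected",
                                        "passed", "reason"]).set_index("sample_id")
    report = QCReport(table, min_genes_detected, effective_min_total)
    keep = report.passed
    if not keep:
        raise DatasetError("all samples fail QC; empty dataset")
    return dataset.subset_samples(keep), report


def invert_log2(dataset: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Inverse of :func:`log2_transform` (``2**y - pseudocount``)."""
    if dataset.scale != "log2":
        raise DatasetError("invert_log2 expects log2 scale")
    vals = np.power(2.0, dataset.values.to_numpy(dtype=float)) - pseudocount
    vals = np.clip(vals, 0.0, None)
    out = pd.DataFrame(vals, index=dataset.values.index, columns=dataset.values.columns)
    return ExpressionDataset(out, dataset.sample_meta.copy(), "fpkm", dataset.gene_lengths)
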