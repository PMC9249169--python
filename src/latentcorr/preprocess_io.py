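"""Readers/writers, QC filters, size factors and window-based aggregation.

File formats
------------
Expression: dense TSV/CSV (cells as rows, features as columns, first column
``cell_id``) or MatrixMarket ``.mtx`` with sidecar ``<stem>.rows.txt`` (cell
ids) and ``<stem>.cols.txt`` (feature ids).  Epigenome: long-format TSV with
columns ``feature_id, cell_id, met_reads, total_reads``.  Scaling factors:
TSV with ``cell_id, size_factor``.  Genomic annotation: BED (0-based
half-open) for sites/regions and GTF (1-based closed, converted on read)
for gene models.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .model import FeatureData

__all__ = [
    "read_expression",
    "read_epigenome",
    "read_factors",
    "read_dataset",
    "write_dataset",
    "qc_filter",
    "aggregate_windows",
    "estimate_size_factors",
    "read_gene_annotation",
]

EPIGENOME_COLUMNS = ("feature_id", "cell_id", "met_reads", "total_reads")


def read_expression(path: str) -> pd.DataFrame:
    """Expression counts as a cells x features frame indexed by cell id."""
    if path.endswith(".mtx"):
        stem = path[: -len(".mtx")]
        matrix = np.asarray(mmread(path).todense())
        with open(stem + ".rows.txt") as fh:
            cells = [line.strip() for line in fh if line.strip()]
        with open(stem + ".cols.txt") as fh:
            feats = [line.strip() for line in fh if line.strip()]
        if matrix.shape != (len(cells), len(feats)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match sidecar files"
            )
        return pd.DataFrame(matrix, index=cells, columns=feats)
    sep = "," if path.endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    if (frame.to_numpy() < 0).any():
        raise ValueError("expression counts must be non-negative")
    return frame


def write_expression(frame: pd.DataFrame, path: str) -> None:
    if path.endswith(".mtx"):
        stem = path[: -len(".mtx")]
        mmwrite(path, csr_matrix(frame.to_numpy()))
        with open(stem + ".rows.txt", "w") as fh:
            fh.write("\n".join(map(str, frame.index)) + "\n")
        with open(stem + ".cols.txt", "w") as fh:
            fh.write("\n".join(map(str, frame.columns)) + "\n")
    else:
        sep = "," if path.endswith(".csv") else "\t"
        frame.to_csv(path, sep=sep)


def read_epigenome(path: str) -> pd.DataFrame:
    """Long-format epigenome table; validates counts row by row."""
    frame = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "cell_id": str})
    missing = set(EPIGENOME_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"epigenome table lacks columns: {sorted(missing)}")
    bad = frame.index[
        (frame["met_reads"] < 0)
        | (frame["total_reads"] < 0)
        | (frame["met_reads"] > frame["total_reads"])
    ]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"invalid met/total counts in {os.path.basename(path)} "
            f"at line(s) {lines}"
        )
    return frame


def read_factors(path: str) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    if not {"cell_id", "size_factor"} <= set(frame.columns):
        raise ValueError("factors table needs columns cell_id, size_factor")
    s = frame.set_index("cell_id")["size_factor"].astype(float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    return s


def read_dataset(
    expression_path: str,
    epigenome_path: str,
    factors_path: str | None = None,
) -> list[FeatureData]:
    """Inner-join the two layers on (feature, cell) into FeatureData records.

    Cells present in the expression matrix but absent from the epigenome
    table get coverage ``n = 0`` (missing, not evidence of zero).
    """
    expr = read_expression(expression_path)
    epi = read_epigenome(epigenome_path)
    cells = expr.index.to_numpy()
    epi_cells = set(epi["cell_id"])
    if epi_cells and not epi_cells & set(cells):
        raise ValueError("expression and epigenome tables share no cells")
    if factors_path is not None:
        factors = read_factors(factors_path)
        missing = set(cells) - set(factors.index)
        if missing:
            raise ValueError(f"size factors missing for cells: {sorted(missing)[:5]}")
        s = factors.loc[cells].to_numpy()
    else:
        s = estimate_size_factors(expr.to_numpy())

    cell_pos = {cell: k for k, cell in enumerate(cells)}
    dataset = []
    grouped = dict(tuple(epi.groupby("feature_id", sort=False)))
    for feature_id in expr.columns:
        y1 = expr[feature_id].to_numpy().astype(np.int64)
        y2 = np.zeros(len(cells), dtype=np.int64)
        n = np.zeros(len(cells), dtype=np.int64)
        block = grouped.get(feature_id)
        if block is not None:
            for cell, met, tot in zip(
                block["cell_id"], block["met_reads"], block["total_reads"]
            ):
                k = cell_pos.get(cell)
                if k is not None:
                    y2[k] += int(met)
                    n[k] += int(tot)
        dataset.append(FeatureData(str(feature_id), y1, y2, n, s))
    return dataset


def write_dataset(
    dataset: Sequence[FeatureData],
    expression_path: str,
    epigenome_path: str,
    factors_path: str | None = None,
) -> None:
    """Inverse of :func:`read_dataset` (round-trips exactly)."""
    cells = [f"cell_{i:04d}" for i in range(dataset[0].n_cells)]
    expr = pd.DataFrame(
        {d.feature_id: d.y1 for d in dataset}, index=pd.Index(cells, name="cell_id")
    )
    write_expression(expr, expression_path)
    rows = []
    for d in dataset:
        for i, cell in enumerate(cells):
            if d.n[i] > 0:
                rows.append((d.feature_id, cell, int(d.y2[i]), int(d.n[i])))
    pd.DataFrame(rows, columns=list(EPIGENOME_COLUMNS)).to_csv(
        epigenome_path, sep="\t", index=False
    )
    if factors_path is not None:
        pd.DataFrame(
            {"cell_id": cells, "size_factor": dataset[0].s}
        ).to_csv(factors_path, sep="\t", index=False)


def qc_filter(
    dataset: Sequence[FeatureData], max_zero_frac: float = 0.80
) -> tuple[list[FeatureData], pd.DataFrame]:
    """Drop zero-variance features and features with too many expression zeros.

    Returns the surviving features and a drop log.  Idempotent: applying
    the filter twice changes nothing.
    """
    kept: list[FeatureData] = []
    log_rows = []
    for data in dataset:
        reasons = []
        if np.ptp(data.y1) == 0:
            reasons.append("zero expression variance")
        rates = np.where(data.n > 0, data.y2 / np.maximum(data.n, 1), np.nan)
        observed = rates[~np.isnan(rates)]
        if observed.size == 0 or np.ptp(observed) == 0:
            reasons.append("zero epigenome variance")
        zero_frac = float(np.mean(data.y1 == 0))
        if zero_frac > max_zero_frac:
            reasons.append(f"expression zeros {zero_frac:.0%} > {max_zero_frac:.0%}")
        if reasons:
            log_rows.append(
                {"feature_id": data.feature_id, "reason": "; ".join(reasons)}
            )
        else:
            kept.append(data)
    if not kept:
        raise ValueError("QC filter removed every feature")
    return kept, pd.DataFrame(log_rows, columns=["feature_id", "reason"])


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 0-based position of the transcription start site
    strand: str


def read_gene_annotation(path: str) -> list[GeneAnnotation]:
    """Gene records from a GTF file (``gene`` features only).

    GTF is 1-based closed; the TSS is converted to a 0-based coordinate:
    ``start - 1`` on the + strand and ``end - 1`` on the - strand.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line {lineno}")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                raise ValueError(
                    f"missing strand for gene at GTF line {lineno}; "
                    "strand is required for TSS anchoring"
                )
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"no gene_id attribute at GTF line {lineno}")
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
    return genes


def read_site_table(path: str) -> pd.DataFrame:
    """Site-level methylation calls: BED-like TSV.

    Columns: chrom, pos (0-based), cell_id, met_reads, total_reads.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell_id": str})
    required = {"chrom", "pos", "cell_id", "met_reads", "total_reads"}
    if not required <= set(frame.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    return frame


def aggregate_windows(
    site_table: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    window_bp: int,
    anchor: str = "promoter",
) -> pd.DataFrame:
    """Sum site-level counts within +/- ``window_bp`` of each gene's TSS.

    The window is the half-open interval ``[tss - window_bp, tss + window_bp
    + 1)`` in 0-based coordinates, so a site exactly at the TSS is included
    for any positive window.  Emits the long epigenome format consumed by
    :func:`read_dataset`.
    """
    if anchor not in ("promoter", "gene_body"):
        raise ValueError("anchor must be 'promoter' or 'gene_body'")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    by_chrom = {
        chrom: block.sort_values("pos")
        for chrom, block in site_table.groupby("chrom")
    }
    for gene in annotation:
        block = by_chrom.get(gene.chrom)
        if block is None:
            continue
        lo = gene.tss - window_bp
        hi = gene.tss + window_bp + 1  # half-open upper bound
        pos = block["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi])
        hits = block.iloc[i0:i1]
        if hits.empty:
            continue
        summed = hits.groupby("cell_id")[["met_reads", "total_reads"]].sum()
        for cell_id, row in summed.iterrows():
            rows.append(
                (gene.gene_id, cell_id, int(row["met_reads"]), int(row["total_reads"]))
            )
    return pd.DataFrame(rows, columns=list(EPIGENOME_COLUMNS))


def estimate_size_factors(
    expression_matrix: np.ndarray, method: str = "libsize"
) -> np.ndarray:
    """Per-cell size factors normalized to mean 1.

    ``libsize`` divides each cell's total counts by the grand mean total
    (zero-count cells are floored with a warning); ``median_ratio`` is the
    DESeq-style median-of-ratios estimator over features detected in all
    cells.
    """
    counts = np.asarray(expression_matrix, dtype=np.float64)
    if counts.ndim != 2 or counts.size == 0:
        raise ValueError("expected a nonempty cells x features matrix")
    if method == "libsize":
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            import warnings

            warnings.warn(
                "cells with zero total counts: size factor floored", stacklevel=2
            )
            totals = np.maximum(totals, 1e-8)
        factors = totals / totals.mean()
    elif method == "median_ratio":
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError("median_ratio undefined for zero-count cells")
        detected = np.all(counts > 0, axis=0)
        if not detected.any():
            raise ValueError("median_ratio needs features detected in all cells")
        log_geo = np.mean(np.log(counts[:, detected]), axis=0)
        factors = np.exp(
            np.median(np.log(counts[:, detected]) - log_geo, axis=1)
        )
    else:
        raise ValueError("method must be 'libsize' or 'median_ratio'")
    return factors / factors.mean()
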