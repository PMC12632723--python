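"""Parsing and normalization of brain expression matrices.

Three data families are supported, all reduced to one annotated gene ×
sample container:

* developmental bulk RNA-seq (RPKM; donor, age/stage, region per sample),
  shipped as an expression matrix plus separate row (gene) and column
  (sample) metadata files;
* adult microarray (probe × sample intensities with a probe→gene map,
  collapsed per gene by the maximum over probes);
* single-cell profiles (TPM or UMI counts with cell-type labels, averaged
  within type; UMI counts pass through CPM and log2(x+1)).

Developmental ages are binned into an ordered stage vocabulary through a
user-overridable age→stage table; the packaged default covers eleven
windows from early prenatal to middle adulthood.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTensor",
    "CellTypeProfile",
    "DEFAULT_STAGES",
    "stage_from_age",
    "load_bulk",
    "load_single_table",
    "collapse_probes_max",
    "mean_by_group",
    "counts_to_log_cpm",
]

#: Ordered developmental stage vocabulary (11 windows). Boundaries are in
#: post-conception days; birth is taken at 40 pcw = 280 days. This default
#: follows the standard developmental windows used for BrainSpan-style data
#: and is configuration, not a fixed constant: pass a custom table wherever
#: a ``stage_table`` argument is accepted.
DEFAULT_STAGES: list[tuple[str, float]] = [
    # (stage label, inclusive upper bound in post-conception days)
    ("Early prenatal", 12 * 7),          # 8-12 pcw
    ("Early mid-prenatal", 17 * 7),      # 13-17 pcw
    ("Late mid-prenatal", 25 * 7),       # 18-25 pcw
    ("Late prenatal", 280),              # 26 pcw - birth
    ("Early infancy", 280 + 182),        # birth - 6 months
    ("Late infancy", 280 + 365),         # 6-12 months
    ("Early childhood", 280 + 6 * 365),  # 1-6 years
    ("Late childhood", 280 + 12 * 365),  # 6-12 years
    ("Adolescence", 280 + 20 * 365),     # 12-20 years
    ("Young Adulthood", 280 + 40 * 365),  # 20-40 years
    ("Middle Adulthood", float("inf")),  # 40+ years
]

_AGE_RE = re.compile(r"^\s*([\d.]+)\s*(pcw|wks?|mos?|yrs?)\s*$", re.IGNORECASE)


def _age_to_days(age_label: str) -> float:
    """Post-conception days from a BrainSpan-style age string.

    Accepts ``"8 pcw"``, ``"4 mos"``, ``"3 yrs"``; postnatal units are
    offset by 280 days of gestation.
    """
    m = _AGE_RE.match(age_label)
    if not m:
        raise ValueError(f"cannot parse age label {age_label!r}")
    value, unit = float(m.group(1)), m.group(2).lower()
    if unit.startswith("pcw") or unit.startswith("wk"):
        return value * 7
    if unit.startswith("mo"):
        return 280 + value * 30.44
    return 280 + value * 365


def stage_from_age(
    age_label: str, stage_table: Sequence[tuple[str, float]] | None = None
) -> str:
    """Assign an ordinal developmental stage to an age label."""
    table = list(stage_table or DEFAULT_STAGES)
    days = _age_to_days(age_label)
    for label, upper in table:
        if days <= upper:
            return label
    return table[-1][0]


@dataclass
class ExpressionTensor:
    """Gene × sample expression matrix with per-sample annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Genes (rows, unique symbols) × samples (columns). Finite; non-
        negative unless ``unit`` is a log scale.
    samples : pandas.DataFrame
        One row per sample (index matches ``values.columns``); typical
        columns: ``donor_id``, ``age``, ``stage``, ``region``,
        ``hemisphere`` for bulk data, or ``cell_type`` for single cells.
    unit : str
        One of ``RPKM, TPM, CPM, LOG2CPM, COUNTS, INTENSITY``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "RPKM"
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample annotation index does not match matrix columns")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.unit not in ("LOG2CPM",) and (vals < 0).any():
            raise ValueError(f"negative values in a {self.unit} matrix")
        if not self.stage_order and "stage" in self.samples.columns:
            default = [s for s, _ in DEFAULT_STAGES]
            present = set(self.samples["stage"])
            self.stage_order = [s for s in default if s in present] or sorted(present)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def universe(self) -> set[str]:
        """Measured gene symbols, for gene-set coverage checks."""
        return set(self.values.index)


@dataclass
class CellTypeProfile:
    """Gene × cell-type matrix of within-type mean expression."""

    values: pd.DataFrame  # genes x cell types
    unit: str = "LOG2CPM"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in cell-type profile")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate cell-type labels")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def _collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene symbol (duplicate-transcript dedup)."""
    if not values.index.duplicated().any():
        return values
    n_before = values.shape[0]
    out = values.groupby(level=0, sort=False).mean()
    logger.info("collapsed %d duplicate gene rows by mean", n_before - out.shape[0])
    return out


def load_bulk(
    matrix_path: str | Path,
    row_meta_path: str | Path,
    col_meta_path: str | Path,
    unit: str = "RPKM",
    stage_table: Sequence[tuple[str, float]] | None = None,
    region_vocabulary: Sequence[str] | None = None,
) -> ExpressionTensor:
    """Load a developmental bulk matrix from the three-file dialect.

    ``matrix_path`` is a header-less CSV of values; ``row_meta_path`` a CSV
    with a ``gene_symbol`` column; ``col_meta_path`` a CSV with at least
    ``donor_id``, ``age`` (or ``stage``) and ``region`` columns, one row per
    matrix column. Rows with duplicated gene symbols are collapsed by the
    arithmetic mean of their values. Stages are assigned from ages via the
    (overridable) age→stage table when not given explicitly.
    """
    values = pd.read_csv(matrix_path, header=None)
    rows = pd.read_csv(row_meta_path)
    cols = pd.read_csv(col_meta_path)
    # tolerate a leading row-number column, as in BrainSpan downloads
    if values.shape[1] == len(cols) + 1:
        values = values.iloc[:, 1:]
    if values.shape[0] != len(rows):
        raise ValueError(
            f"matrix has {values.shape[0]} rows but row metadata has {len(rows)}"
        )
    if values.shape[1] != len(cols):
        raise ValueError(
            f"matrix has {values.shape[1]} columns but column metadata has {len(cols)}"
        )
    if "gene_symbol" not in rows.columns:
        raise ValueError("row metadata needs a 'gene_symbol' column")

    sample_ids = (
        cols["sample_id"].astype(str).tolist()
        if "sample_id" in cols.columns
        else [f"S{i + 1}" for i in range(len(cols))]
    )
    values.index = rows["gene_symbol"].astype(str).str.strip().str.upper()
    values.index.name = "gene"
    values.columns = sample_ids
    values = _collapse_duplicate_genes(values)

    samples = cols.copy()
    samples.index = pd.Index(sample_ids, name="sample_id")
    if "stage" not in samples.columns:
        if "age" not in samples.columns:
            raise ValueError("column metadata needs an 'age' or 'stage' column")
        samples["stage"] = [stage_from_age(a, stage_table) for a in samples["age"]]
    if "region" not in samples.columns:
        raise ValueError("column metadata needs a 'region' column")
    if region_vocabulary is not None:
        unknown = sorted(set(samples["region"]) - set(region_vocabulary))
        if unknown:
            raise ValueError(f"unknown region codes: {unknown}")
    return ExpressionTensor(values=values, samples=samples, unit=unit)


def load_single_table(
    path: str | Path, sample_meta: pd.DataFrame | None = None, unit: str = "RPKM"
) -> ExpressionTensor:
    """Load a simple single-file TSV (gene symbols in the first column)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.strip().str.upper()
    values = _collapse_duplicate_genes(values)
    if sample_meta is None:
        sample_meta = pd.DataFrame(index=values.columns)
    return ExpressionTensor(values=values, samples=sample_meta, unit=unit)


def collapse_probes_max(
    probe_matrix: pd.DataFrame,
    probe_to_gene: pd.Series | dict[str, str],
    samples: pd.DataFrame | None = None,
    unit: str = "INTENSITY",
) -> ExpressionTensor:
    """Collapse a probe × sample matrix to gene level by the per-cell max.

    Microarray platforms carry several probes per gene; for each gene and
    sample the maximum intensity across its probes is kept. Probes absent
    from the map are dropped (count logged).
    """
    mapping = pd.Series(probe_to_gene, dtype=str)
    if mapping.empty:
        raise ValueError("probe-to-gene mapping is empty")
    mapping = mapping.str.strip().str.upper()
    mapped = probe_matrix.index.intersection(mapping.index)
    dropped = probe_matrix.shape[0] - len(mapped)
    if dropped:
        logger.info("dropping %d unmapped probes", dropped)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the mapping")
    sub = probe_matrix.loc[mapped]
    genes = mapping.loc[mapped]
    values = sub.groupby(genes.to_numpy()).max()
    values.index.name = "gene"
    if samples is None:
        samples = pd.DataFrame(index=values.columns)
    return ExpressionTensor(values=values, samples=samples, unit=unit)


def mean_by_group(t: ExpressionTensor, group_key: str) -> ExpressionTensor:
    """Average sample columns within each level of an annotation field.

    One output column per group (e.g. region, or cell type), the arithmetic
    mean of its member columns. Group order follows first appearance.
    """
    if group_key not in t.samples.columns:
        raise ValueError(f"annotation field {group_key!r} missing from sample table")
    groups = t.samples[group_key].astype(str)
    order = list(dict.fromkeys(groups))
    means = {g: t.values.loc[:, groups[groups == g].index].mean(axis=1) for g in order}
    values = pd.DataFrame(means, index=t.values.index)[order]
    samples = pd.DataFrame({group_key: order}, index=pd.Index(order, name=group_key))
    return ExpressionTensor(
        values=values, samples=samples, unit=t.unit, stage_order=list(t.stage_order)
    )


def to_celltype_profile(t: ExpressionTensor, cell_type_key: str = "cell_type") -> CellTypeProfile:
    """Within-type mean profile from single-cell columns."""
    m = mean_by_group(t, cell_type_key)
    return CellTypeProfile(values=m.values, unit=t.unit)


def counts_to_log_cpm(t: ExpressionTensor) -> ExpressionTensor:
    """Counts → counts-per-million → ``log2(x + 1)``.

    ``v_gs = log2(1 + 1e6 * count_gs / colsum_s)``; the log transform tames
    the right skew of count data before rank/mean summaries.
    """
    if t.unit not in ("COUNTS", "UMI"):
        raise ValueError(f"expected a counts matrix, got unit {t.unit!r}")
    colsums = t.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero total counts in sample(s): {list(zero.index)[:5]}")
    cpm = t.values * (1e6 / colsums)
    values = np.log2(cpm + 1.0)
    return ExpressionTensor(
        values=values, samples=t.samples.copy(), unit="LOG2CPM",
        stage_order=list(t.stage_order),
    )
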