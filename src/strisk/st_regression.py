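"""Spatiotemporal dummy-variable regression of module eigengenes.

Each module eigengene is modelled by ordinary least squares on treatment-
coded region and stage indicators (no interactions):

    ME_s = intercept + beta_region(s) + beta_stage(s) + error

with one reference region and one reference stage absorbed into the
intercept (for the full human-brain configuration: Thalamus and Young
Adulthood, giving 11 spatial + 11 temporal dummies from 12 levels each).
The additive predicted level on the full region × stage grid locates each
module's spatiotemporal expression peak, and modules are retained for
downstream annotation when at least one coefficient exceeds a threshold
on the raw (unstandardized) scale — meaningful because eigengenes share a
fixed unit-norm scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["DummyDesign", "STFit", "build_design", "fit_st_model", "predict_grid"]


@dataclass
class DummyDesign:
    """Treatment-coded design matrix over region and stage levels."""

    matrix: pd.DataFrame  # samples x (const + region dummies + stage dummies)
    region_levels: list[str]  # full ordered vocabulary, reference first excluded nowhere
    stage_levels: list[str]
    region_ref: str
    stage_ref: str

    @property
    def region_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if c.startswith("region[")]

    @property
    def stage_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if c.startswith("stage[")]


def build_design(
    samples: pd.DataFrame,
    region_ref: str,
    stage_ref: str,
    region_levels: list[str] | None = None,
    stage_levels: list[str] | None = None,
) -> DummyDesign:
    """Treatment-coded dummies for region and stage with explicit references.

    Samples whose region or stage fall outside the declared vocabularies
    are dropped (count logged). Column order follows the declared level
    order; reference levels contribute no column, so a sample at
    ``(region_ref, stage_ref)`` has an all-zero dummy row plus the
    intercept.
    """
    region_levels = list(region_levels or dict.fromkeys(samples["region"]))
    stage_levels = list(stage_levels or dict.fromkeys(samples["stage"]))
    if region_ref not in region_levels:
        raise ValueError(f"region reference {region_ref!r} not among levels")
    if stage_ref not in stage_levels:
        raise ValueError(f"stage reference {stage_ref!r} not among levels")

    in_vocab = samples["region"].isin(region_levels) & samples["stage"].isin(stage_levels)
    n_dropped = int((~in_vocab).sum())
    if n_dropped:
        logger.info("dropping %d sample(s) outside the region/stage vocabularies", n_dropped)
    sub = samples.loc[in_vocab]

    cols: dict[str, np.ndarray] = {"const": np.ones(len(sub))}
    for lvl in region_levels:
        if lvl == region_ref:
            continue
        cols[f"region[{lvl}]"] = (sub["region"] == lvl).to_numpy(float)
    for lvl in stage_levels:
        if lvl == stage_ref:
            continue
        cols[f"stage[{lvl}]"] = (sub["stage"] == lvl).to_numpy(float)
    matrix = pd.DataFrame(cols, index=sub.index)
    return DummyDesign(matrix=matrix, region_levels=region_levels,
                       stage_levels=stage_levels, region_ref=region_ref,
                       stage_ref=stage_ref)


@dataclass
class STFit:
    """OLS fit of one eigengene on the spatiotemporal dummies."""

    module: str
    intercept: float
    region_beta: pd.Series  # indexed by region level; reference = 0
    stage_beta: pd.Series
    pvalues: pd.Series  # per design column, two-sided t
    resid: np.ndarray
    retained: bool
    threshold: float

    @property
    def max_beta(self) -> float:
        return float(max(self.region_beta.max(), self.stage_beta.max()))


def fit_st_model(
    eigengene: pd.Series | np.ndarray,
    design: DummyDesign,
    module: str = "",
    retain_threshold: float = 0.05,
    standardized: bool = False,
) -> STFit:
    """OLS of an eigengene on the dummy design; retention by effect size.

    ``retained`` is True when the largest coefficient (region or stage)
    exceeds ``retain_threshold``; p-values are reported but play no role
    in retention. ``standardized=True`` scales the response to unit
    variance first, switching the threshold to standardized betas.
    """
    y = np.asarray(
        eigengene.loc[design.matrix.index] if isinstance(eigengene, pd.Series) else eigengene,
        dtype=float,
    )
    X = design.matrix
    if len(y) != len(X):
        raise ValueError("eigengene length does not match design rows")
    if len(y) <= X.shape[1]:
        raise ValueError("need more samples than design columns")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns for the error message
        bad = []
        cols = X.columns.tolist()
        for i in range(1, len(cols) + 1):
            if np.linalg.matrix_rank(X.iloc[:, :i].to_numpy()) < i:
                bad.append(cols[i - 1])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    if standardized:
        sd = y.std(ddof=1)
        if sd > 0:
            y = (y - y.mean()) / sd
    res = sm.OLS(y, X).fit()
    params = pd.Series(res.params, index=X.columns)

    region_beta = pd.Series(0.0, index=design.region_levels)
    stage_beta = pd.Series(0.0, index=design.stage_levels)
    for lvl in design.region_levels:
        col = f"region[{lvl}]"
        if col in params.index:
            region_beta[lvl] = params[col]
    for lvl in design.stage_levels:
        col = f"stage[{lvl}]"
        if col in params.index:
            stage_beta[lvl] = params[col]

    max_beta = float(max(region_beta.max(), stage_beta.max()))
    return STFit(
        module=module,
        intercept=float(params["const"]),
        region_beta=region_beta,
        stage_beta=stage_beta,
        pvalues=pd.Series(res.pvalues, index=X.columns),
        resid=np.asarray(res.resid),
        retained=max_beta > retain_threshold,
        threshold=retain_threshold,
    )


def predict_grid(fit: STFit) -> pd.DataFrame:
    """Additive predicted eigengene level on the full region × stage grid.

    ``level(r, s) = intercept + beta_r + beta_s`` with reference betas 0;
    the reference cell equals the intercept exactly.
    """
    grid = pd.DataFrame(
        np.add.outer(fit.region_beta.to_numpy(), fit.stage_beta.to_numpy())
        + fit.intercept,
        index=fit.region_beta.index,
        columns=fit.stage_beta.index,
    )
    grid.index.name = "region"
    grid.columns.name = "stage"
    return grid


def grid_argmax(grid: pd.DataFrame) -> tuple[str, str]:
    """Hot-spot cell of a predicted grid; ties break by region then stage order."""
    arr = grid.to_numpy()
    flat = np.argmax(arr)  # first occurrence in row-major order = declared order
    i, j = np.unravel_index(flat, arr.shape)
    return str(grid.index[i]), str(grid.columns[j])
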