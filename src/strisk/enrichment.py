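"""Per-sample rank-biserial enrichment of risk gene sets.

The central statistic: within each transcriptome sample, expression values
are ranked and the risk gene set is compared with the remaining genes by a
Mann-Whitney U test. The rank-biserial correlation

    r = 2U / (n1 * n2) - 1

is the effect size, equal to P(risk gene outranks non-risk gene) minus the
reverse probability, ranging from -1 (deprivation) to +1 (enrichment).
One-sided p-values (alternative: risk group ranks higher) come from the
normal approximation with tie correction and a 0.5 continuity correction;
Benjamini-Hochberg FDR is applied within each gene set across its samples,
and r values are Z-scored per set for cross-trait comparison.

Temporal dynamics are summarized per developmental stage (mean r across
the stage's samples) and smoothed with an unpadded centered moving average
of window 3, so 11 stages yield 9 smoothed points. "Hot-spots" are the
(region, stage) combinations with the highest average r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionTensor
from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentCell",
    "EnrichmentMatrix",
    "StageTrajectory",
    "HotSpot",
    "rank_biserial",
    "enrich_matrix",
    "stage_trajectory",
    "moving_average",
    "top_hotspots",
]


@dataclass(frozen=True)
class EnrichmentCell:
    """One gene-set × sample enrichment result."""

    set_name: str
    sample_id: str
    r: float
    U: float
    n1: int
    n2: int
    p: float
    q: float = np.nan


def _rank_stats(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Ascending average ranks and the tie term sum(t^3 - t)."""
    ranks = stats.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, tie_term


def _one_sided_p(U: float, n1: int, n2: int, n: int, tie_term: float) -> float:
    """P(U' >= U) under the null, normal approximation.

    Tie-corrected variance and a 0.5 continuity correction; degenerate
    samples (all values identical) give p = 0.5.
    """
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.5
    z = (U - mu - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def rank_biserial(
    sample_values: np.ndarray,
    risk: np.ndarray,
    set_name: str = "",
    sample_id: str = "",
) -> EnrichmentCell | None:
    """Rank-biserial enrichment of the masked genes in one sample.

    Parameters
    ----------
    sample_values : array of shape (n_genes,)
        Expression values of all measured genes in one sample.
    risk : boolean array of shape (n_genes,)
        Membership mask of the risk group.

    Returns
    -------
    EnrichmentCell, or None when the risk group is empty (missing cell).
    """
    sample_values = np.asarray(sample_values, dtype=float)
    risk = np.asarray(risk, dtype=bool)
    n1 = int(risk.sum())
    n2 = int((~risk).sum())
    if n1 == 0:
        logger.warning("empty risk group for set %s in sample %s", set_name, sample_id)
        return None
    if n2 == 0:
        raise ValueError("non-risk group is empty")
    ranks, tie_term = _rank_stats(sample_values)
    n = n1 + n2
    R1 = float(ranks[risk].sum())
    U = R1 - n1 * (n1 + 1) / 2.0
    r = 2.0 * U / (n1 * n2) - 1.0
    p = _one_sided_p(U, n1, n2, n, tie_term)
    return EnrichmentCell(set_name=set_name, sample_id=sample_id, r=r, U=U,
                          n1=n1, n2=n2, p=p, q=np.nan)


@dataclass
class EnrichmentMatrix:
    """Gene-set × sample grid of enrichment results.

    ``table`` is the long-format result (one row per set × sample with r,
    U, n1, n2, p, q); ``r``/``z`` are wide set × sample matrices; ``samples``
    carries the sample annotations through to trajectory and hot-spot
    summaries.
    """

    table: pd.DataFrame
    r: pd.DataFrame
    z: pd.DataFrame
    samples: pd.DataFrame
    stage_order: list[str] = field(default_factory=list)

    @property
    def set_names(self) -> list[str]:
        return list(self.r.index)


def _zscore_rows(r: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-score with sample SD (ddof=1); zero-SD rows map to 0."""
    mean = r.mean(axis=1)
    sd = r.std(axis=1, ddof=1)
    z = r.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def enrich_matrix(
    t: ExpressionTensor,
    coll: GeneSetCollection,
    fdr_scope: str = "per_set",
) -> EnrichmentMatrix:
    """Score every gene set in every sample of an expression tensor.

    Risk genes absent from the tensor are excluded from the risk group
    (logged once per set). FDR correction is Benjamini-Hochberg within each
    set across its samples (``fdr_scope="per_set"``) or pooled over the
    whole grid (``"global"``). Z-scores are always per set across samples.
    """
    if fdr_scope not in ("per_set", "global"):
        raise ValueError("fdr_scope must be 'per_set' or 'global'")
    genes = pd.Index(t.values.index)
    X = t.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape

    # rank each sample once; all sets share the rank vectors
    ranks = np.empty_like(X)
    tie_terms = np.empty(n_samples)
    for j in range(n_samples):
        ranks[:, j], tie_terms[j] = _rank_stats(X[:, j])

    rows = []
    measured_any = False
    for gs in coll:
        mask = np.asarray(genes.isin(gs.genes))
        n1 = int(mask.sum())
        n2 = n_genes - n1
        if n1 == 0:
            logger.warning("gene set %s: no measured genes; row of missing cells", gs.name)
            for j, sid in enumerate(t.values.columns):
                rows.append((gs.name, sid, np.nan, np.nan, 0, n_genes, np.nan))
            continue
        if n1 < len(gs.genes):
            logger.info("gene set %s: %d/%d genes not measured, excluded",
                        gs.name, len(gs.genes) - n1, len(gs.genes))
        measured_any = True
        R1 = ranks[mask].sum(axis=0)
        U = R1 - n1 * (n1 + 1) / 2.0
        r = 2.0 * U / (n1 * n2) - 1.0
        p = np.array([_one_sided_p(U[j], n1, n2, n_genes, tie_terms[j])
                      for j in range(n_samples)])
        for j, sid in enumerate(t.values.columns):
            rows.append((gs.name, sid, r[j], U[j], n1, n2, p[j]))
    if not measured_any:
        raise ValueError("no gene set has any measured gene")

    table = pd.DataFrame(rows, columns=["set", "sample", "r", "U", "n1", "n2", "p"])

    def _bh(p: pd.Series) -> pd.Series:
        out = pd.Series(np.nan, index=p.index)
        ok = p.notna()
        if ok.any():
            out[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
        return out

    if fdr_scope == "per_set":
        table["q"] = table.groupby("set", sort=False)["p"].transform(_bh)
    else:
        table["q"] = _bh(table["p"])

    r_wide = table.pivot(index="set", columns="sample", values="r")
    r_wide = r_wide.loc[coll.names, t.values.columns]
    z = _zscore_rows(r_wide)
    return EnrichmentMatrix(table=table, r=r_wide, z=z, samples=t.samples.copy(),
                            stage_order=list(t.stage_order))


@dataclass
class StageTrajectory:
    """Per-stage mean enrichment and its window-3 moving average."""

    set_name: str
    stages: list[str]
    stage_means: np.ndarray
    smoothed: np.ndarray  # length n_stages - 2; NaN where a window is incomplete

    def as_frame(self) -> pd.DataFrame:
        sm = np.full(len(self.stages), np.nan)
        sm[1:-1] = self.smoothed
        return pd.DataFrame(
            {"set": self.set_name, "stage": self.stages,
             "mean_r": self.stage_means, "smoothed_r": sm}
        )


def moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Unpadded centered moving average; output length ``len(x) - window + 1``.

    Windows containing a missing (NaN) value yield NaN rather than
    shrinking the window.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < window:
        raise ValueError(f"need at least {window} points, got {len(x)}")
    return np.convolve(x, np.ones(window) / window, mode="valid")


def stage_trajectory(m: EnrichmentMatrix, set_name: str, window: int = 3) -> StageTrajectory:
    """Developmental trajectory of a gene set's enrichment.

    r values are averaged over all samples within each ordered stage, then
    smoothed with the centered window-3 moving average (11 stages → 9
    points). Stages with no samples give missing means, which propagate to
    every window containing them.
    """
    if set_name not in m.r.index:
        raise KeyError(set_name)
    stages = m.stage_order or sorted(set(m.samples["stage"]))
    if len(stages) < window:
        raise ValueError(f"need >= {window} stages, got {len(stages)}")
    r = m.r.loc[set_name]
    stage_of = m.samples["stage"]
    means = np.array([
        r[stage_of[stage_of == s].index].mean() if (stage_of == s).any() else np.nan
        for s in stages
    ])
    if np.isnan(means).any():
        logger.warning("set %s: %d stage(s) without samples; affected windows are NaN",
                       set_name, int(np.isnan(means).sum()))
    return StageTrajectory(set_name=set_name, stages=list(stages),
                           stage_means=means, smoothed=moving_average(means, window))


@dataclass(frozen=True)
class HotSpot:
    """A (region, stage) combination ranked by average enrichment."""

    set_name: str
    region: str
    stage: str
    mean_r: float
    n_samples: int
    rank: int


def top_hotspots(m: EnrichmentMatrix, set_name: str, k: int = 3) -> list[HotSpot]:
    """Top-k (region, stage) cells by mean enrichment r for one gene set.

    Ties are broken deterministically: more samples first, then
    lexicographic region, then earlier stage.
    """
    if set_name not in m.r.index:
        raise KeyError(set_name)
    r = m.r.loc[set_name]
    ann = m.samples
    stages = m.stage_order or sorted(set(ann["stage"]))
    stage_rank = {s: i for i, s in enumerate(stages)}
    df = pd.DataFrame({"r": r, "region": ann["region"], "stage": ann["stage"]})
    agg = (
        df.groupby(["region", "stage"], sort=False)["r"]
        .agg(mean_r="mean", n="count")
        .reset_index()
    )
    agg = agg[agg["n"] >= 1]
    if len(agg) < k:
        logger.warning("set %s: only %d populated (region, stage) cells (< k=%d)",
                       set_name, len(agg), k)
    agg["stage_idx"] = agg["stage"].map(stage_rank)
    agg = agg.sort_values(
        by=["mean_r", "n", "region", "stage_idx"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).head(k)
    return [
        HotSpot(set_name=set_name, region=row.region, stage=row.stage,
                mean_r=float(row.mean_r), n_samples=int(row.n), rank=i + 1)
        for i, row in enumerate(agg.itertuples(index=False))
    ]
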