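"""Signed weighted co-expression network construction and module detection.

The network stage: genes are filtered for minimal total expression and
outlier samples removed; pairwise Pearson correlations are soft-thresholded
into a signed adjacency

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta

with beta chosen for approximate scale-free topology; the topological
overlap measure (TOM) converts shared-neighborhood structure into a
dissimilarity (1 - TOM); average-linkage clustering of that dissimilarity
is pruned adaptively into modules of at least ``min_module_size`` genes;
and each module is summarized by its
eigengene, the first principal component of its standardized expression,
sign-oriented to correlate positively with the module's mean profile.

The whole network is computed in a single block, guarded by a gene-count
cap; the classical implementation approximates large problems block-wise,
which can change module boundaries — runs record this deviation in their
manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .expression_io import ExpressionTensor

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "SoftPowerFit",
    "ModuleSet",
    "filter_and_qc",
    "signed_adjacency",
    "pick_soft_power",
    "tom_dissimilarity",
    "detect_modules",
    "compute_eigengenes",
]


@dataclass
class NetworkConfig:
    """Parameters of the co-expression network stage.

    Defaults follow the standard choices for bulk developmental brain
    RNA-seq: genes with total expression below 10 over all samples are
    removed; the soft power is 7 (or chosen to reach scale-free fit
    R² > 0.85 when ``soft_power="auto"``); modules must contain at least
    40 genes. ``sample_cut_height`` (dendrogram height for outlier-sample
    exclusion) has no universal scale — it depends on the expression units
    — so it defaults to off.
    """

    min_total_expression: float = 10.0
    sample_cut_height: float | None = None
    soft_power: int | str = 7
    scale_free_r2_target: float = 0.85
    min_module_size: int = 40
    merge_height: float | None = None  # reserved; eigengene merging not performed
    cut_gap: float = 0.1  # relative height drop required to split a branch
    max_genes: int = 20_000  # single-block guard

    def __post_init__(self) -> None:
        if self.soft_power != "auto" and int(self.soft_power) < 1:
            raise ValueError("soft_power must be >= 1 or 'auto'")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def filter_and_qc(t: ExpressionTensor, cfg: NetworkConfig) -> ExpressionTensor:
    """Drop low-expression genes and (optionally) outlier samples.

    Genes whose total expression over all samples is below
    ``cfg.min_total_expression`` are removed. When ``sample_cut_height``
    is set, samples are clustered by average linkage on inter-sample
    Euclidean distances and branches above the cut are excluded; the
    largest cluster under the cut is kept.
    """
    keep = t.values.sum(axis=1) >= cfg.min_total_expression
    if not keep.any():
        raise ValueError("all genes removed by the expression filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filtered %d low-expression genes (threshold %g)",
                    dropped, cfg.min_total_expression)
    values = t.values.loc[keep]

    samples = t.samples
    if cfg.sample_cut_height is not None and values.shape[1] > 2:
        D = pdist(values.to_numpy().T, metric="euclidean")
        Z = hierarchy.linkage(D, method="average")
        labels = hierarchy.fcluster(Z, t=cfg.sample_cut_height, criterion="distance")
        counts = pd.Series(labels).value_counts()
        keep_label = counts.idxmax()
        keep_mask = labels == keep_label
        n_cut = int((~keep_mask).sum())
        if n_cut:
            logger.info("excluded %d outlier sample(s) at cut height %g",
                        n_cut, cfg.sample_cut_height)
        values = values.loc[:, keep_mask]
        samples = t.samples.loc[keep_mask]
    return ExpressionTensor(values=values, samples=samples.copy(), unit=t.unit,
                            stage_order=list(t.stage_order))


def _pearson_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-row Pearson correlation; constant rows are flagged for removal."""
    sd = X.std(axis=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("dropping %d constant gene row(s) before correlation",
                       int((~ok).sum()))
    C = np.corrcoef(X[ok])
    C = np.clip(C, -1.0, 1.0)
    return C, ok


def signed_adjacency(t: ExpressionTensor, power: int) -> pd.DataFrame:
    """Signed soft-threshold adjacency ``((1 + cor)/2)^power``, zero diagonal."""
    X = t.values.to_numpy(dtype=float)
    if X.shape[0] > 20_000:
        raise ValueError(
            f"{X.shape[0]} genes exceed the single-block cap; "
            "raise NetworkConfig.max_genes deliberately or pre-filter"
        )
    C, ok = _pearson_rows(X)
    A = ((1.0 + C) / 2.0) ** power
    np.fill_diagonal(A, 0.0)
    genes = t.values.index[ok]
    return pd.DataFrame(A, index=genes, columns=genes)


@dataclass
class SoftPowerFit:
    """Scale-free topology fit over candidate soft powers."""

    candidates: list[int]
    r_squared: list[float]
    mean_connectivity: list[float]
    chosen: int
    target: float


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R² of log10 p(k) vs log10 k over equal-width connectivity bins."""
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return 0.0
    fit = stats.linregress(log_k, log_p)
    return float(fit.rvalue ** 2)


def pick_soft_power(
    t: ExpressionTensor,
    candidates: list[int] | None = None,
    target_r2: float = 0.85,
) -> SoftPowerFit:
    """Choose the soft-threshold power for approximate scale-free topology.

    For each candidate power the signed adjacency is formed, per-gene
    connectivity ``k_i = sum_j a_ij`` computed, and the linearity of
    log10 p(k) vs log10 k measured. The smallest power whose fit exceeds
    ``target_r2`` is chosen; if none reaches it, the power with the best
    fit (smallest power on ties) is used.
    """
    candidates = sorted(candidates or [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16])
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate powers")
    X = t.values.to_numpy(dtype=float)
    C, _ = _pearson_rows(X)
    base = (1.0 + C) / 2.0
    np.fill_diagonal(base, 0.0)

    r2s, mean_k = [], []
    for p in candidates:
        A = base ** p
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        r2s.append(_scale_free_r2(k))
        mean_k.append(float(k.mean()))
    passing = [p for p, r2 in zip(candidates, r2s) if r2 > target_r2]
    chosen = passing[0] if passing else candidates[int(np.argmax(r2s))]
    return SoftPowerFit(candidates=candidates, r_squared=r2s,
                        mean_connectivity=mean_k, chosen=chosen, target=target_r2)


def tom_dissimilarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap dissimilarity ``1 - TOM`` of a signed adjacency.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``;
    two genes overlap fully (dissimilarity 0) when they share identical
    neighborhoods and are directly connected, and not at all
    (dissimilarity 1) when unconnected with disjoint neighborhoods.
    """
    A = adjacency.to_numpy() if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency)
    A = A.astype(float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if np.abs(np.diag(A)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    shared = A @ A  # zero diagonal makes this sum_{u != i,j} a_iu a_uj
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip(diss, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(diss, index=adjacency.index, columns=adjacency.columns)
    return diss


@dataclass
class ModuleSet:
    """Gene→module assignment with module eigengenes.

    Labels are ``"M1", "M2", ...`` ordered by descending module size
    (ties by first member); genes in no sufficiently large cohesive branch
    are ``"unassigned"``. ``eigengenes`` is module × sample (unit-norm PC1
    score rows), filled by :func:`compute_eigengenes`.
    """

    assignment: pd.Series  # gene -> label
    eigengenes: pd.DataFrame | None = None
    linkage_matrix: np.ndarray | None = None

    @property
    def sizes(self) -> pd.Series:
        assigned = self.assignment[self.assignment != "unassigned"]
        return assigned.value_counts()

    @property
    def module_labels(self) -> list[str]:
        return sorted(self.sizes.index, key=lambda m: int(m[1:]))

    def members(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])


def _cut_tree_dynamic(
    Z: np.ndarray, n: int, min_size: int, gap: float
) -> list[list[int]]:
    """Adaptive branch pruning of the dendrogram.

    The cut height is chosen relative to the tree itself — ``(1 - gap)``
    of the top merge height — so that joins near the dissimilarity
    ceiling (unrelated branches in a soft-thresholded signed network sit
    close to 1 - TOM = 1) are severed while cohesive branches survive
    intact. Maximal branches below the cut with at least ``min_size``
    leaves are the modules; everything else (noise genes merge near the
    ceiling and scatter into small fragments) stays unassigned.
    """
    root_height = Z[:, 2].max() if len(Z) else 0.0
    t = (1.0 - gap) * root_height
    labels = hierarchy.fcluster(Z, t=t, criterion="distance")
    branches: dict[int, list[int]] = {}
    for leaf, lab in enumerate(labels):
        branches.setdefault(int(lab), []).append(leaf)
    return [b for b in branches.values() if len(b) >= min_size]


def detect_modules(
    dissimilarity: pd.DataFrame, cfg: NetworkConfig
) -> ModuleSet:
    """Average-linkage clustering of 1-TOM with an adaptive (dynamic) cut.

    Deterministic given its inputs: the dendrogram is built once and
    branches are accepted as modules when cohesive and at least
    ``cfg.min_module_size`` genes; everything else is ``"unassigned"``.
    """
    genes = list(dissimilarity.index)
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    n = D.shape[0]
    if n < cfg.min_module_size:
        logger.warning("fewer genes (%d) than min module size (%d): all unassigned",
                       n, cfg.min_module_size)
        return ModuleSet(assignment=pd.Series("unassigned", index=genes))
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    branches = _cut_tree_dynamic(Z, n, cfg.min_module_size, cfg.cut_gap)

    modules = [b for b in branches if len(b) >= cfg.min_module_size]
    if not modules:
        logger.warning("no cohesive branch reached min module size %d: all unassigned",
                       cfg.min_module_size)
        return ModuleSet(assignment=pd.Series("unassigned", index=genes),
                         linkage_matrix=Z)
    modules.sort(key=lambda b: (-len(b), min(b)))
    assignment = pd.Series("unassigned", index=genes, dtype=object)
    for i, members in enumerate(modules, start=1):
        assignment.iloc[members] = f"M{i}"
    return ModuleSet(assignment=assignment, linkage_matrix=Z)


def compute_eigengenes(t: ExpressionTensor, assignment: pd.Series) -> pd.DataFrame:
    """Module eigengenes: PC1 sample scores of each module's expression.

    Per module, gene rows are standardized (zero mean, unit variance over
    samples) and the first right singular vector across samples taken as
    the eigengene (unit norm). The sign is oriented so that the eigengene
    correlates positively with the module's mean standardized profile;
    downstream regression coefficients depend on this convention.
    """
    labels = [m for m in pd.unique(assignment) if m != "unassigned"]
    labels.sort(key=lambda m: (len(m), m))
    if not labels:
        raise ValueError("no assigned modules")
    rows = {}
    for label in labels:
        members = assignment.index[assignment == label]
        if len(members) < 2:
            raise ValueError(f"module {label} has fewer than 2 genes")
        X = t.values.loc[members].to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        # first right singular vector = PC1 sample scores (unit norm)
        _, _, vt = np.linalg.svd(Xs, full_matrices=False)
        me = vt[0]
        mean_profile = Xs.mean(axis=0)
        orient = np.dot(me, mean_profile)
        if orient < 0 or (orient == 0 and (me[me != 0][:1] < 0).any()):
            me = -me
        rows[label] = me
    eig = pd.DataFrame(rows, index=t.values.columns).T
    eig.index.name = "module"
    return eig
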