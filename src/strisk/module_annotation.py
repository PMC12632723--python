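"""Annotation of co-expression modules and gene sets.

Three complementary enrichments:

* module × trait overlap by one-sided Fisher's exact test against the
  network gene universe, Bonferroni-corrected over all tested pairs, with
  the top three modules per trait flagged by odds ratio;
* cell-type specificity by rank-biserial enrichment of a module's (or
  gene set's) genes within each cell-type mean-expression column,
  Z-scored across cell types;
* generic over-representation of a gene list against a user-supplied
  term → gene annotation table (hypergeometric upper tail, BH-corrected,
  with a term-size window applied before testing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import rank_biserial
from .expression_io import CellTypeProfile
from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_module_trait",
    "celltype_enrichment",
    "overrepresentation",
]


def _fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail hypergeometric p for a 2x2 table (enrichment direction)."""
    # overlap a out of a+b module genes, a+c trait genes, N total
    N = a + b + c + d
    K = a + c  # trait genes in background
    n = a + b  # module size
    return float(stats.hypergeom.sf(a - 1, N, K, n))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def fisher_module_trait(
    assignment: pd.Series,
    trait_sets: GeneSetCollection,
    background: set[str] | None = None,
    alpha: float = 0.05,
    bonferroni_family: str = "all",
) -> pd.DataFrame:
    """Risk-gene enrichment of each module against each trait set.

    The background universe is the network's gene universe (the genes that
    survived filtering and were assigned or left unassigned), not the full
    genome; trait sets are intersected with it before counting. Returns
    one row per (module, trait) with the 2×2 counts, odds ratio, one-sided
    p, Bonferroni-corrected p (family = all tests, or per trait), a
    significance flag at ``alpha``, and a top-3-per-trait flag by
    descending odds ratio.
    """
    if bonferroni_family not in ("all", "per_trait"):
        raise ValueError("bonferroni_family must be 'all' or 'per_trait'")
    background = set(background) if background is not None else set(assignment.index)
    if not set(assignment.index) <= background:
        raise ValueError("background must contain every module gene")
    modules = [m for m in pd.unique(assignment) if m != "unassigned"]

    rows = []
    for gs in trait_sets:
        trait_genes = gs.genes & background
        if not trait_genes:
            logger.warning("trait set %s has empty intersection with background", gs.name)
            for module in modules:
                rows.append((module, gs.name, np.nan, np.nan, np.nan, np.nan,
                             np.nan, np.nan))
            continue
        for module in modules:
            member = set(assignment.index[assignment == module])
            a = len(member & trait_genes)
            b = len(member) - a
            c = len(trait_genes) - a
            d = len(background) - a - b - c
            rows.append((module, gs.name, a, b, c, d,
                         _odds_ratio(a, b, c, d), _fisher_one_sided(a, b, c, d)))
    out = pd.DataFrame(rows, columns=["module", "trait", "a", "b", "c", "d",
                                      "odds_ratio", "p"])
    tested = out["p"].notna()
    if bonferroni_family == "all":
        n_tests = int(tested.sum())
        out["p_bonferroni"] = np.minimum(out["p"] * n_tests, 1.0)
    else:
        out["p_bonferroni"] = np.nan
        for trait, idx in out.groupby("trait").groups.items():
            sub = out.loc[idx, "p"]
            out.loc[idx, "p_bonferroni"] = np.minimum(sub * sub.notna().sum(), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha

    out["top3_for_trait"] = False
    for trait, grp in out[tested].groupby("trait"):
        ranked = grp.sort_values(
            by=["odds_ratio", "p"], ascending=[False, True], kind="mergesort"
        )
        out.loc[ranked.index[:3], "top3_for_trait"] = True
    return out


def celltype_enrichment(
    profile: CellTypeProfile,
    units: dict[str, set[str]] | GeneSetCollection,
) -> pd.DataFrame:
    """Rank-biserial cell-type specificity of gene lists.

    Per unit (module member list or trait gene set) and per cell type, the
    unit's measured genes are compared with all remaining genes within
    that cell type's mean-expression column; r values are Z-scored across
    cell types within each unit. Units with no measured gene are skipped.
    """
    if profile.values.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if isinstance(units, GeneSetCollection):
        units = {gs.name: set(gs.genes) for gs in units}
    genes = pd.Index(profile.values.index)

    rows = []
    for name, members in units.items():
        mask = np.asarray(genes.isin(members))
        if mask.sum() == 0:
            logger.warning("unit %s has no measured genes; skipped", name)
            continue
        if mask.all():
            logger.warning("unit %s covers every measured gene; skipped", name)
            continue
        for ct in profile.cell_types:
            cell = rank_biserial(profile.values[ct].to_numpy(), mask,
                                 set_name=name, sample_id=str(ct))
            rows.append((name, ct, cell.r, cell.p))
    out = pd.DataFrame(rows, columns=["unit", "cell_type", "r", "p"])

    def _z(r: pd.Series) -> pd.Series:
        sd = r.std(ddof=1)
        if not sd > 0:
            return pd.Series(0.0, index=r.index)
        return (r - r.mean()) / sd

    out["z"] = out.groupby("unit", sort=False)["r"].transform(_z)
    return out


def overrepresentation(
    genes: set[str] | list[str],
    annotation: dict[str, set[str]] | GeneSetCollection,
    universe: set[str],
    q_cut: float = 0.05,
    min_size: int = 3,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against terms.

    Terms (GO/KEGG-style, user-supplied) are restricted to the universe,
    filtered by the [min_size, max_size] window *before* testing, scored
    by the hypergeometric upper tail, and BH-corrected across the tested
    terms. ``kept`` flags terms with q below ``q_cut``.
    """
    query = {g.strip().upper() for g in genes}
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    if isinstance(annotation, GeneSetCollection):
        annotation = {gs.name: set(gs.genes) for gs in annotation}

    N, k = len(universe), len(query)
    rows = []
    n_window_excluded = 0
    for term, members in annotation.items():
        members = set(members) & universe
        if not (min_size <= len(members) <= max_size):
            n_window_excluded += 1
            continue
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, N, len(members), k))
        rows.append((term, len(members), overlap, p))
    if n_window_excluded:
        logger.info("%d term(s) excluded by the [%d, %d] size window",
                    n_window_excluded, min_size, max_size)
    if not rows:
        logger.warning("no testable terms after size filtering")
        return pd.DataFrame(columns=["term", "term_size", "overlap", "p", "q", "kept"])
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    from statsmodels.stats.multitest import multipletests

    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["kept"] = out["q"] < q_cut
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
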