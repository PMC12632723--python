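"""Imaging-transcriptomics correlation.

Regional risk-gene enrichment (rank-biserial r on region-averaged adult
expression profiles) is correlated with case-control structural
effect sizes (d_icv: intracranial-volume-adjusted Cohen's d per region
from meta-analyzed MRI) by Spearman rank correlation over the matched
regions. A user-editable match table maps transcriptome atlas regions to
morphometry regions, lists the left/right hemisphere members to average,
and marks exclusions (e.g. the lateral ventricles, which are
non-parenchymal) that never enter the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMatchTable",
    "CorrelationResult",
    "average_hemispheres",
    "correlate",
]

MATCH_COLUMNS = ["atlas_region", "morph_region", "member", "excluded", "reason"]


@dataclass
class RegionMatchTable:
    """Atlas ↔ morphometry region correspondence.

    One row per (morphometry region, hemisphere member); ``excluded`` rows
    (with a reason) are dropped before averaging and correlation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MATCH_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"match table missing columns: {missing}")
        self.table = self.table.copy()
        self.table["excluded"] = self.table["excluded"].astype(bool)

    @classmethod
    def from_tsv(cls, path) -> "RegionMatchTable":
        return cls(pd.read_csv(path, sep="\t"))

    def retained(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]


def average_hemispheres(
    effects: pd.Series, match: RegionMatchTable
) -> pd.DataFrame:
    """Hemisphere-averaged structural effect size per retained region.

    ``effects`` maps member labels (e.g. ``L_hippocampus``) to effect
    sizes; for every retained morphometry region the arithmetic mean of
    its members is taken (single-hemisphere structures pass through).
    Excluded regions are dropped; a missing member is a hard error.
    """
    rows = []
    for morph, grp in match.retained().groupby("morph_region", sort=False):
        members = grp["member"].tolist()
        absent = [m for m in members if m not in effects.index]
        if absent:
            raise ValueError(f"region {morph!r}: missing effect size for {absent}")
        atlas = sorted(set(grp["atlas_region"]))
        rows.append((morph, ";".join(atlas), float(effects[members].mean()), len(members)))
    n_excluded = int(match.table["excluded"].sum())
    if n_excluded:
        logger.info("excluded %d match row(s): %s", n_excluded,
                    sorted(set(match.table.loc[match.table['excluded'], 'morph_region'])))
    return pd.DataFrame(rows, columns=["morph_region", "atlas_region", "d_icv", "n_members"])


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of regional enrichment with structural effects."""

    trait: str
    rho: float
    p: float
    n: int


def correlate(
    effect_table: pd.DataFrame,
    enrichment_col: str = "enrichment_r",
    effect_col: str = "d_icv",
    trait: str = "",
) -> CorrelationResult:
    """Spearman rho (average-rank ties, two-sided p) across matched regions.

    ``effect_table`` needs one row per retained region with a regional
    enrichment column and a structural effect column. Constant columns
    leave rho undefined (NaN, with a warning).
    """
    x = effect_table[enrichment_col].to_numpy(dtype=float)
    y = effect_table[effect_col].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 regions, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant column; Spearman rho undefined")
        return CorrelationResult(trait=trait, rho=np.nan, p=np.nan, n=n)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(trait=trait, rho=float(rho), p=float(p), n=n)
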