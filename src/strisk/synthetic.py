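"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure each analysis stage
assumes, with known truth so recovery can be scored:

* ``make_bulk`` — a genes × (region × stage × donor) expression tensor
  with log-normal baseline expression and planted risk gene sets whose
  members get a multiplicative boost ``exp(delta)`` in chosen
  (region, stage) target cells — a rank shift, so the monotone-invariance
  properties of the enrichment statistic are preserved;
* ``make_modules`` — latent-factor co-expression modules whose factors
  follow additive region/stage effects, for network/module-detection and
  spatiotemporal regression recovery;
* ``make_celltypes`` — cell-type mean profiles with planted signature
  gene sets elevated by a configured fold;
* ``make_morphometry`` — per-region structural effect sizes coupled to a
  regional enrichment vector with a calibrated target Spearman
  correlation, emitted as left/right hemisphere pairs.

Everything is deterministic under the configured seed. Default dimensions
are sized for sub-minute runs (2,000 genes, 6 regions × 6 stages ×
2 donors) while keeping every planted effect comfortably detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import DEFAULT_STAGES, CellTypeProfile, ExpressionTensor
from .genesets import GeneSet, GeneSetCollection
from .imaging import RegionMatchTable

__all__ = [
    "PlantedSet",
    "PlantedModule",
    "SynthConfig",
    "GroundTruth",
    "make_bulk",
    "make_modules",
    "make_celltypes",
    "make_morphometry",
    "make_match_table",
    "overlapping_sets",
    "enrichment_preset",
    "modules_preset",
]

DEFAULT_REGIONS = ["NCX", "HIP", "AMY", "STR", "MD", "CBC"]
DEFAULT_STAGE_LABELS = [s for s, _ in DEFAULT_STAGES[:6]]


@dataclass(frozen=True)
class PlantedSet:
    """A risk gene set over-expressed in chosen (region, stage) cells."""

    name: str
    size: int
    cells: tuple[tuple[str, str], ...]  # (region, stage) target cells
    delta: float = 2.0  # log-scale boost; rank-shift effect size
    trait: str = ""

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class PlantedModule:
    """A latent-factor co-expression module with a spatiotemporal profile."""

    name: str
    size: int
    region_effects: tuple[tuple[str, float], ...] = ()
    stage_effects: tuple[tuple[str, float], ...] = ()
    rho: float = 0.6  # within-module pairwise correlation
    factor_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie strictly between 0 and 1")


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic generators."""

    n_genes: int = 2000
    regions: list[str] = field(default_factory=lambda: list(DEFAULT_REGIONS))
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGE_LABELS))
    donors_per_cell: int = 2
    baseline_mu: float = 1.0   # log-scale location of gene means
    baseline_sd: float = 1.0   # spread of gene-specific locations
    noise_sd: float = 0.5      # within-gene log-scale sample noise
    planted_sets: list[PlantedSet] = field(default_factory=list)
    planted_modules: list[PlantedModule] = field(default_factory=list)
    cell_types: list[str] = field(
        default_factory=lambda: ["Ex", "In", "Astro", "Oligo", "Micro"]
    )
    signature_size: int = 40
    signature_fold: float = 4.0
    morph_target_rho: float = -0.48
    seed: int = 0

    def __post_init__(self) -> None:
        total_set = sum(s.size for s in self.planted_sets)
        total_mod = sum(m.size for m in self.planted_modules)
        if max(total_set, total_mod) > self.n_genes:
            raise ValueError("planted sets/modules exceed the number of genes")
        for s in self.planted_sets:
            for region, stage in s.cells:
                if region not in self.regions or stage not in self.stages:
                    raise ValueError(f"planted cell ({region}, {stage}) outside vocabularies")

    def sample_frame(self) -> pd.DataFrame:
        """Sample annotations for the full region × stage × donor layout."""
        rows = []
        for region in self.regions:
            for stage in self.stages:
                for d in range(1, self.donors_per_cell + 1):
                    sid = f"{region}.{stage.replace(' ', '_')}.d{d}"
                    rows.append((sid, f"donor{d}", stage, region))
        df = pd.DataFrame(rows, columns=["sample_id", "donor_id", "stage", "region"])
        return df.set_index("sample_id")


@dataclass
class GroundTruth:
    """What was planted, sufficient to score recovery."""

    set_cells: dict[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)
    set_genes: dict[str, list[str]] = field(default_factory=dict)
    module_members: dict[str, list[str]] = field(default_factory=dict)
    module_factors: pd.DataFrame | None = None  # module x sample raw factors
    module_effects: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    signatures: dict[str, list[str]] = field(default_factory=dict)
    regional_enrichment: pd.Series | None = None

    def module_assignment(self) -> pd.Series:
        items = {}
        for label, members in self.module_members.items():
            for g in members:
                items[g] = label
        return pd.Series(items, dtype=object)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def make_bulk(cfg: SynthConfig) -> tuple[ExpressionTensor, GeneSetCollection, GroundTruth]:
    """Bulk tensor with planted risk-set over-expression in target cells.

    Baseline: ``x_gs = exp(mu_g + noise_sd * eps_gs)`` with gene locations
    ``mu_g ~ N(baseline_mu, baseline_sd)``. In each of a planted set's
    target cells its member genes are multiplied by ``exp(delta)``,
    shifting their within-sample ranks upward.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    samples = cfg.sample_frame()
    n_s = len(samples)

    mu = rng.normal(cfg.baseline_mu, cfg.baseline_sd, size=cfg.n_genes)
    log_x = mu[:, None] + cfg.noise_sd * rng.standard_normal((cfg.n_genes, n_s))

    truth = GroundTruth()
    cursor = 0
    sets = []
    cell_of = list(zip(samples["region"], samples["stage"]))
    for ps in cfg.planted_sets:
        members = genes[cursor : cursor + ps.size]
        cursor += ps.size
        idx = np.arange(cursor - ps.size, cursor)
        target_cols = np.array([cell in ps.cells for cell in cell_of])
        log_x[np.ix_(idx, np.flatnonzero(target_cols))] += ps.delta
        sets.append(GeneSet.from_symbols(ps.name, members,
                                         trait=ps.trait or ps.name, strategy="planted"))
        truth.set_cells[ps.name] = ps.cells
        truth.set_genes[ps.name] = list(members)

    values = pd.DataFrame(np.exp(log_x), index=pd.Index(genes, name="gene"),
                          columns=samples.index)
    tensor = ExpressionTensor(values=values, samples=samples, unit="RPKM",
                              stage_order=list(cfg.stages))
    coll = GeneSetCollection(sets=sets, universe=set(genes))
    return tensor, coll, truth


def make_modules(cfg: SynthConfig) -> tuple[ExpressionTensor, GroundTruth]:
    """Latent-factor module tensor on the region × stage × donor layout.

    Each planted module has a per-sample factor
    ``f_s = sum region/stage effects + N(0, factor_noise_sd)``; member
    genes are ``sqrt(rho) * standardize(f) + sqrt(1-rho) * noise`` so the
    expected within-module pairwise correlation is ``rho``. Remaining
    genes are independent noise. Values are on a log-like scale (may be
    negative), unit ``LOG2CPM``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    samples = cfg.sample_frame()
    n_s = len(samples)

    X = rng.standard_normal((cfg.n_genes, n_s))
    truth = GroundTruth()
    factors = {}
    cursor = 0
    for pm in cfg.planted_modules:
        members = genes[cursor : cursor + pm.size]
        idx = np.arange(cursor, cursor + pm.size)
        cursor += pm.size
        region_eff = dict(pm.region_effects)
        stage_eff = dict(pm.stage_effects)
        f = (
            samples["region"].map(lambda r: region_eff.get(r, 0.0)).to_numpy()
            + samples["stage"].map(lambda s: stage_eff.get(s, 0.0)).to_numpy()
            + pm.factor_noise_sd * rng.standard_normal(n_s)
        )
        f_std = (f - f.mean()) / f.std()
        eps = rng.standard_normal((pm.size, n_s))
        X[idx] = np.sqrt(pm.rho) * f_std[None, :] + np.sqrt(1 - pm.rho) * eps
        factors[pm.name] = f
        truth.module_members[pm.name] = list(members)
        truth.module_effects[pm.name] = {"region": region_eff, "stage": stage_eff}

    truth.module_factors = pd.DataFrame(factors, index=samples.index).T
    values = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples.index)
    tensor = ExpressionTensor(values=values, samples=samples, unit="LOG2CPM",
                              stage_order=list(cfg.stages))
    return tensor, truth


def make_celltypes(cfg: SynthConfig) -> tuple[CellTypeProfile, GroundTruth]:
    """Cell-type mean profiles with planted signature gene sets.

    Each cell type gets ``signature_size`` dedicated genes whose mean
    expression is multiplied by ``signature_fold`` in that type's column.
    A fold of 1 is the null (no specificity).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    base = np.exp(rng.normal(cfg.baseline_mu, cfg.baseline_sd, size=cfg.n_genes))
    noise = np.exp(0.1 * rng.standard_normal((cfg.n_genes, len(cfg.cell_types))))
    values = base[:, None] * noise

    truth = GroundTruth()
    cursor = 0
    for j, ct in enumerate(cfg.cell_types):
        sig = list(range(cursor, cursor + cfg.signature_size))
        cursor += cfg.signature_size
        if cursor > cfg.n_genes:
            raise ValueError("signatures exceed the number of genes")
        values[sig, j] *= cfg.signature_fold
        truth.signatures[ct] = [genes[i] for i in sig]

    profile = CellTypeProfile(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                            columns=cfg.cell_types),
        unit="CPM",
    )
    return profile, truth


def make_match_table(regions: list[str]) -> RegionMatchTable:
    """L/R match-table skeleton over morphometry regions, ventricles excluded."""
    rows = []
    for region in regions:
        for hemi in ("L", "R"):
            rows.append((region, region, f"{hemi}_{region}", False, ""))
    rows.append(("Lateral_Ventricles", "Lateral_Ventricles", "L_Lateral_Ventricles",
                 True, "non-parenchymal"))
    rows.append(("Lateral_Ventricles", "Lateral_Ventricles", "R_Lateral_Ventricles",
                 True, "non-parenchymal"))
    return RegionMatchTable(pd.DataFrame(
        rows, columns=["atlas_region", "morph_region", "member", "excluded", "reason"]
    ))


def make_morphometry(
    regional_enrichment: pd.Series,
    target_rho: float,
    seed: int = 0,
    lr_jitter_sd: float = 0.02,
    scale: float = 0.2,
) -> tuple[pd.Series, RegionMatchTable]:
    """Structural effect sizes coupled to regional enrichment.

    The coupling is built on normal scores of the enrichment ranks with
    Pearson correlation ``2 sin(pi * target_rho / 6)`` — the classical
    conversion giving an expected Spearman correlation of ``target_rho``
    for bivariate normal data. Effects are scaled to Cohen's-d-like
    magnitudes and emitted as left/right hemisphere members with small
    jitter, together with a match table that includes excluded
    ventricles.
    """
    if not -1 <= target_rho <= 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    regions = list(regional_enrichment.index)
    n = len(regions)
    from scipy import stats as _st

    ranks = _st.rankdata(regional_enrichment.to_numpy())
    z = _st.norm.ppf((ranks - 0.5) / n)
    rho_p = 2 * np.sin(np.pi * target_rho / 6)
    y = rho_p * z + np.sqrt(max(0.0, 1 - rho_p**2)) * rng.standard_normal(n)
    d = scale * y

    effects = {}
    for region, val in zip(regions, d):
        jitter = lr_jitter_sd * rng.standard_normal()
        effects[f"L_{region}"] = val + jitter
        effects[f"R_{region}"] = val - jitter
    # ventricle entries exist but are excluded by the match table
    effects["L_Lateral_Ventricles"] = float(rng.normal(0, scale))
    effects["R_Lateral_Ventricles"] = float(rng.normal(0, scale))
    return pd.Series(effects, name="d_icv"), make_match_table(regions)


def overlapping_sets(
    universe: list[str], size_a: int, size_b: int, jaccard: float, seed: int = 0,
    names: tuple[str, str] = ("A", "B"),
) -> GeneSetCollection:
    """Two gene sets with (approximately) a requested Jaccard similarity.

    The shared-gene count is ``round(J * (size_a + size_b) / (1 + J))``;
    the realized Jaccard is exact up to that rounding.
    """
    overlap = round(jaccard * (size_a + size_b) / (1 + jaccard))
    if overlap > min(size_a, size_b):
        raise ValueError("requested Jaccard not achievable at these sizes")
    realized = overlap / (size_a + size_b - overlap)
    if abs(realized - jaccard) > 0.02:
        raise ValueError(
            f"requested Jaccard {jaccard} not achievable at these sizes "
            f"(closest realizable: {realized:.3f})")
    need = size_a + size_b - overlap
    if need > len(universe):
        raise ValueError("universe too small")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=need, replace=False)
    pool = [universe[i] for i in chosen]
    shared = pool[:overlap]
    a = shared + pool[overlap : overlap + size_a - overlap]
    b = shared + pool[overlap + size_a - overlap :]
    return GeneSetCollection(sets=[
        GeneSet.from_symbols(names[0], a, trait=names[0]),
        GeneSet.from_symbols(names[1], b, trait=names[1]),
    ])


def enrichment_preset(seed: int = 0, delta: float = 2.0) -> SynthConfig:
    """Default enrichment study conditions: one planted set per target cell."""
    return SynthConfig(
        n_genes=2000,
        planted_sets=[
            PlantedSet("RiskA", 100, (("NCX", DEFAULT_STAGE_LABELS[0]),), delta, trait="TraitA"),
            PlantedSet("RiskB", 100, (("MD", DEFAULT_STAGE_LABELS[4]),), delta, trait="TraitB"),
        ],
        seed=seed,
    )


def modules_preset(seed: int = 0, rho: float = 0.6, n_modules: int = 5) -> SynthConfig:
    """Default module study conditions: 500 genes in 5 planted modules,
    5 regions × 6 stages × 2 donors = 60 samples."""
    regions = DEFAULT_REGIONS[:5]
    stages = DEFAULT_STAGE_LABELS[:6]
    modules = [
        PlantedModule(
            name=f"truth{i + 1}",
            size=100,
            region_effects=((regions[i % len(regions)], 1.0),),
            stage_effects=((stages[i % len(stages)], 1.0),),
            rho=rho,
        )
        for i in range(n_modules)
    ]
    return SynthConfig(
        n_genes=100 * n_modules,
        regions=regions,
        stages=stages,
        donors_per_cell=2,
        planted_modules=modules,
        seed=seed,
    )
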