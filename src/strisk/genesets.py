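"""Named risk gene sets: loading, merging, Jaccard overlap, random controls.

Gene sets are curated gene-symbol lists per trait and gene-mapping strategy
(GWAS positional/MAGMA mapping, exome sequencing, eQTL nomination, ...).
Symbols are normalized by whitespace-stripping and upper-casing only; no
alias mapping is attempted, so the lists stay auditable against their
sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "load_gene_sets",
    "write_gmt",
    "merge_by_trait",
    "jaccard_matrix",
    "random_control_sets",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and upper-cased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named, de-duplicated set of gene symbols with provenance.

    Parameters
    ----------
    name : str
        Unique short identifier (e.g. ``"SZ_ES_2022Nature"``).
    genes : frozenset of str
        Case-normalized unique symbols; must be non-empty.
    trait : str
        Trait label (one of the study traits, or ``"control"``).
    strategy : str
        Free-text gene-mapping strategy (e.g. ``"Exome Sequencing"``).
    source : str
        Free-text citation string.
    """

    name: str
    genes: frozenset[str]
    trait: str = ""
    strategy: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty after normalization")

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        trait: str = "",
        strategy: str = "",
        source: str = "",
    ) -> "GeneSet":
        genes = frozenset(normalize_symbol(s) for s in symbols if s.strip())
        return cls(name=name, genes=genes, trait=trait, strategy=strategy, source=source)

    def __len__(self) -> int:
        return len(self.genes)

    def coverage(self, universe: set[str]) -> float:
        """Fraction of member genes found in ``universe``."""
        return len(self.genes & universe) / len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets.

    ``universe`` is the optional background of measurable symbols (e.g. the
    genes present in an expression matrix); it is not used to trim sets —
    trimming happens at scoring time.
    """

    sets: list[GeneSet] = field(default_factory=list)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene set names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def traits(self) -> list[str]:
        """Distinct trait labels in collection order."""
        seen: dict[str, None] = {}
        for s in self.sets:
            if s.trait:
                seen.setdefault(s.trait)
        return list(seen)


def load_gene_sets(
    path: str | Path,
    universe: set[str] | None = None,
    metadata: str | Path | None = None,
) -> GeneSetCollection:
    """Load gene sets from a GMT file, optionally attaching metadata.

    GMT format: tab-separated ``name<TAB>description<TAB>gene1<TAB>gene2...``
    per line. ``metadata`` is an optional TSV with columns
    ``name/trait/strategy/source`` keyed on set name. If ``universe`` is
    given, per-set coverage is computed and sets with genes missing from it
    are reported via logging (the genes are retained).
    """
    path = Path(path)
    meta: dict[str, dict[str, str]] = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
        meta = {row["name"]: row for _, row in mdf.iterrows()}

    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc = fields[0], fields[1]
            symbols = [f for f in fields[2:] if f.strip()]
            if not symbols:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            m = meta.get(name, {})
            gs = GeneSet.from_symbols(
                name,
                symbols,
                trait=m.get("trait", desc),
                strategy=m.get("strategy", ""),
                source=m.get("source", ""),
            )
            sets.append(gs)

    coll = GeneSetCollection(sets=sets, universe=universe)
    if universe is not None:
        for s in coll:
            missing = len(s.genes) - len(s.genes & universe)
            if missing:
                logger.warning(
                    "gene set %s: %d/%d symbols absent from universe (coverage %.3f)",
                    s.name, missing, len(s), s.coverage(universe),
                )
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (sorted symbols for reproducible diffs)."""
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.trait or "na", *sorted(s.genes)]) + "\n")


def merge_by_trait(
    coll: GeneSetCollection, trait: str, exclude: Sequence[str] | None = None
) -> GeneSet:
    """Union of all member sets carrying ``trait``, named ``<trait>_merged``.

    Traits mapped by several strategies are merged into one pan risk set for
    cross-trait comparison; callers keep heterogeneous sub-phenotypes apart
    (e.g. exome-sequencing vs GWAS schizophrenia) by tagging them as distinct
    traits.
    """
    exclude = set(exclude or ())
    members = [s for s in coll if s.trait == trait and s.name not in exclude]
    if not members:
        raise ValueError(f"no gene set carries trait {trait!r}")
    genes: frozenset[str] = frozenset().union(*(s.genes for s in members))
    return GeneSet(
        name=f"{trait}_merged",
        genes=genes,
        trait=trait,
        strategy="merged",
        source=";".join(s.name for s in members),
    )


def jaccard_matrix(coll: GeneSetCollection) -> pd.DataFrame:
    """Pairwise Jaccard similarity ``|A∩B| / |A∪B|`` over the full sets.

    Computed on the curated lists as given (no intersection with the
    expression universe). Symmetric with unit diagonal.
    """
    if len(coll) < 2:
        raise ValueError("need at least 2 gene sets for a Jaccard matrix")
    names = coll.names
    n = len(names)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = coll.sets[i].genes, coll.sets[j].genes
            J[i, j] = J[j, i] = len(a & b) / len(a | b)
    return pd.DataFrame(J, index=names, columns=names)


def random_control_sets(
    universe: Sequence[str] | set[str],
    sizes: Sequence[int],
    n_reps: int = 1,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets sampled without replacement from ``universe``.

    Negative controls for the enrichment analysis: ``n_reps`` independent
    draws at each requested size, reproducible for a fixed ``seed``. Set
    names follow ``Random_<size>`` (suffixed ``_r<rep>`` when n_reps > 1).
    """
    pool = sorted(normalize_symbol(g) for g in universe)
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"requested size {size} exceeds universe size {len(pool)}")
        for rep in range(n_reps):
            name = f"Random_{size}" if n_reps == 1 else f"Random_{size}_r{rep + 1}"
            chosen = rng.choice(len(pool), size=size, replace=False)
            sets.append(
                GeneSet(
                    name=name,
                    genes=frozenset(pool[i] for i in chosen),
                    trait="control",
                    strategy="Randomly Selected",
                )
            )
    return GeneSetCollection(sets=sets, universe=set(pool))
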