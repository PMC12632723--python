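#!/usr/bin/env python
"""Annotate detected modules against trait sets and cell types.

Fisher's exact enrichment of each planted trait (truth member list) in
each detected module against the network gene universe — detected
modules should light up only for their own planted truth — plus
rank-biserial cell-type specificity of the planted signature gene sets
and a generic over-representation run of one module against the truth
"annotation" to exercise the ORA path.
"""

from pathlib import Path

import pandas as pd

from strisk import genesets
from strisk.expression_io import CellTypeProfile
from strisk.module_annotation import (
    celltype_enrichment,
    fisher_module_trait,
    overrepresentation,
)

DATA = Path("results/data")
OUT = Path("results")

assignment = pd.read_csv(OUT / "module_assignment.tsv", sep="\t", index_col=0)["module"]
truth = pd.read_csv(DATA / "truth_modules.tsv", sep="\t", index_col=0)["module"]
trait_sets = genesets.GeneSetCollection(sets=[
    genesets.GeneSet.from_symbols(f"{label}_truth",
                                  truth.index[truth == label], trait=label)
    for label in truth.unique()])

fisher = fisher_module_trait(assignment, trait_sets,
                             background=set(assignment.index))
fisher.to_csv(OUT / "module_trait_fisher.tsv", sep="\t", index=False)
sig = fisher[fisher.significant]
print(f"fisher: {len(fisher)} module x trait tests, "
      f"{len(sig)} significant after Bonferroni")

profile = CellTypeProfile(pd.read_csv(DATA / "celltype_profile.tsv",
                                      sep="\t", index_col=0))
signatures = genesets.load_gene_sets(DATA / "truth_signatures.gmt")
ct = celltype_enrichment(profile, signatures)
ct.to_csv(OUT / "celltype_enrichment.tsv", sep="\t", index=False)
argmax = ct.loc[ct.groupby("unit")["z"].idxmax()]
print("cell types: argmax z per signature ->",
      dict(zip(argmax.unit, argmax.cell_type)))

# ORA of the first detected module against the planted truth lists
universe = set(assignment.index)
module_genes = set(assignment.index[assignment == "M1"])
ann = {gs.name: set(gs.genes) for gs in trait_sets}
ora = overrepresentation(module_genes, ann, universe, max_size=500)
ora.to_csv(OUT / "module1_ora.tsv", sep="\t", index=False)
print(f"ora: best term for M1 is {ora.iloc[0].term} (q={ora.iloc[0].q:.2e})")
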