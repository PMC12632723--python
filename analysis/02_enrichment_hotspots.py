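#!/usr/bin/env python
"""Score every risk gene set in every bulk sample and extract hot-spots.

Per (set, sample): Mann-Whitney rank-biserial r with one-sided p and
per-set BH FDR; per set: stage-mean trajectory with window-3 smoothing
and the top-3 (region, stage) hot-spot cells. Checks the planted target
cells against the rank-1 hot-spots and reports the per-set Jaccard
overlap structure.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from strisk import enrichment, expression_io, genesets

DATA = Path("results/data")
OUT = Path("results")

tensor = expression_io.load_single_table(
    DATA / "bulk_expression.tsv",
    sample_meta=pd.read_csv(DATA / "bulk_samples.tsv", sep="\t", index_col=0))
coll = genesets.load_gene_sets(DATA / "risk_sets.gmt", universe=tensor.universe())
truth = pd.read_csv(DATA / "truth_cells.tsv", sep="\t", index_col=0)["target_cells"]

em = enrichment.enrich_matrix(tensor, coll)
em.table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

rows, hits = [], []
for name in em.set_names:
    hotspots = enrichment.top_hotspots(em, name, k=3)
    rows += [dataclasses.asdict(h) for h in hotspots]
    if name in truth.index:
        region, stage = truth[name].split(";")[0].split("|")
        hits.append((name, (hotspots[0].region, hotspots[0].stage) == (region, stage)))
pd.DataFrame(rows).to_csv(OUT / "hotspots.tsv", sep="\t", index=False)

traj = pd.concat([enrichment.stage_trajectory(em, n).as_frame()
                  for n in em.set_names])
traj.to_csv(OUT / "trajectories.tsv", sep="\t", index=False)

J = genesets.jaccard_matrix(coll)
J.to_csv(OUT / "jaccard.tsv", sep="\t")

import numpy as np

sig = em.table[em.table.q < 0.05]
print(f"enrichment: {len(em.set_names)} sets x {tensor.n_samples} samples; "
      f"{len(sig)} cells at q<0.05")
for name, ok in hits:
    print(f"  planted set {name}: rank-1 hot-spot "
          f"{'matches' if ok else 'MISSES'} the planted target cell")
offdiag = J.to_numpy() - np.eye(len(J))
print(f"  max off-diagonal Jaccard among sets: {offdiag.max():.3f}")
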