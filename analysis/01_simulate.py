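#!/usr/bin/env python
"""Generate the synthetic study datasets with serialized ground truth.

Four data families are written under results/data/: a developmental bulk
tensor with two planted risk gene sets (plus random negative-control
sets), a latent-factor module tensor, cell-type mean profiles with
planted signatures, and hemisphere-paired structural effect sizes coupled
to a regional enrichment vector. Every downstream script reads these
files, so the whole analysis is reproducible from this single seed.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from strisk import genesets, synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

# --- bulk tensor with planted enrichment -------------------------------
cfg = synthetic.enrichment_preset(seed=SEED)
tensor, planted, truth = synthetic.make_bulk(cfg)
controls = genesets.random_control_sets(tensor.universe(), sizes=[50, 100, 1000],
                                        n_reps=1, seed=SEED)
coll = genesets.GeneSetCollection(sets=list(planted) + list(controls),
                                  universe=tensor.universe())
tensor.values.to_csv(OUT / "bulk_expression.tsv", sep="\t")
tensor.samples.to_csv(OUT / "bulk_samples.tsv", sep="\t")
genesets.write_gmt(coll, OUT / "risk_sets.gmt")
pd.Series({k: ";".join(f"{r}|{s}" for r, s in v)
           for k, v in truth.set_cells.items()},
          name="target_cells").to_csv(OUT / "truth_cells.tsv", sep="\t")
print(f"bulk: {tensor.n_genes} genes x {tensor.n_samples} samples "
      f"({len(cfg.regions)} regions x {len(cfg.stages)} stages), "
      f"{len(planted)} planted risk sets (delta={cfg.planted_sets[0].delta}), "
      f"{len(controls)} random controls")

# --- module tensor ------------------------------------------------------
mcfg = synthetic.modules_preset(seed=SEED)
mtensor, mtruth = synthetic.make_modules(mcfg)
mtensor.values.to_csv(OUT / "module_expression.tsv", sep="\t")
mtensor.samples.to_csv(OUT / "module_samples.tsv", sep="\t")
mtruth.module_assignment().rename("module").to_csv(OUT / "truth_modules.tsv", sep="\t")
mtruth.module_factors.to_csv(OUT / "truth_factors.tsv", sep="\t")
print(f"modules: {mtensor.n_genes} genes in {len(mtruth.module_members)} planted "
      f"modules (rho={mcfg.planted_modules[0].rho}), {mtensor.n_samples} samples")

# --- cell-type profiles -------------------------------------------------
ccfg = synthetic.SynthConfig(n_genes=1500, seed=SEED)
profile, ctruth = synthetic.make_celltypes(ccfg)
profile.values.to_csv(OUT / "celltype_profile.tsv", sep="\t")
genesets.write_gmt(
    genesets.GeneSetCollection(sets=[
        genesets.GeneSet.from_symbols(f"sig_{k}", v, trait=k)
        for k, v in ctruth.signatures.items()]),
    OUT / "truth_signatures.gmt")
print(f"cell types: {profile.values.shape[0]} genes x "
      f"{len(profile.cell_types)} types, fold={ccfg.signature_fold}")

# --- morphometry --------------------------------------------------------
rng = np.random.default_rng(SEED)
regions = [f"R{i:02d}" for i in range(38)]
regional = pd.Series(rng.normal(0, 0.1, len(regions)), index=regions,
                     name="enrichment_r")
effects, match = synthetic.make_morphometry(
    regional, target_rho=-0.48, seed=int(rng.integers(0, 2**31 - 1)))
effects.to_csv(OUT / "morph_effects.tsv", sep="\t")
match.table.to_csv(OUT / "region_match.tsv", sep="\t", index=False)
regional.to_csv(OUT / "regional_enrichment.tsv", sep="\t")
print(f"morphometry: {len(regions)} regions, target Spearman -0.48, "
      "ventricles present but flagged excluded")
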