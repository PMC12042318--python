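#!/usr/bin/env python
"""Signed protein co-expression modules per disorder, module-trait
correlations, and cross-disorder module preservation (Fisher overlap of the
PTSD-built and MDD-built module memberships)."""

import argparse
from pathlib import Path

import pandas as pd

from omicweaver import coexpression, pipeline, synthetic
from omicweaver.io_core import write_result_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--region", default="DLPFC")
parser.add_argument("--out", default="results/modules")
args = parser.parse_args()

outdir = Path(args.out)
outdir.mkdir(parents=True, exist_ok=True)
protein, _, _, samples, truth = synthetic.generate_cohort(
    synthetic.CohortConfig(), args.seed)

modsets = {}
for case in ("PTSD", "MDD"):
    mods = pipeline.build_modules(protein, samples, case, args.region)
    modsets[case] = mods
    assign = pd.DataFrame(sorted(mods.assignment.items()),
                          columns=["feature_id", "module"])
    write_result_table(assign, outdir / f"assignment_{case}_{args.region}.tsv")
    mt = coexpression.module_trait_correlation(mods, samples, case=case)
    write_result_table(mt, outdir / f"module_trait_{case}_{args.region}.tsv")
    sizes = assign[assign["module"] != "grey"]["module"].value_counts()
    dx_sig = mt[(mt["trait"] == "dx") & (mt["fdr"] < 0.05)]
    print(f"{case}/{args.region}: {len(sizes)} modules "
          f"(sizes {sizes.min()}-{sizes.max()}), "
          f"{len(dx_sig)} dx-associated at FDR<0.05: {list(dx_sig['module'])}")

pres = coexpression.module_overlap_preservation(modsets["PTSD"], modsets["MDD"])
write_result_table(pres, outdir / f"preservation_PTSD_vs_MDD_{args.region}.tsv")
n_pres = int(pres.groupby("module_a")["preserved"].any().sum())
print(f"preservation: {n_pres}/{pres['module_a'].nunique()} PTSD modules have a "
      f"preserved MDD counterpart (FDR<0.05)")
print(f"tables written to {outdir}/")
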