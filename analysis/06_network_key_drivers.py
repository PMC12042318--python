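#!/usr/bin/env python
"""ARACNE-pruned mutual-information network over module proteins and
undirected key-driver analysis within each module's local network, using the
nominal DEP set as the disease signature."""

import argparse
from pathlib import Path

import pandas as pd

from omicweaver import pipeline, synthetic
from omicweaver.io_core import write_result_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--region", default="DLPFC")
parser.add_argument("--case", default="PTSD")
parser.add_argument("--out", default="results/network")
args = parser.parse_args()

outdir = Path(args.out)
outdir.mkdir(parents=True, exist_ok=True)
protein, _, _, samples, truth = synthetic.generate_cohort(
    synthetic.CohortConfig(), args.seed)

de_prot, _ = pipeline.protein_de(protein, samples, args.case, args.region)
deps = set(de_prot.loc[de_prot["p"] < 0.05, "feature_id"])
mods = pipeline.build_modules(protein, samples, args.case, args.region)
kda = pipeline.module_network_drivers(protein, samples, mods, args.case,
                                      args.region, deps)

for mod, tab in kda.items():
    write_result_table(tab, outdir / f"kda_{args.case}_{mod}.tsv")
    drivers = tab[tab["is_key_driver"]]
    if len(drivers):
        top = drivers.iloc[0]
        print(f"module {mod}: {len(drivers)} key drivers; top {top['node']} "
              f"(OR {top['odds_ratio']:.1f}, FDR {top['fdr']:.2g})")
    else:
        print(f"module {mod}: no key drivers at FDR<0.05")
print(f"tables written to {outdir}/")
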