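#!/usr/bin/env python
"""Distance decay and variation partitioning.

Per habitat: OLS distance-decay regressions of Bray-Curtis dissimilarity
on log10 geographic and environmental distance, 1000 x 21-sample bootstrap
slope distributions with Wilcoxon comparisons between habitats, and
variation partitioning of community dissimilarity between the PCNM
(geographic) and PCA (environmental) predictors with 999-permutation
fraction tests.

Writes results/tables/ddr.json, bootstrap_slopes.tsv, varpart.json.
"""
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from habspec import read_community_table, read_sample_frame
from habspec.beta import bray_curtis
from habspec.core_io import HABITATS
from habspec.ddr import (bootstrap_ddr_slopes, compare_slopes,
                         distance_decay_fit, test_fraction,
                         variation_partitioning)
from skbio import DistanceMatrix

DATA = Path("results/data")
OUT = Path("results/tables")
SEED = 1
N_BOOT, SUBSAMPLE, N_PERM = 1000, 21, 999

table = read_community_table(DATA / "table_rarefied.tsv")
samples = read_sample_frame(DATA / "samples.tsv").loc[table.sample_ids]
dm = bray_curtis(table)


def load_dm(name):
    frame = pd.read_csv(OUT / name, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=list(frame.index))


geo_dm, env_dm = load_dm("dist_geo.tsv"), load_dm("dist_env.tsv")
pcnm_cols = pd.read_csv(OUT / "pcnm.tsv", sep="\t", index_col=0)
env_scores = pd.read_csv(OUT / "env_scores.tsv", sep="\t", index_col=0)

rng = np.random.default_rng(SEED)
ddr, boots, slope_rows = {}, {}, []
for habitat in HABITATS:
    ids = list(samples.index[samples["habitat"] == habitat])
    sub_c = dm.filter(ids)
    for label, pred, offset in (("geographic", geo_dm.filter(ids), 1000.0),
                                ("environmental", env_dm.filter(ids), None)):
        fit = distance_decay_fit(sub_c, pred, offset=offset, predictor=label)
        ddr[f"{habitat}_{label}"] = vars(fit).copy()
        boot = bootstrap_ddr_slopes(sub_c, pred, n_boot=N_BOOT,
                                    subsample=SUBSAMPLE,
                                    seed=int(rng.integers(2 ** 31)),
                                    label=habitat, offset=offset)
        boots[(habitat, label)] = boot
        slope_rows.append(pd.DataFrame({"habitat": habitat, "predictor": label,
                                        "slope": boot.slopes}))
for label in ("geographic", "environmental"):
    for i, ha in enumerate(HABITATS):
        for hb in HABITATS[i + 1:]:
            p, larger = compare_slopes(boots[(ha, label)], boots[(hb, label)])
            ddr[f"wilcoxon_{label}_{ha}_vs_{hb}"] = {"p": p, "larger": larger}
pd.concat(slope_rows).to_csv(OUT / "bootstrap_slopes.tsv", sep="\t", index=False)
with open(OUT / "ddr.json", "w") as fh:
    json.dump(ddr, fh, indent=2, default=float)

varpart = {}
for habitat in HABITATS:
    ids = list(samples.index[samples["habitat"] == habitat])
    sub_c = dm.filter(ids)
    vp = variation_partitioning(sub_c, pcnm_cols.loc[ids], env_scores.loc[ids])
    _, p_geo = test_fraction(sub_c, pcnm_cols.loc[ids], env_scores.loc[ids],
                             n_perm=N_PERM, seed=int(rng.integers(2 ** 31)))
    _, p_env = test_fraction(sub_c, env_scores.loc[ids], pcnm_cols.loc[ids],
                             n_perm=N_PERM, seed=int(rng.integers(2 ** 31)))
    varpart[habitat] = {"pure_geo": vp.pure_geo, "shared": vp.shared,
                        "pure_env": vp.pure_env, "residual": vp.residual,
                        "p_pure_geo": p_geo, "p_pure_env": p_env}
with open(OUT / "varpart.json", "w") as fh:
    json.dump(varpart, fh, indent=2, default=float)

print("Geographic DDR slope (full fit) per habitat:")
for habitat in HABITATS:
    print(f"  {habitat:12s} slope = {ddr[f'{habitat}_geographic']['slope']:+.3f} "
          f"(R2 = {ddr[f'{habitat}_geographic']['r2']:.2f})")
w = ddr["wilcoxon_geographic_sediment_vs_gut_tissue"]
print(f"Bootstrap slopes sediment vs gut tissue: Wilcoxon p = {w['p']:.2e}, "
      f"larger in {w['larger']} — distance decay weakens with specificity.")
print("Variation partitioning (adjusted fractions):")
for habitat, v in varpart.items():
    print(f"  {habitat:12s} geo = {v['pure_geo']:+.3f} (p={v['p_pure_geo']:.3g}) "
          f"env = {v['pure_env']:+.3f} (p={v['p_pure_env']:.3g}) "
          f"shared = {v['shared']:+.3f} residual = {v['residual']:.3f}")
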