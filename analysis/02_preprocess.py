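#!/usr/bin/env python
"""Preprocess the raw count table: remove singletons and OTUs below 0.005%
relative abundance, rarefy every sample to 6000 reads (samples below that
depth are dropped), and reconcile table, tree, metadata, and environment.

Writes results/data/table_rarefied.tsv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from habspec import (align_inputs, filter_low_abundance, rarefy,
                     read_community_table, read_env_table, read_sample_frame,
                     read_tree)

DATA = Path("results/data")
SEED = 1

table = read_community_table(DATA / "table.tsv")
tree = read_tree(DATA / "tree.nwk")
samples = read_sample_frame(DATA / "samples.tsv")
env = read_env_table(DATA / "env.tsv")

n0 = table.shape
table = filter_low_abundance(table, min_rel_abund=5e-5)
n1 = table.shape
table = rarefy(table, depth=6000, seed=SEED)
bundle = align_inputs(table, tree, samples, env)
bundle.table.write_tsv(DATA / "table_rarefied.tsv")

print(f"Raw table: {n0[0]} samples x {n0[1]} OTUs")
print(f"After singleton/0.005% filter: {n1[1]} OTUs "
      f"({n0[1] - n1[1]} removed)")
print(f"After rarefaction to 6000: {bundle.table.shape[0]} samples x "
      f"{bundle.table.shape[1]} OTUs -> {DATA / 'table_rarefied.tsv'}")
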