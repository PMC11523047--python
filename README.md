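# habspec

Quantitative framework for measuring how **habitat specificity** modulates
bacterial biogeographic patterns and community assembly processes, built
around the natural gradient offered by deposit-feeding *Abatus* sea
urchins in the Southern Ocean: external **sediment** (least specific) →
ingested **gut content** → intestinal **gut tissue** (most specific).

The package is for microbial ecologists analysing multi-site,
multi-habitat 16S OTU surveys who want, in one tested toolkit:

* preprocessing: singleton / relative-abundance (<0.005%) filtering and
  seeded rarefaction to a common depth (6000 reads);
* alpha diversity (Shannon *H*, Faith PD) and Levins niche breadth
  *B<sub>j</sub>* = 1/Σ<sub>i</sub> p<sub>ij</sub>², normalized
  *B<sub>n</sub>* = (*B*−1)/(*N*−1), with Kruskal–Wallis + Dunn/Holm group
  comparisons;
* beta diversity (Bray–Curtis, binary Jaccard, unweighted UniFrac), PCoA,
  PERMANOVA with *R*² and Holm-adjusted pairwise contrasts, and the
  betadisper-style dispersion test;
* geographic/environmental predictors: WGS84 geodesic distances, PCNM
  spatial eigenfunctions (truncation at the maximum distance),
  centre-reduction, Pearson > 0.95 variable pruning, PCA, and the PC1–PC2
  environmental distance;
* distance–decay regressions (Bray–Curtis vs log₁₀ distance), a
  1000-resampling × 21-sample bootstrap slope comparison (Wilcoxon), and
  variation partitioning between geography and environment via db-RDA
  with Ezekiel-adjusted *R*² and 999-permutation fraction tests;
* null-model quantification of assembly processes: abundance-weighted
  βMNTD with a tip-shuffle null

  βNTI = (βMNTD<sub>obs</sub> − mean βMNTD<sub>null</sub>) / sd βMNTD<sub>null</sub>

  and the Bray–Curtis Raup–Crick index RC<sub>Bray</sub> ∈ [−1, 1], with
  the two-step classification: βNTI > 2 variable selection, βNTI < −2
  homogeneous selection; otherwise RC > 0.95 dispersal limitation,
  RC < −0.95 homogenizing dispersal, else ecological drift;
* a synthetic metacommunity generator that reproduces the study design
  (5 sites × 3 habitats, unbalanced replication, 200 samples) with a
  controlled habitat-specificity gradient, so every stage can be tested
  against ground truth.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
metacommunity (800-OTU pool, 200 samples, seed 1):

```sh
python analysis/01_simulate.py      # dataset -> results/data/
python analysis/02_preprocess.py    # filter + rarefy
python analysis/03_alpha_niche.py
python analysis/04_beta_structure.py
python analysis/05_geo_env.py
python analysis/06_ddr_varpart.py
python analysis/07_assembly.py
```

`03_alpha_niche.py` prints the specificity gradient:

```
Mean Shannon by habitat:
gut_content    3.56
gut_tissue     1.77
sediment       4.17
Kruskal-Wallis Shannon p = 8.94e-35
```

— diversity and niche breadth (mean Bn 0.335 → 0.081 → 0.063) fall from
sediment to gut tissue: gut habitats are poorer and more
specialist-dominated.  `04_beta_structure.py` shows site differentiation
weakening along the same gradient:

```
PERMANOVA site R^2 within each habitat (Bray-Curtis):
  sediment     R2 = 0.940 (p = 0.001)
  gut_content  R2 = 0.294 (p = 0.001)
  gut_tissue   R2 = 0.101 (p = 0.001)
```

`06_ddr_varpart.py` quantifies the biogeographic signal: the geographic
distance–decay slope is +0.133 in sediment versus +0.009 in gut tissue
(bootstrap Wilcoxon p ≈ 0), and variation partitioning attributes similar
pure fractions to geography (+0.385) and environment (+0.375) in
sediment, collapsing to near zero in gut tissue (residual 0.96).
`07_assembly.py` reports the process fractions: within sites, sediment
pairs are 98.5% homogenizing dispersal, while gut tissue pairs are
dominated by dispersal limitation and drift — the island-like behaviour
of host-associated habitats.

A `habspec` CLI wraps the same library (`habspec run --config run.yaml`,
plus `simulate`, `alpha`, `beta`, `geoenv` subcommands).

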