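"""Synthetic metacommunities with a controlled habitat-specificity gradient.

The generator emulates the study design this package analyses: five
Southern-Ocean sites, three habitats per site along a specificity gradient
(sediment -> gut content -> gut tissue), unbalanced replication, OTU counts
with lognormal abundance structure, phylogenetically conserved niche
optima, and a site-level environmental table containing a near-duplicate
variable pair to exercise correlation pruning.

The habitat gradient is expressed mechanistically:

* ``richness_scale`` — gut-like habitats subsample the OTU pool per sample
  (island-like colonization), lowering richness and niche breadth and
  creating dispersal limitation between hosts;
* ``selection_strength`` — a Gaussian filter on the mismatch between each
  OTU's (Brownian) niche optimum and the site environment; strong in
  sediment, weak in gut tissue, driving the site-differentiation gradient;
* ``dispersal_rate`` — mixing of each sample with the shared metacommunity
  pool;
* ``drift_intensity`` — Dirichlet overdispersion of per-sample relative
  abundances, the exchangeable noise signature that the Raup-Crick null
  reads as ecological drift.

A second generator, :func:`simulate_under_process`, emits community pairs
engineered for a single named assembly process and is the ground truth for
the process classifier.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .core_io import CommunityTable, HABITATS

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)

#: The five study sites: (latitude, longitude, depth_m, host species).
SITES = {
    "Patagonia": (-52.33138, -69.48625, 0.1, "A. cavernosus"),
    "Falkland": (-51.69607, -57.78576, 0.1, "A. cavernosus"),
    "SouthGeorgia": (-54.16200, -36.66400, 16.0, "A. agassizii"),
    "SouthShetland": (-62.21879, -58.95786, 2.0, "A. agassizii"),
    "Kerguelen": (-49.35370, 70.21910, 3.0, "A. cordatus"),
}

#: Replication per site x habitat (sediment, gut_content, gut_tissue),
#: mirroring the study's unbalanced design (200 samples in total).
DEFAULT_REPLICATION = {
    "Patagonia": (6, 37, 15),
    "Falkland": (5, 15, 12),
    "SouthGeorgia": (6, 7, 9),
    "SouthShetland": (6, 36, 20),
    "Kerguelen": (5, 15, 6),
}


@dataclass
class HabitatParams:
    richness_scale: float = 1.0       # fraction of the OTU pool reachable per sample
    selection_strength: float = 1.0   # 1/sigma^2-like weight on niche mismatch
    dispersal_rate: float = 0.2       # mixing with the metacommunity pool
    drift_intensity: float = 0.1      # Dirichlet overdispersion (larger = noisier)

    def __post_init__(self):
        if not 0 < self.richness_scale <= 1:
            raise ValueError("richness_scale must be in (0, 1]")
        if not 0 <= self.dispersal_rate <= 1:
            raise ValueError("dispersal_rate must be in [0, 1]")


#: Habitat defaults along the specificity gradient.  Sediment: full pool,
#: strong environmental selection, well-mixed, low drift.  Gut tissue:
#: narrow per-host pool, weak external selection, dispersal-limited, noisy.
#: drift_intensity is the inverse of the total Dirichlet concentration, so
#: 0.001 means per-sample compositions are nearly deterministic replicates
#: of the site pool, while 0.3 gives strong sample-to-sample lottery noise.
DEFAULT_HABITATS = {
    "sediment": HabitatParams(1.0, 1.5, 0.30, 0.001),
    "gut_content": HabitatParams(0.6, 0.7, 0.15, 0.02),
    "gut_tissue": HabitatParams(0.25, 0.3, 0.05, 0.3),
}


@dataclass
class Scenario:
    """Full description of one synthetic study."""
    n_otus: int = 1200
    depth: int = 6000
    env_axes: int = 2
    phylo_signal: float = 1.0          # Brownian trait variance per unit branch
    lognormal_sigma: float = 2.0       # metacommunity abundance spread (skewed,
                                       # so per-sample richness << pool size)
    seed: int = 0
    habitats: dict = field(default_factory=lambda: dict(DEFAULT_HABITATS))
    sites: dict = field(default_factory=lambda: dict(SITES))
    replication: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATION))
    env_decoys: bool = True

    def __post_init__(self):
        self.habitats = {
            name: (p if isinstance(p, HabitatParams) else HabitatParams(**p))
            for name, p in self.habitats.items()
        }
        self.sites = {k: tuple(v) for k, v in self.sites.items()}
        self.replication = {k: tuple(int(x) for x in v) for k, v in self.replication.items()}
        if set(self.replication) != set(self.sites):
            raise ValueError("replication and sites must cover the same site set")
        if any(min(v) < 1 for v in self.replication.values()):
            raise ValueError("replication counts must be >= 1")

    def scaled(self, **overrides) -> "Scenario":
        """Copy with selected fields replaced (used for scaled-down runs)."""
        d = self.to_dict()
        d.update(overrides)
        return Scenario(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["habitats"] = {k: asdict(v) if isinstance(v, HabitatParams) else dict(v)
                         for k, v in self.habitats.items()}
        d["sites"] = {k: list(v) for k, v in self.sites.items()}
        d["replication"] = {k: list(v) for k, v in self.replication.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""
    optima: pd.DataFrame          # OTU x env-axis niche optima (standardized)
    site_env: pd.DataFrame        # site x env-axis latent environment
    habitat_params: dict          # name -> HabitatParams
    base_abundance: pd.Series     # metacommunity relative abundances


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_taxa: int, seed: int | None = None) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with unit birth rate.

    Epoch durations are exponential with rate equal to the number of extant
    lineages; the expected root-to-tip depth is therefore sum_{k=2..n} 1/k.
    Tips are labelled ``OTU_0001`` ...
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    birth = {id(root): 0.0}
    t = 0.0
    # root split at time 0 into two lineages
    active = []
    for _ in range(2):
        child = TreeNode(length=0.0)
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode(length=0.0)
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / n_taxa)  # final epoch with n lineages
    for node in active:
        node.length = t - birth[id(node)]
    width = max(4, len(str(n_taxa)))
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU_{i + 1:0{width}d}"
    return root


def assign_niche_optima(tree: TreeNode, axes: int = 1, brownian_var: float = 1.0,
                        seed: int | None = None) -> pd.DataFrame:
    """Brownian-motion niche optima along the tree (root value 0).

    Sibling tips covary by ``brownian_var`` times their shared path length.
    Returns an OTU x axis DataFrame in tip order.
    """
    if brownian_var < 0:
        raise ValueError("brownian_var must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    for node in tree.preorder(include_self=True):
        parent = values.get(id(node.parent), np.zeros(axes)) if node.parent is not None \
            else np.zeros(axes)
        length = node.length or 0.0
        step = rng.normal(0.0, np.sqrt(brownian_var * length), size=axes) \
            if brownian_var * length > 0 else np.zeros(axes)
        values[id(node)] = parent + step
    tips = list(tree.tips())
    out = pd.DataFrame([values[id(t)] for t in tips],
                       index=[t.name for t in tips],
                       columns=[f"axis{i + 1}" for i in range(axes)])
    return out


# ---------------------------------------------------------------------------
# Metacommunity generator
# ---------------------------------------------------------------------------

def _site_environment(scenario: Scenario, rng: np.random.Generator) -> pd.DataFrame:
    """Latent per-site environment.  Axis 1 follows standardized latitude,
    giving the spatially structured gradient that species sorting converts
    into distance decay; remaining axes are independent standard normals."""
    sites = list(scenario.sites)
    lat = np.array([scenario.sites[s][0] for s in sites], dtype=float)
    ax1 = (lat - lat.mean()) / lat.std(ddof=1)
    cols = [ax1]
    for _ in range(scenario.env_axes - 1):
        cols.append(rng.normal(size=len(sites)))
    env = pd.DataFrame(np.column_stack(cols), index=sites,
                       columns=[f"axis{i + 1}" for i in range(scenario.env_axes)])
    return env


def _env_table(site_env: pd.DataFrame, rng: np.random.Generator,
               decoys: bool) -> pd.DataFrame:
    """Observable environmental table: the latent axes under measured-variable
    names, a >0.95-correlated decoy pair, and two noise variables."""
    env = pd.DataFrame(index=site_env.index)
    names = ["temperature", "salinity", "nitrate", "silicate"]
    for i, ax in enumerate(site_env.columns):
        env[names[i % len(names)] + ("" if i < len(names) else str(i))] = site_env[ax].to_numpy()
    if decoys:
        base = site_env.iloc[:, 0].to_numpy()
        env["chlorophyll_a"] = base + rng.normal(0.0, 0.02, size=len(base))
    env["ph"] = rng.normal(size=len(site_env))
    env["current_velocity"] = rng.normal(size=len(site_env))
    return env


def simulate_metacommunity(scenario: Scenario, tree: TreeNode, optima: pd.DataFrame
                           ) -> tuple[CommunityTable, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate counts, sample metadata, environmental table, and ground truth.

    Per sample the OTU weights are ``base_abundance x exp(-s * ||optimum -
    site_env||^2)``, optionally masked to a per-sample random subset of the
    pool (gut-like habitats), perturbed by Dirichlet drift noise, mixed with
    the metacommunity pool at the habitat's dispersal rate, and drawn
    multinomially at the configured depth.
    """
    tip_names = [t.name for t in tree.tips()]
    if list(optima.index) != tip_names:
        optima = optima.loc[tip_names]
    rng = np.random.default_rng(scenario.seed)
    S = len(tip_names)

    # standardized optima: selection_strength is in units of 1/trait-variance
    opt = optima.to_numpy()
    opt_std = (opt - opt.mean(axis=0)) / opt.std(axis=0, ddof=1)

    base = rng.lognormal(0.0, scenario.lognormal_sigma, size=S)
    base_rel = base / base.sum()

    site_env = _site_environment(scenario, rng)
    env_table = _env_table(site_env, rng, scenario.env_decoys)

    rows, meta = [], []
    for site in scenario.sites:
        lat, lon, depth_m, host = scenario.sites[site]
        e = site_env.loc[site].to_numpy()[: scenario.env_axes]
        for h_idx, habitat in enumerate(HABITATS):
            if habitat not in scenario.habitats:
                continue
            par = scenario.habitats[habitat]
            mismatch = ((opt_std[:, : scenario.env_axes] - e) ** 2).sum(axis=1)
            w_site = base_rel * np.exp(-par.selection_strength * mismatch)
            w_site = w_site / w_site.sum()
            n_rep = scenario.replication[site][h_idx]
            for rep in range(n_rep):
                w = w_site
                if par.richness_scale < 1.0:
                    keep = rng.random(S) < par.richness_scale
                    if not keep.any():
                        keep[rng.integers(S)] = True
                    w = np.where(keep, w, 0.0)
                    if w.sum() == 0:
                        w = np.where(keep, base_rel, 0.0)
                    w = w / w.sum()
                if par.drift_intensity > 0:
                    pos = w > 0
                    alpha = w[pos] / par.drift_intensity
                    q = np.zeros(S)
                    q[pos] = rng.dirichlet(np.maximum(alpha, 1e-8))
                else:
                    q = w
                p = (1.0 - par.dispersal_rate) * q + par.dispersal_rate * base_rel
                rows.append(rng.multinomial(scenario.depth, p / p.sum()))
                sample_id = f"{site}_{habitat}_{rep + 1:02d}"
                meta.append({
                    "sample_id": sample_id, "site": site, "habitat": habitat,
                    "host_species": "" if habitat == "sediment" else host,
                    "latitude": lat, "longitude": lon, "depth": depth_m,
                })
    samples = pd.DataFrame(meta).set_index("sample_id")
    counts = pd.DataFrame(np.array(rows), index=samples.index, columns=tip_names)
    table = CommunityTable(counts).drop_empty_otus()
    truth = GroundTruth(
        optima=pd.DataFrame(opt_std, index=tip_names, columns=optima.columns),
        site_env=site_env,
        habitat_params=dict(scenario.habitats),
        base_abundance=pd.Series(base_rel, index=tip_names),
    )
    return table, samples, env_table, truth


def simulate_dataset(scenario: Scenario):
    """Convenience wrapper: tree + optima + metacommunity from one seed."""
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_opt = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    tree = simulate_phylogeny(scenario.n_otus, seed=s_tree)
    optima = assign_niche_optima(tree, axes=scenario.env_axes,
                                 brownian_var=scenario.phylo_signal, seed=s_opt)
    table, samples, env, truth = simulate_metacommunity(scenario, tree, optima)
    return table, tree, samples, env, truth


# ---------------------------------------------------------------------------
# Single-process pair generator (classifier ground truth)
# ---------------------------------------------------------------------------

@dataclass
class ProcessParams:
    n_taxa: int = 400
    depth: int = 250
    selection_strength: float = 4.0   # strong Gaussian filter (1/trait-var units)
    optima_offset: float = 2.0        # +/- optimum (trait SD); extreme optima select
                                      # phylogenetic tails, i.e. conserved clades
    mixing: float = 0.75              # resampled-copy weight for homogenizing dispersal
    drift_depth: int = 250
    lognormal_sigma: float = 0.5
    brownian_var: float = 1.0


def simulate_under_process(process: str, n_pairs: int,
                           params: ProcessParams | None = None,
                           seed: int | None = None):
    """Community pairs engineered for one named assembly process.

    Returns ``(table, tree, pairs)`` where ``pairs`` lists ``(id_a, id_b)``
    tuples.  Constructions: homogeneous_selection = identical strong filter
    (admission to one conserved clade, the limit of perfect trait
    conservatism), independent draws; variable_selection = strong Gaussian
    filters at optima 4 trait SD apart (opposite phylogenetic tails);
    homogenizing_dispersal = one community plus a heavily resampled
    copy; dispersal_limitation = disjoint halves of the pool; drift =
    independent unfiltered draws from the shared pool at moderate depth.
    """
    if process not in PROCESSES:
        raise ValueError(f"unknown process {process!r}; expected one of {PROCESSES}")
    params = params or ProcessParams()
    rng = np.random.default_rng(seed)
    tree = simulate_phylogeny(params.n_taxa, seed=int(rng.integers(2 ** 31)))
    optima = assign_niche_optima(tree, axes=1, brownian_var=params.brownian_var,
                                 seed=int(rng.integers(2 ** 31)))
    tip_names = list(optima.index)
    opt = optima.to_numpy()[:, 0]
    opt = (opt - opt.mean()) / opt.std(ddof=1)
    S = params.n_taxa
    base = rng.lognormal(0.0, params.lognormal_sigma, size=S)
    base_rel = base / base.sum()

    def filtered(env_value):
        w = base_rel * np.exp(-params.selection_strength * (opt - env_value) ** 2)
        return w / w.sum()

    if process == "homogeneous_selection":
        # the identical strong filter is a phylogenetically conserved niche:
        # admission to one internal clade (richness between ~10% and ~35% of
        # the pool), the limiting case of perfect trait conservatism
        tip_index = {name: i for i, name in enumerate(tip_names)}
        candidates = []
        for node in tree.non_tips():
            size = sum(1 for _ in node.tips())
            if params.n_taxa * 0.10 <= size <= params.n_taxa * 0.35:
                candidates.append(node)
        if not candidates:  # tiny trees: nearest-to-quarter clade
            nodes = [(abs(sum(1 for _ in nd.tips()) - 0.25 * S), nd)
                     for nd in tree.non_tips()]
            candidates = [min(nodes, key=lambda x: x[0])[1]]
        clade = candidates[rng.integers(len(candidates))]
        clade_mask = np.zeros(S, dtype=bool)
        for t in clade.tips():
            clade_mask[tip_index[t.name]] = True
        p_clade = np.where(clade_mask, base_rel, 0.0)
        p_clade = p_clade / p_clade.sum()

    rows, ids, pairs = [], [], []
    for k in range(n_pairs):
        id_a, id_b = f"pair{k + 1:03d}_a", f"pair{k + 1:03d}_b"
        if process == "homogeneous_selection":
            # per-sample colonization lottery within the selected clade:
            # species turnover between replicates stays phylogenetically
            # shallow, which is what distinguishes homogeneous selection
            # from simple community copying
            qa = rng.dirichlet(np.where(clade_mask, 1.0, 1e-9))
            qb = rng.dirichlet(np.where(clade_mask, 1.0, 1e-9))
            a = rng.multinomial(params.depth, qa / qa.sum())
            b = rng.multinomial(params.depth, qb / qb.sum())
        elif process == "variable_selection":
            a = rng.multinomial(params.depth, filtered(-params.optima_offset))
            b = rng.multinomial(params.depth, filtered(+params.optima_offset))
        elif process == "homogenizing_dispersal":
            a = rng.multinomial(params.depth, base_rel)
            mix = params.mixing * (a / a.sum()) + (1 - params.mixing) * base_rel
            b = rng.multinomial(params.depth, mix)
        elif process == "dispersal_limitation":
            perm = rng.permutation(S)
            half_a, half_b = perm[: S // 2], perm[S // 2:]
            pa = np.zeros(S); pa[half_a] = base_rel[half_a]
            pb = np.zeros(S); pb[half_b] = base_rel[half_b]
            a = rng.multinomial(params.depth, pa / pa.sum())
            b = rng.multinomial(params.depth, pb / pb.sum())
        else:  # drift
            a = rng.multinomial(params.drift_depth, base_rel)
            b = rng.multinomial(params.drift_depth, base_rel)
        rows += [a, b]
        ids += [id_a, id_b]
        pairs.append((id_a, id_b))
    counts = pd.DataFrame(np.array(rows).reshape(len(ids), S) if rows else
                          np.empty((0, S), dtype=int), index=ids, columns=tip_names)
    if n_pairs == 0:
        return counts, tree, pairs
    table = CommunityTable(counts)
    return table, tree, pairs
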