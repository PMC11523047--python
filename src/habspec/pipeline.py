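"""End-to-end orchestration: filter -> rarefy -> alpha/niche -> beta ->
geo-env predictors -> DDR/varpart -> assembly processes, from one config.

Seeds propagate deterministically: each stochastic stage draws its seed
from the master seed via a fixed named counter (``_STAGE_SEEDS``), so
adding a stage never shifts the streams of existing stages.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha as alpha_mod
from . import assembly as asm
from . import beta as beta_mod
from . import core_io, ddr as ddr_mod, geo as geo_mod
from . import synthetic
from .core_io import CommunityTable

logger = logging.getLogger("habspec")

__version__ = "0.1.0"

_STAGE_SEEDS = {
    "rarefy": 1,
    "permanova": 2,
    "permdisp": 3,
    "ddr_bootstrap": 4,
    "varpart": 5,
    "assembly_bnti": 6,
    "assembly_rc": 7,
}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    table: str = ""
    tree: str = ""
    metadata: str = ""
    env: str = ""
    out_dir: str = "results/run"
    depth: int = 6000
    min_rel_abund: float = 5e-5
    metrics: tuple = ("braycurtis", "jaccard", "unifrac")
    n_perm: int = 999
    n_boot: int = 1000
    subsample: int = 21
    n_null: int = 999
    env_axes: int = 2
    pcnm_axes: int = 3
    seed: int = 0
    run_assembly: bool = True
    run_ddr: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        for label in ("table", "tree", "metadata", "env"):
            path = getattr(self, label)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{label} input not found: {path!r}")


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _write_dm(dm, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


def _dumps(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in dependency order; deterministic given the
    master seed.  Outputs are written as TSV/JSON under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    t_all = time.time()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                report.stage_seconds[name] = round(time.time() - self.t0, 3)
                if exc is not None:
                    report.warnings.append(f"stage {name} failed: {exc}")
                    report.write(out / "report.json")
                return False
        return _Timer()

    # ------------------------------------------------------------------ io
    with stage("load"):
        table = core_io.read_community_table(config.table)
        tree = core_io.read_tree(config.tree)
        samples = core_io.read_sample_frame(config.metadata)
        env = core_io.read_env_table(config.env)

    with stage("preprocess"):
        table = core_io.filter_low_abundance(table, config.min_rel_abund)
        table = core_io.rarefy(table, depth=config.depth,
                               seed=stage_seed(config.seed, "rarefy"))
        bundle = core_io.align_inputs(table, tree, samples, env)
        table, tree, samples, env = bundle.table, bundle.tree, bundle.samples, bundle.env
        table.write_tsv(out / "table_rarefied.tsv")
        report.outputs["table_rarefied"] = str(out / "table_rarefied.tsv")

    habitats = [h for h in core_io.HABITATS if h in set(samples["habitat"])]

    # --------------------------------------------------------------- alpha
    with stage("alpha"):
        adf = pd.DataFrame({
            "shannon": alpha_mod.shannon_per_sample(table),
            "faith_pd": alpha_mod.faith_pd_per_sample(table, tree),
        })
        adf.join(samples[["site", "habitat"]]).to_csv(out / "alpha.tsv", sep="\t")
        report.outputs["alpha"] = str(out / "alpha.tsv")

        breadth_rows = []
        for hab in habitats:
            ids = samples.index[samples["habitat"] == hab]
            sub = table.select_samples(ids).drop_empty_otus()
            res = alpha_mod.levins_breadth(sub)
            b = res.breadth.copy()
            b["habitat"] = hab
            breadth_rows.append(b)
        breadth = pd.concat(breadth_rows)
        breadth.to_csv(out / "levins.tsv", sep="\t")
        report.outputs["levins"] = str(out / "levins.tsv")

        tests = {
            "shannon_by_habitat": _group_test(adf["shannon"], samples["habitat"]),
            "faith_pd_by_habitat": _group_test(adf["faith_pd"], samples["habitat"]),
            "levins_bn_by_habitat": _group_test(
                breadth["Bn"].to_numpy(), breadth["habitat"].to_numpy()),
        }
        _dumps(tests, out / "alpha_tests.json")
        report.outputs["alpha_tests"] = str(out / "alpha_tests.json")

    # ---------------------------------------------------------------- beta
    with stage("beta"):
        dms = {}
        for metric in config.metrics:
            if metric == "braycurtis":
                dms[metric] = beta_mod.bray_curtis(table)
            elif metric == "jaccard":
                dms[metric] = beta_mod.jaccard_binary(table)
            elif metric == "unifrac":
                dms[metric] = beta_mod.unweighted_unifrac(table, tree)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            _write_dm(dms[metric], out / f"dist_{metric}.tsv")
            report.outputs[f"dist_{metric}"] = str(out / f"dist_{metric}.tsv")

        stats = {}
        rng = np.random.default_rng(stage_seed(config.seed, "permanova"))
        for metric, dm in dms.items():
            entry = {"habitat_all": _perm_entry(beta_mod.permanova(
                dm, samples["habitat"], n_perm=config.n_perm,
                seed=int(rng.integers(2 ** 31)), term="habitat"))}
            for hab in habitats:
                ids = samples.index[samples["habitat"] == hab]
                sub = dm.filter(ids)
                entry[f"site_within_{hab}"] = _perm_entry(beta_mod.permanova(
                    sub, samples.loc[list(sub.ids), "site"], n_perm=config.n_perm,
                    seed=int(rng.integers(2 ** 31)), term=f"site|{hab}"))
            stats[metric] = entry
        _dumps(stats, out / "permanova.json")
        report.outputs["permanova"] = str(out / "permanova.json")

        disp = beta_mod.permdisp(dms[next(iter(dms))], samples["habitat"],
                                 n_perm=config.n_perm,
                                 seed=stage_seed(config.seed, "permdisp"))
        _dumps({"statistic": disp.statistic, "pvalue": disp.pvalue,
                "group_means": disp.group_means.to_dict()}, out / "permdisp.json")
        report.outputs["permdisp"] = str(out / "permdisp.json")

        ordin = beta_mod.pcoa(dms[next(iter(dms))])
        ordin.coordinates.iloc[:, :4].to_csv(out / "pcoa.tsv", sep="\t")
        report.outputs["pcoa"] = str(out / "pcoa.tsv")

    # -------------------------------------------------------------- geoenv
    with stage("geoenv"):
        geo_dm = geo_mod.sample_geodesic_matrix(samples)
        _write_dm(geo_dm, out / "dist_geo.tsv")
        sites = samples[["site", "latitude", "longitude"]].drop_duplicates("site").set_index("site")
        site_geo = geo_mod.geodesic_distance_matrix(sites)
        basis = geo_mod.pcnm(site_geo)
        pcnm_sample = basis.vectors.loc[samples["site"]].iloc[:, :config.pcnm_axes]
        pcnm_sample.index = samples.index
        pcnm_sample.to_csv(out / "pcnm.tsv", sep="\t")

        env_std = geo_mod.standardize_env(env)
        env_pruned, dropped = geo_mod.prune_correlated(env_std)
        pca = geo_mod.env_pca(env_pruned)
        env_dm = geo_mod.env_distance(pca, n_axes=min(config.env_axes, pca.scores.shape[1]),
                                      site_of_sample=samples["site"])
        _write_dm(env_dm, out / "dist_env.tsv")
        env_scores = pca.scores.loc[samples["site"]].iloc[:, :config.env_axes]
        env_scores.index = samples.index
        env_scores.to_csv(out / "env_scores.tsv", sep="\t")
        _dumps({"pruned": dropped,
                "proportion_explained": list(pca.proportion_explained)},
               out / "env_pca.json")
        for key in ("dist_geo", "pcnm", "dist_env", "env_scores", "env_pca"):
            report.outputs[key] = str(out / f"{key.replace('dist_', 'dist_')}.tsv"
                                      if not key.endswith("pca") else out / "env_pca.json")

    # ----------------------------------------------------------------- ddr
    if config.run_ddr:
        with stage("ddr_varpart"):
            comm = dms["braycurtis"]
            ddr_out = {}
            slope_frames = []
            rngb = np.random.default_rng(stage_seed(config.seed, "ddr_bootstrap"))
            boots = {}
            for hab in habitats:
                ids = list(samples.index[samples["habitat"] == hab])
                sub_c = comm.filter(ids)
                for pred_label, pred_dm, offset in (
                        ("geographic", geo_dm.filter(ids), 1000.0),
                        ("environmental", env_dm.filter(ids), None)):
                    fit = ddr_mod.distance_decay_fit(sub_c, pred_dm, offset=offset,
                                                     predictor=pred_label)
                    ddr_out[f"{hab}_{pred_label}"] = vars(fit).copy()
                    n_sub = min(config.subsample, len(ids) - 1)
                    boot = ddr_mod.bootstrap_ddr_slopes(
                        sub_c, pred_dm, n_boot=config.n_boot, subsample=n_sub,
                        seed=int(rngb.integers(2 ** 31)), label=f"{hab}_{pred_label}",
                        offset=offset)
                    boots[(hab, pred_label)] = boot
                    slope_frames.append(pd.DataFrame({
                        "habitat": hab, "predictor": pred_label, "slope": boot.slopes}))
            for pred_label in ("geographic", "environmental"):
                for i, ha in enumerate(habitats):
                    for hb in habitats[i + 1:]:
                        p, larger = ddr_mod.compare_slopes(boots[(ha, pred_label)],
                                                           boots[(hb, pred_label)])
                        ddr_out[f"wilcoxon_{pred_label}_{ha}_vs_{hb}"] = {
                            "pvalue": p, "larger": larger}
            pd.concat(slope_frames).to_csv(out / "bootstrap_slopes.tsv", sep="\t", index=False)
            _dumps(ddr_out, out / "ddr.json")
            report.outputs["ddr"] = str(out / "ddr.json")

            vp_out = {}
            rngv = np.random.default_rng(stage_seed(config.seed, "varpart"))
            for hab in habitats:
                ids = list(samples.index[samples["habitat"] == hab])
                sub_c = comm.filter(ids)
                xg = pcnm_sample.loc[ids]
                xe = env_scores.loc[ids]
                vp = ddr_mod.variation_partitioning(sub_c, xg, xe)
                f_geo, p_geo = ddr_mod.test_fraction(sub_c, xg, xe, n_perm=config.n_perm,
                                                     seed=int(rngv.integers(2 ** 31)))
                f_env, p_env = ddr_mod.test_fraction(sub_c, xe, xg, n_perm=config.n_perm,
                                                     seed=int(rngv.integers(2 ** 31)))
                vp_out[hab] = {"pure_geo": vp.pure_geo, "shared": vp.shared,
                               "pure_env": vp.pure_env, "residual": vp.residual,
                               "adj_r2": vp.adj_r2,
                               "p_pure_geo": p_geo, "p_pure_env": p_env}
            _dumps(vp_out, out / "varpart.json")
            report.outputs["varpart"] = str(out / "varpart.json")

    # ------------------------------------------------------------ assembly
    if config.run_assembly:
        with stage("assembly"):
            all_cls = []
            for i, hab in enumerate(habitats):
                ids = list(samples.index[samples["habitat"] == hab])
                sub = table.select_samples(ids).drop_empty_otus()
                bnti = asm.beta_nti(sub, tree, n_null=config.n_null,
                                    seed=stage_seed(config.seed, "assembly_bnti") + i)
                rc = asm.raup_crick_bray(sub, n_null=config.n_null,
                                         seed=stage_seed(config.seed, "assembly_rc") + i)
                all_cls.append(asm.classify_processes(bnti, rc))
            cls = pd.concat(all_cls, ignore_index=True)
            cls.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
            summary = asm.summarize_processes(cls, samples)
            summary.to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
            report.outputs["assembly_pairs"] = str(out / "assembly_pairs.tsv")
            report.outputs["assembly_summary"] = str(out / "assembly_summary.tsv")

    report.stage_seconds["total"] = round(time.time() - t_all, 3)
    report.write(out / "report.json")
    return report


def _group_test(values, groups) -> dict:
    res = alpha_mod.kruskal_dunn(np.asarray(values, dtype=float), np.asarray(groups))
    return {"H": res.statistic, "p": res.pvalue,
            "pairwise": res.pairwise.to_dict(orient="records")}


def _perm_entry(res) -> dict:
    return {"pseudo_f": res.statistic, "r2": res.r2, "p": res.pvalue,
            "n_perm": res.n_permutations}


def make_fixture(out_dir, seed: int = 0, scenario: synthetic.Scenario | None = None):
    """Write a small synthetic dataset (table/tree/metadata/env + ground
    truth) in the exact formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = synthetic.Scenario(
            n_otus=150, depth=1000, seed=seed,
            replication={k: (3, 3, 3) for k in synthetic.SITES},
        )
    table, tree, samples, env, truth = synthetic.simulate_dataset(scenario)
    table.write_tsv(out / "table.tsv")
    core_io.write_tree(tree, out / "tree.nwk")
    samples.to_csv(out / "samples.tsv", sep="\t")
    env.to_csv(out / "env.tsv", sep="\t")
    truth.optima.to_csv(out / "truth_optima.tsv", sep="\t")
    truth.site_env.to_csv(out / "truth_site_env.tsv", sep="\t")
    scenario.to_yaml(out / "scenario.yaml")
    return {name: str(out / name) for name in
            ("table.tsv", "tree.nwk", "samples.tsv", "env.tsv", "scenario.yaml")}
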