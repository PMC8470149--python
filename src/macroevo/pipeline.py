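"""Study orchestration: synthetic or user data through the full analysis.

Stages: prune -> preparation (midpoints, imputation, contrasts, GLS size
correction, phylogenetic PCA) -> ancestral-state paintings -> 11-scenario
fits per variable per tree -> comparison table -> disparity/MDI ->
half-life table -> optional bootstrap power test between the top two models.
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

from . import __version__
from .disparity import mdi_test
from .gauss_models import (
    ModelConfig,
    SCENARIO_ORDER,
    build_scenarios,
    compare_scenarios,
    half_life,
    stationary_variance,
)
from .mk_asr import MkModel, fit_mk, marginal_asr, ml_states
from .power import pmc_test
from .synthetic_data import (
    SimulationConfig,
    simulate_mk_states,
    simulate_posterior_sample,
    simulate_species_table,
    simulate_traits,
    simulate_yule_tree,
)
from .trait_prep import (
    gls_residuals,
    iterative_impute,
    phylo_pca,
    pic_correlation,
    pvr_eigenvectors,
)
from .trees import (
    PhyloTree,
    RegimePainting,
    paint_from_node_states,
    parse_newick,
    prune_to_taxa,
    single_state_painting,
    write_newick,
)
from .gauss_models import ModelParams

log = logging.getLogger("macroevo.pipeline")

ANALYSIS_VARIABLES = [
    "plant_size",
    "leaf_size_pPC1",
    "flower_size_pPC2",
    "SLA",
    "altitudinal_pPC1",
    "latitudinal_pPC2",
]


@dataclass
class StudyConfig:
    outdir: str = "study_out"
    seed: int = 0
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    paths: dict | None = None
    slice_age: float = 2.6
    root_mode: str = "fixed"
    er_free_post_sigma: bool = False
    n_posterior_use: int = 20
    mdi_nsim: int = 200
    power_nsim: int = 200
    k_eigenvectors: int = 10
    imputer: str = "ridge"
    ntree: int = 100
    run_power: bool = True

    def __post_init__(self):
        if (self.simulation is None) == (self.paths is None):
            raise ValueError("exactly one of simulation/paths must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        paths = raw.pop("paths", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        elif paths is None:
            sim = SimulationConfig()
        return cls(simulation=sim, paths=paths, **raw)


@dataclass
class StudyData:
    tree: PhyloTree
    posterior: list[PhyloTree]
    ranges: pd.DataFrame
    climate: pd.DataFrame
    sla: pd.Series
    habitat: dict[str, str]
    geo: dict[str, str]
    clade_tips: set[str]


def _pick_clade(tree: PhyloTree, target_frac: float, rng) -> set[str]:
    tipsets = tree.tip_sets()
    target = target_frac * tree.n_tips
    best, best_err = None, np.inf
    for node in tree.nodes:
        if node.is_tip or node is tree.root:
            continue
        size = len(tipsets[node.id])
        err = abs(size - target)
        if err < best_err:
            best, best_err = node, err
    return {tree.tips[i].label for i in tipsets[best.id]}


def generate_study(sim: SimulationConfig) -> StudyData:
    """A complete synthetic dataset with the study's shapes."""
    seed = sim.seed
    tree = simulate_yule_tree(sim.n_tips, sim.birth_rate, sim.target_height, seed=seed)
    posterior = simulate_posterior_sample(tree, sim.n_posterior, sim.jitter_sd,
                                          seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    habitat, _, habitat_paint = simulate_mk_states(
        tree, MkModel.er(["UMF", "LMF"], sim.mk_rate_habitat), "UMF", seed=seed + 3
    )
    geo, _, _ = simulate_mk_states(
        tree, MkModel.er(["NA", "AHZ", "CA"], sim.mk_rate_geo), "NA", seed=seed + 4
    )
    clade_tips = _pick_clade(tree, 0.35, rng)
    clade_paint = paint_from_node_states(
        tree,
        {t: ("clade" if t in clade_tips else "bg") for t in tree.taxa},
        _clade_node_states(tree, clade_tips),
    )

    size = pd.Series(simulate_traits(
        tree, ModelConfig("BM", "BM1"), ModelParams(sigma2=0.05, x0=7.0), seed=seed + 5
    ))
    oum_clade = ModelConfig("OU", "OUM_Clade", painting=clade_paint)
    bmm_clade = ModelConfig("BM", "BMM_Clade", painting=clade_paint)
    raw = {
        "plant_height": size,
        "leaf_length": pd.Series(simulate_traits(
            tree, oum_clade,
            ModelParams(sigma2=0.3, alpha=1.0, theta={"bg": 5.0, "clade": 6.5}),
            seed=seed + 6)),
        "leaf_width": pd.Series(simulate_traits(
            tree, oum_clade,
            ModelParams(sigma2=0.3, alpha=1.0, theta={"bg": 3.5, "clade": 5.0}),
            seed=seed + 7)),
        "calyx_width": pd.Series(simulate_traits(
            tree, ModelConfig("BM", "BM1"), ModelParams(sigma2=0.04, x0=2.5),
            seed=seed + 8)),
        "corolla_width": pd.Series(simulate_traits(
            tree, bmm_clade,
            ModelParams(sigma2={"bg": 0.03, "clade": 0.15}, x0=3.2), seed=seed + 9)),
        "corolla_length": pd.Series(simulate_traits(
            tree, bmm_clade,
            ModelParams(sigma2={"bg": 0.03, "clade": 0.15}, x0=3.8), seed=seed + 10)),
    }
    # induce size correlations as in real morphologies
    morph = pd.DataFrame(raw)
    for col in morph.columns:
        if col != "plant_height":
            morph[col] = morph[col] + 0.3 * (size - 7.0)

    n = tree.n_tips
    n_morph = max(8, int(round(n * 55 / 63)))
    n_climate = max(8, int(round(n * 62 / 63)))
    n_sla = max(8, int(round(n * 31 / 63)))
    taxa = np.array(tree.taxa)
    morph_sp = sorted(rng.choice(taxa, n_morph, replace=False))
    climate_sp = sorted(rng.choice(taxa, n_climate, replace=False))
    sla_sp = sorted(rng.choice(taxa, n_sla, replace=False))

    ranges, climate = simulate_species_table(
        tree, morph.loc[morph_sp], missing_rate=sim.missing_rate,
        range_spread=sim.range_spread, seed=seed + 11,
    )
    climate = climate.reindex(climate_sp).dropna(how="all")
    sla_full = pd.Series(simulate_traits(
        tree, ModelConfig("OU", "OUM_Regime", painting=habitat_paint),
        ModelParams(sigma2=0.2, alpha=1.0, theta={"UMF": 2.3, "LMF": 3.0}),
        seed=seed + 12))
    sla = sla_full.loc[sla_sp]
    return StudyData(tree, posterior, ranges, climate, sla, habitat, geo, clade_tips)


def load_study(paths: dict) -> StudyData:
    tree = parse_newick(Path(paths["tree"]).read_text())
    posterior = [
        parse_newick(line)
        for line in Path(paths["posterior"]).read_text().splitlines()
        if line.strip()
    ]
    ranges = pd.read_csv(paths["ranges"], index_col="species")
    climate = pd.read_csv(paths["climate"], index_col="species")
    sla = pd.read_csv(paths["sla"], index_col="species").iloc[:, 0]
    habitat = pd.read_csv(paths["habitat"], index_col="species").iloc[:, 0].to_dict()
    geo = pd.read_csv(paths["geo"], index_col="species").iloc[:, 0].to_dict()
    clade = set(pd.read_csv(paths["clade"], index_col="species").query("in_clade == 1").index)
    return StudyData(tree, posterior, ranges, climate, sla, habitat, geo, clade)


def write_study(data: StudyData, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(write_newick(data.tree) + "\n")
    (outdir / "posterior.nwk").write_text(
        "".join(write_newick(t) + "\n" for t in data.posterior)
    )
    data.ranges.to_csv(outdir / "ranges.csv")
    data.climate.to_csv(outdir / "climate.csv")
    data.sla.rename("sla").rename_axis("species").to_csv(outdir / "sla.csv")
    pd.Series(data.habitat, name="habitat").rename_axis("species").to_csv(
        outdir / "habitat.csv")
    pd.Series(data.geo, name="region").rename_axis("species").to_csv(outdir / "geo.csv")
    pd.Series(
        {t: int(t in data.clade_tips) for t in data.tree.taxa}, name="in_clade"
    ).rename_axis("species").to_csv(outdir / "clade.csv")


# -- paintings ---------------------------------------------------------


def _clade_node_states(tree: PhyloTree, clade_tips: set[str]) -> dict[int, str]:
    tipsets = tree.tip_sets()
    states = {}
    for node in tree.nodes:
        if node.is_tip:
            continue
        tips = {tree.tips[i].label for i in tipsets[node.id]}
        states[node.id] = "clade" if tips <= clade_tips else "bg"
    return states


def asr_painting(tree: PhyloTree, tip_states: dict[str, str],
                 flavor: str = "ER") -> RegimePainting:
    """Fit an Mk model, reconstruct internal states by ML, paint child-stems."""
    present = {t: tip_states[t] for t in tree.taxa}
    if len(set(present.values())) < 2:
        return single_state_painting(tree, next(iter(set(present.values()))))
    try:
        model = fit_mk(tree, present, flavor=flavor)
    except ValueError:
        model = fit_mk(tree, present, flavor="ER")
        log.info("SYM fit failed; fell back to ER rates")
    asr = marginal_asr(tree, present, model)
    nodes = ml_states(asr, tree)
    return paint_from_node_states(tree, present, nodes)


def clade_painting(tree: PhyloTree, clade_tips: set[str]) -> RegimePainting:
    present = clade_tips & set(tree.taxa)
    return paint_from_node_states(
        tree,
        {t: ("clade" if t in present else "bg") for t in tree.taxa},
        _clade_node_states(tree, present),
    )


# -- the full study ----------------------------------------------------


def run_study(config: StudyConfig) -> Path:
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage_t = time.time()

    if config.simulation is not None:
        data = generate_study(config.simulation)
        write_study(data, outdir / "data")
    else:
        data = load_study(config.paths)
    timings["data"] = time.time() - stage_t

    # -- preparation ---------------------------------------------------
    stage_t = time.time()
    morph_sp = [s for s in data.tree.taxa if s in data.ranges.index]
    dropped = sorted(set(data.tree.taxa) - set(morph_sp))
    if dropped:
        log.warning("dropping %d species without morphological data", len(dropped))
    morph_tree = prune_to_taxa(data.tree, morph_sp)
    log_ranges = np.log(data.ranges.loc[morph_tree.taxa])
    eig, _ = pvr_eigenvectors(morph_tree, k=min(config.k_eigenvectors,
                                                morph_tree.n_tips - 1))
    imp = iterative_impute(log_ranges, eig, regressor=config.imputer,
                           ntree=config.ntree, seed=config.seed + 100)
    # midpoints straight off the imputed log matrix (imputed minima may
    # slightly exceed maxima; the midpoint is well defined either way)
    traits = sorted({c[:-4] for c in imp.completed.columns if c.endswith("_min")})
    means = pd.DataFrame(
        {t: 0.5 * (imp.completed[f"{t}_min"] + imp.completed[f"{t}_max"])
         for t in traits})
    means.to_csv(outdir / "trait_means.csv")

    size = means["plant_height"]
    pic_rows = []
    for trait in means.columns:
        if trait == "plant_height":
            continue
        r, p = pic_correlation(morph_tree, size, means[trait])
        pic_rows.append({"trait": trait, "r": r, "p": p})
    pd.DataFrame(pic_rows).to_csv(outdir / "pic_correlations.csv", index=False)

    resid = pd.DataFrame(
        {t: gls_residuals(morph_tree, means[t], size) for t in means.columns
         if t != "plant_height"}
    )
    morph_ppca = phylo_pca(morph_tree, resid, mode="cov")
    morph_ppca.loadings_table().to_csv(outdir / "ppca_morphology.csv")

    climate_sp = [s for s in data.tree.taxa if s in data.climate.index]
    climate_tree = prune_to_taxa(data.tree, climate_sp)
    clim_ppca = phylo_pca(climate_tree, data.climate.loc[climate_tree.taxa], mode="cor")
    clim_ppca.loadings_table().to_csv(outdir / "ppca_climate.csv")

    variables: dict[str, pd.Series] = {
        "plant_size": size,
        "leaf_size_pPC1": morph_ppca.scores["pPC1"],
        "flower_size_pPC2": morph_ppca.scores["pPC2"],
        "SLA": data.sla.dropna(),
        "altitudinal_pPC1": clim_ppca.scores["pPC1"],
        "latitudinal_pPC2": clim_ppca.scores["pPC2"],
    }
    pd.DataFrame({"nrmse": [imp.nrmse], "n_iter": [imp.n_iter]}).to_csv(
        outdir / "imputation.csv", index=False)
    timings["prep"] = time.time() - stage_t

    # -- model comparison per variable ---------------------------------
    stage_t = time.time()
    sample = data.posterior[: config.n_posterior_use]
    comparison: dict[str, dict[str, str]] = {}
    halflife_rows = []
    (outdir / "dtt").mkdir(exist_ok=True)
    (outdir / "power").mkdir(exist_ok=True)

    for vi, (var, series) in enumerate(variables.items()):
        keep = [s for s in data.tree.taxa if s in series.index]
        ref = prune_to_taxa(data.tree, keep)
        trees = [ref] + [prune_to_taxa(t, keep) for t in sample]
        traits = series.loc[ref.taxa].to_dict()

        def builder(tree: PhyloTree) -> list[ModelConfig]:
            return build_scenarios(
                tree,
                asr_painting(tree, data.habitat, flavor="ER"),
                clade_painting(tree, data.clade_tips),
                asr_painting(tree, data.geo, flavor="SYM"),
                slice_age=config.slice_age,
                er_free_post_sigma=config.er_free_post_sigma,
            )

        table = compare_scenarios(trees, traits, builder, root_mode=config.root_mode)
        cells = {}
        for i, s in enumerate(table.scenarios):
            cell = f"{table.reference_delta[i]:.2f}"
            if table.quantiles is not None:
                q = table.quantiles[i]
                cell += f"({q[0]:.2f};{q[1]:.2f};{q[2]:.2f})"
            cells[s] = cell
        comparison[var] = cells

        fits = {f.config.scenario_name: f for f in table.reference_fits}
        ou1 = fits["OU1"]
        s2 = ou1.params.sigma2 if not isinstance(ou1.params.sigma2, dict) else \
            next(iter(ou1.params.sigma2.values()))
        row = {"trait": var}
        # alpha at the search floor means the pull is indistinguishable from 0
        if ou1.params.alpha > 1e-8:
            row["halflife_OU1"] = half_life(ou1.params.alpha)
            row["stationary_variance_OU1"] = stationary_variance(s2, ou1.params.alpha)
        else:
            row["halflife_OU1"] = np.inf
            row["stationary_variance_OU1"] = np.nan
        best = table.best_scenario()
        if best.startswith("OUM"):
            bf = fits[best]
            bs2 = bf.params.sigma2 if not isinstance(bf.params.sigma2, dict) else \
                next(iter(bf.params.sigma2.values()))
            row["best_OUM"] = best
            row["halflife_OUM"] = half_life(bf.params.alpha)
            row["stationary_variance_OUM"] = stationary_variance(bs2, bf.params.alpha)
        else:
            row["best_OUM"] = "NA"
            row["halflife_OUM"] = np.nan
            row["stationary_variance_OUM"] = np.nan
        halflife_rows.append(row)

        dtt = mdi_test(ref, traits, nsim=config.mdi_nsim,
                       seed=config.seed + 200 + vi)
        (outdir / "dtt" / f"{var}.tsv").write_text(dtt.to_tsv())
        (outdir / "dtt" / f"{var}.json").write_text(dtt.summary_json())

        if config.run_power:
            order = np.argsort([f.aicc for f in table.reference_fits])
            best_cfg = table.reference_fits[order[0]].config
            second_cfg = table.reference_fits[order[1]].config
            try:
                pr = pmc_test(ref, traits, model1=second_cfg, model2=best_cfg,
                              nsim=config.power_nsim, seed=config.seed + 300 + vi,
                              root_mode=config.root_mode)
                payload = json.loads(pr.to_json())
                payload["model1"] = second_cfg.scenario_name
                payload["model2"] = best_cfg.scenario_name
                (outdir / "power" / f"{var}.json").write_text(json.dumps(payload))
            except RuntimeError as exc:
                (outdir / "power" / f"{var}.json").write_text(
                    json.dumps({"error": str(exc)}))

    pd.DataFrame(comparison).loc[SCENARIO_ORDER].rename_axis("model").to_csv(
        outdir / "comparison.csv")
    pd.DataFrame(halflife_rows).to_csv(outdir / "halflife.csv", index=False)
    timings["models"] = time.time() - stage_t

    manifest = {
        "macroevo": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    return d
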