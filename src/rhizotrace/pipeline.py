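"""Config-driven end-to-end runs with a hashed output manifest.

A run config (YAML or dict) names a global seed, the stages to execute
and per-stage parameter maps.  Stages run in dependency order —
simulate first, then the analysis stages on its outputs — and every file
written is sha256-hashed into ``manifest.json``, so two runs of the same
config can be compared byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import commstats as cs
from . import imprint as imp
from . import integrate as integ
from . import io as rio
from . import metmod as mm
from . import netkey as nk
from . import synthio
from .errors import InvalidConfigError

__all__ = ["RunConfig", "run_pipeline", "DEMO_CONFIG"]

STAGES = ("simulate", "imprint", "commstats", "assembly", "network",
          "metmod", "integrate")

DEMO_CONFIG = {
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "n_taxa": 60,
        "n_groups": 4,
        "n_samples_per_group": 5,
        "n_metabolites": 100,
        "image_shape": [96, 96],
        "sequencing_depth": 5000,
    },
    "imprint": {"fraction_above_mean": 0.25, "block": 8, "n_perm": 199},
    "commstats": {"n_perm": 199},
    "assembly": {"n_null": 199},
    "network": {"r_threshold": 0.6, "p_threshold": 0.05},
    "metmod": {"min_module_size": 28},
    "integrate": {"boruta_rounds": 20, "boruta_trees": 100},
}


@dataclass
class RunConfig:
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        seed = int(mapping.pop("seed", 0))
        stages = list(mapping.pop("stages", STAGES))
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise InvalidConfigError(f"unknown stages: {unknown}")
        bad_keys = [k for k in mapping if k not in STAGES]
        if bad_keys:
            raise InvalidConfigError(f"unknown config keys: {bad_keys}")
        return cls(seed=seed, stages=stages, params=mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def _write_yaml(obj, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def run_pipeline(config, outdir) -> dict[str, str]:
    """Execute the configured stages; return {relative path: sha256}."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_mapping(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path):
        written.append(path)

    needs_sim = [s for s in config.stages if s != "simulate"]
    if needs_sim and "simulate" not in config.stages:
        raise InvalidConfigError(
            "analysis stages require the simulate stage (no external inputs "
            "are configured)"
        )

    sim_cfg = synthio.SimulationConfig(
        seed=config.seed,
        **{k: (tuple(v) if isinstance(v, list) else v)
           for k, v in config.stage_params("simulate").items()},
    )

    # --- simulate ---------------------------------------------------------
    imp_sim = synthio.simulate_imprint(sim_cfg)
    com_sim = synthio.simulate_community(sim_cfg)
    met_sim = synthio.simulate_metabolome(sim_cfg)
    int_sim = synthio.simulate_integrated(sim_cfg, n_samples=200)

    sim_dir = outdir / "simulated"
    sim_dir.mkdir(exist_ok=True)
    rio.write_gray_image(imp_sim.gray, sim_dir / "imprint_gray.tiff")
    rio.write_mask(imp_sim.root_mask, sim_dir / "root_mask.png")
    rio.write_calibration_series(imp_sim.calibration, sim_dir / "calibration.tsv")
    rio.write_community_table(com_sim.table, sim_dir / "community.tsv")
    rio.write_tree(com_sim.tree, sim_dir / "tree.nwk")
    com_sim.groups.to_frame().to_csv(sim_dir / "groups.tsv", sep="\t",
                                     index_label="sample_id")
    rio.write_table(met_sim.matrix, sim_dir / "metabolites.tsv")
    rio.write_table(int_sim.data, sim_dir / "integrated.tsv")
    _write_yaml(
        {
            "regime": com_sim.regime,
            "environments": {k: float(v)
                             for k, v in com_sim.environments.items()},
            "metabolite_modules": {
                k: int(v) for k, v in met_sim.module_labels.items()
            },
            "path_coefficients": {
                f"{a}->{b}": float(v)
                for (a, b), v in int_sim.truth_coefficients.items()
            },
            "vpa_truth": {k: float(v) for k, v in int_sim.truth_vpa.items()},
        },
        sim_dir / "truth.yaml",
    )
    for p in sorted(sim_dir.iterdir()):
        emit(p)

    results: dict[str, object] = {"config": config}

    # --- imprint ----------------------------------------------------------
    if "imprint" in config.stages:
        p = config.stage_params("imprint")
        d = outdir / "imprint"
        d.mkdir(exist_ok=True)
        curve = imp.fit_calibration(imp_sim.calibration, kind="linear")
        conc = imp.invert_to_concentration(imp_sim.gray, curve)
        hs = imp.detect_hotspots(imp_sim.gray,
                                 p.get("fraction_above_mean", 0.25))
        r, pv = imp.colocalization(
            imp_sim.root_mask, imp_sim.gray, block=p.get("block", 8),
            n_perm=p.get("n_perm", 999), seed=config.seed,
        )
        pd.DataFrame(
            [{
                "hotspot_percent": hs.hotspot_percent,
                "threshold_value": hs.threshold_value,
                "mean_level": hs.mean_level,
                "calibration_r2": curve.fit_r2,
                "mean_concentration_mg_kg": float(conc.pixels.mean()),
                "colocalization_r": r,
                "colocalization_p": pv,
            }]
        ).to_csv(d / "hotspot_summary.tsv", sep="\t", index=False)
        imp.render_pseudocolor(imp_sim.gray, d / "pseudocolor.png",
                               p.get("fraction_above_mean", 0.25))
        results["imprint"] = {"hotspot_percent": hs.hotspot_percent,
                              "colocalization_r": r}
        for f in sorted(d.iterdir()):
            emit(f)

    # --- commstats --------------------------------------------------------
    if "commstats" in config.stages:
        p = config.stage_params("commstats")
        d = outdir / "commstats"
        d.mkdir(exist_ok=True)
        alpha = cs.alpha_diversity(com_sim.table)
        rio.write_table(alpha, d / "alpha_diversity.tsv")
        bc = cs.bray_curtis(com_sim.table)
        rio.write_table(bc, d / "bray_curtis.tsv")
        ord_res = cs.nmds(bc, seed=config.seed)
        rio.write_table(ord_res.coordinates, d / "nmds.tsv")
        r, pv = cs.anosim(bc, com_sim.groups, n_perm=p.get("n_perm", 999),
                          seed=config.seed)
        pd.DataFrame([{"R": r, "p": pv, "stress": ord_res.stress}]).to_csv(
            d / "anosim.tsv", sep="\t", index=False)
        g1, g2 = com_sim.groups.unique()[:2]
        sim_tab = cs.simper(com_sim.table, com_sim.groups, pair=(g1, g2))
        sim_tab.to_csv(d / f"simper_{g1}_vs_{g2}.tsv", sep="\t", index=False)
        results["commstats"] = {"anosim_R": r, "anosim_p": pv,
                                "stress": ord_res.stress}
        for f in sorted(d.iterdir()):
            emit(f)

    # --- assembly ---------------------------------------------------------
    if "assembly" in config.stages:
        p = config.stage_params("assembly")
        d = outdir / "assembly"
        d.mkdir(exist_ok=True)
        n_null = p.get("n_null", 999)
        z = asm.beta_nti(com_sim.table, com_sim.tree, n_null=n_null,
                         seed=config.seed)
        rc = asm.raup_crick_bray(com_sim.table, n_null=n_null,
                                 seed=config.seed)
        res = asm.classify_processes(z, rc)
        res.pair_process.to_csv(d / "pairs.tsv", sep="\t", index=False)
        res.process_fractions.rename("fraction").to_frame().to_csv(
            d / "process_fractions.tsv", sep="\t", index_label="process")
        results["assembly"] = res
        for f in sorted(d.iterdir()):
            emit(f)

    # --- network ----------------------------------------------------------
    if "network" in config.stages:
        p = config.stage_params("network")
        d = outdir / "network"
        d.mkdir(exist_ok=True)
        net = nk.build_network(
            com_sim.table,
            r_threshold=p.get("r_threshold", 0.6),
            p_threshold=p.get("p_threshold", 0.05),
            min_prevalence=p.get("min_prevalence", 0.5),
        )
        net.edges.to_csv(d / "edges.tsv", sep="\t", index=False)
        stats_ = nk.topology_stats(net, seed=config.seed)
        pd.DataFrame([vars(stats_)]).to_csv(d / "topology.tsv", sep="\t",
                                            index=False)
        if net.graph.number_of_edges() > 0:
            ranking = nk.keystone_rank(net, top_k=p.get("top_k", 9))
            ranking.scores.to_csv(d / "keystones.tsv", sep="\t", index=False)
            results["network"] = {"stats": stats_, "keystones": ranking.keystones}
        for f in sorted(d.iterdir()):
            emit(f)

    # --- metmod -----------------------------------------------------------
    if "metmod" in config.stages:
        p = config.stage_params("metmod")
        d = outdir / "metmod"
        d.mkdir(exist_ok=True)
        logm = mm.preprocess(met_sim.matrix)
        power, diag = mm.pick_soft_threshold(logm)
        _, _, diss = mm.adjacency_tom(logm, power)
        modules = mm.detect_modules(diss, p.get("min_module_size", 28))
        profile, merged = mm.eigenmetabolites(logm, modules)
        trait_tab = mm.module_trait(profile, met_sim.trait)
        hubs = mm.hub_metabolites(logm, merged, profile)
        merged.labels.to_frame().to_csv(d / "modules.tsv", sep="\t",
                                        index_label="metabolite")
        rio.write_table(profile.scores, d / "eigenmetabolites.tsv")
        trait_tab.to_csv(d / "module_trait.tsv", sep="\t", index=False)
        hubs.to_csv(d / "hub_metabolites.tsv", sep="\t", index=False)
        diag.to_csv(d / "soft_threshold.tsv", sep="\t", index=False)
        results["metmod"] = {"power": power, "modules": merged,
                             "module_trait": trait_tab}
        for f in sorted(d.iterdir()):
            emit(f)

    # --- integrate --------------------------------------------------------
    if "integrate" in config.stages:
        p = config.stage_params("integrate")
        d = outdir / "integrate"
        d.mkdir(exist_ok=True)
        data = int_sim.data
        blocks = data[["metabolite", "microbe", "soil"]]
        screen = integ.spearman_screen(
            blocks, data[["Cd"]], r_min=p.get("r_min", 0.6),
            p_max=p.get("p_max", 0.05),
        )
        screen.edges.to_csv(d / "spearman_screen.tsv", sep="\t", index=False)
        rng = np.random.default_rng([config.seed, 99])
        noise = pd.DataFrame(
            rng.normal(size=(len(data), 3)), index=data.index,
            columns=["noise_1", "noise_2", "noise_3"],
        )
        boruta = integ.boruta_screen(
            pd.concat([blocks, noise], axis=1), data["Cd"],
            n_rounds=p.get("boruta_rounds", 100),
            n_trees=p.get("boruta_trees", 500),
            importance=p.get("boruta_importance", "impurity"),
            seed=config.seed,
        )
        boruta.decisions.to_csv(d / "boruta.tsv", sep="\t", index=False)
        dag = [list(e) for e in int_sim.truth_coefficients]
        model = integ.fit_path_model(data, dag)
        model.paths.to_csv(d / "path_coefficients.tsv", sep="\t", index=False)
        model.effects.to_csv(d / "path_effects.tsv", sep="\t", index=False)
        vpa = integ.variance_partition(
            data["Cd"], data[["metabolite"]], data[["microbe"]],
            data[["soil"]], names=("metabolite", "microbe", "soil"),
        )
        with open(d / "vpa.json", "w") as fh:
            json.dump({"fractions": vpa.fractions, "total_r2": vpa.total_r2,
                       "residual": vpa.residual}, fh, indent=2, sort_keys=True)
        results["integrate"] = {"model": model, "vpa": vpa, "boruta": boruta}
        for f in sorted(d.iterdir()):
            emit(f)

    manifest = {
        str(f.relative_to(outdir)): rio.file_sha256(f) for f in written
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
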