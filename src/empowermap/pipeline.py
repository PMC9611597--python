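"""End-to-end reproducible run: simulate -> cluster -> map -> fit -> compare.

Every stochastic stage receives its own integer seed derived from the
master seed through a fixed splitting rule (recorded in the run log), so
partial stages can be re-run independently and the whole pipeline is a
pure function of (config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import default_initial_modes, fit_kmodes
from .design import build_design
from .diagnostics import gelman_rubin, geweke_report
from .io import write_graph, write_ground_truth, write_survey
from .spatial import psu_effect_morans, psu_proportions
from .star import (
    McmcSettings,
    PriorConfig,
    mcmc_fit,
    psu_effect_medians,
    region_effect_medians,
    summarize_posterior,
)
from .synthetic import (
    CovariateConfig,
    GroundTruth,
    build_region_lattice,
    simulate_survey,
)

_STAGES = ("simulate", "cluster", "fit_full", "fit_null", "diagnose")


@dataclass
class RunConfig:
    """Settings for one pipeline run; round-trips losslessly through YAML."""

    seed: int = 0
    lattice_rows: int = 4
    lattice_cols: int = 4
    psus_per_region: int = 4
    respondents_per_psu: tuple[int, int] = (15, 100)
    beta1: list = field(default_factory=lambda: [0.2, 0.3, 0.2, 0.5, 0.0, 0.1, 0.2, 0.4])
    beta2: list = field(default_factory=lambda: [-0.2, -0.3, -0.2, -0.5, 0.0, -0.1, -0.2, -0.4])
    psu_sd: float = 0.3
    region_sd: float = 0.8
    epsilon: float = 0.05
    n_categories: int = 3
    kmodes_max_iter: int = 100
    iterations: int = 4000
    burn_in: int = 1000
    thinning: int = 10
    n_chains: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "respondents_per_psu" in raw:
            raw["respondents_per_psu"] = tuple(raw["respondents_per_psu"])
        return cls(**raw)


def stage_seeds(master_seed: int, n: int = len(_STAGES)) -> dict:
    """Fixed master-seed -> per-stage seed derivation (SeedSequence spawning)."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n)
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) or 1
        for name, child in zip(_STAGES, children)
    }


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages, persisting every declared artifact under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    log: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        graph = build_region_lattice(config.lattice_rows, config.lattice_cols)
        write_graph(graph, out / "regions.gra")
        truth = GroundTruth(
            beta=np.vstack([config.beta1, config.beta2]),
            psu_sd=config.psu_sd,
            region_sd=config.region_sd,
            epsilon=config.epsilon,
        )
        survey, truth = simulate_survey(
            graph,
            truth,
            psus_per_region=config.psus_per_region,
            respondents_per_psu_range=tuple(config.respondents_per_psu),
            covariate_config=CovariateConfig(),
            seed=seeds["simulate"],
            lattice_shape=(config.lattice_rows, config.lattice_cols),
            n_categories=config.n_categories,
        )
        write_survey(survey, out / "survey.csv")
        write_ground_truth(truth, out / "truth.json")
        log["stages"][stage] = {"n_respondents": len(survey),
                                "seconds": round(time.time() - t0, 3)}

        stage = "cluster"
        t0 = time.time()
        assignment = fit_kmodes(
            survey, default_initial_modes(), max_iter=config.kmodes_max_iter,
            seed=seeds["cluster"],
        )
        pd.DataFrame(
            {"resp_id": survey["resp_id"], "category": assignment.labels}
        ).to_csv(out / "labels.csv", index=False)
        pd.DataFrame([m._asdict() for m in assignment.modes]).to_csv(
            out / "modes.csv", index=False
        )
        summary = psu_proportions(assignment, survey)
        summary.to_csv(out / "map.csv", index=False,
                       columns=[c for c in summary.columns if c != "has_dominant"])
        log["stages"][stage] = {
            "cost": assignment.cost, "n_iter": assignment.n_iter,
            "sizes": assignment.sizes().tolist(),
            "seconds": round(time.time() - t0, 3),
        }

        design = build_design(survey, assignment.labels)
        settings = McmcSettings(config.iterations, config.burn_in, config.thinning)
        fits = {}
        for model, spatial in (("full", True), ("null", False)):
            stage = f"fit_{model}"
            t0 = time.time()
            fit = mcmc_fit(
                design, graph=graph if spatial else None,
                priors=PriorConfig(), settings=settings, spatial=spatial,
                seed=seeds[stage], n_chains=config.n_chains,
            )
            fits[model] = fit
            fdir = out / f"fitdir_{model}"
            fdir.mkdir(exist_ok=True)
            summarize_posterior(fit).to_csv(fdir / "summary.csv", index=False)
            dic = fit.dic()
            pd.DataFrame(
                [{"model": model, "Dbar": dic.dbar, "Dhat": dic.dhat,
                  "pD": dic.p_d, "DIC": dic.dic}]
            ).to_csv(fdir / "dic.csv", index=False)
            if spatial:
                region_effect_medians(fit).to_csv(
                    fdir / "region_effects.csv", index=False
                )
            psu_effect_medians(fit).to_csv(fdir / "psu_effects.csv", index=False)
            np.savetxt(fdir / "deviance.csv", fit.pooled("deviance"),
                       header="deviance", comments="")
            log["stages"][stage] = {
                "DIC": dic.dic, "pD": dic.p_d,
                "seconds": round(time.time() - t0, 3),
            }

        # comparisons consume only persisted artifacts
        # keep_default_na: the literal model name "null" must stay a string
        dic_rows = [
            pd.read_csv(out / f"fitdir_{m}" / "dic.csv", keep_default_na=False)
            for m in ("full", "null")
        ]
        pd.concat(dic_rows).to_csv(out / "dic_comparison.csv", index=False)

        morans_rows = []
        for model in ("full", "null"):
            eff = pd.read_csv(out / f"fitdir_{model}" / "psu_effects.csv")
            merged = eff.merge(
                pd.read_csv(out / "map.csv")[["psu", "region"]], on="psu"
            )
            for k in (1, 2):
                i_val = psu_effect_morans(
                    merged[f"b_k{k}"].to_numpy(), merged["region"].to_numpy(),
                    graph, mode="region_median",
                )
                morans_rows.append(
                    {"model": model, "category": k,
                     "weights": "region_median_adjacency", "morans_i": i_val}
                )
        pd.DataFrame(morans_rows).to_csv(out / "morans_comparison.csv", index=False)

        stage = "diagnose"
        t0 = time.time()
        diag_frames = []
        for model, fit in fits.items():
            gw = geweke_report({"beta": fit.chains["beta"]})
            gw.insert(0, "model", model)
            if fit.n_chains >= 2:
                gr = gelman_rubin({"beta": fit.chains["beta"]})
                gw = gw.merge(gr.table, on="parameter", how="left")
            diag_frames.append(gw)
        pd.concat(diag_frames).to_csv(out / "diagnostics.csv", index=False)
        log["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    except Exception as err:
        log["failed_stage"] = stage
        log["error"] = repr(err)
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out
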