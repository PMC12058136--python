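"""End-to-end pipeline: simulate/load -> network fit -> patterns -> centralities -> regression.

Gender stratification is a first-class axis: by default separate networks
are fitted for men and women. Pattern identities are only comparable
between genders under a shared partition, so stratified runs additionally
fit a pooled network whose community structure defines the patterns used
for the gender prevalence comparison and for the complex-phenotype
regression outcome.

Every source of randomness descends from one integer seed recorded in the
run manifest; identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bridging import ModelSpec, fit_logistic, regression_report
from .cohort import Cohort, filter_multimorbid, read_cohort, summarize_prevalence
from .mgm import DiseaseNetworkModel, MGMConfig
from .netmetrics import compute_centralities, detect_communities, rank_bridges
from .network import write_network
from .patterns import assign_patterns, compare_prevalence
from .simulate import (
    DemographicSpec,
    PlantedDesign,
    build_planted_ising,
    default_design,
    simulate_cohort,
)


@dataclass
class PipelineConfig:
    input: str | None = None            # cohort CSV; exactly one of input/simulation
    simulation: dict | None = None      # {'n': int, 'design': 'default'|dict, 'designs': {M:..., F:...}}
    outdir: str = "morbnet_run"
    seed: int = 0
    stratify: bool = True
    min_diseases: int = 2
    min_count: int = 2
    metric: str = "betweenness"
    top_k_bridges: int = 3
    predictors: tuple[str, ...] | None = None
    mgm: dict = field(default_factory=dict)
    weighted_centralities: bool = True

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulation is None):
            raise ValueError("exactly one of input / simulation must be given")

    def mgm_config(self, seed: int) -> MGMConfig:
        return MGMConfig(seed=seed, **self.mgm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("predictors") is not None:
            d["predictors"] = list(d["predictors"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("predictors") is not None:
            raw["predictors"] = tuple(raw["predictors"])
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _resolve_design(entry) -> PlantedDesign:
    if entry in (None, "default"):
        return default_design()
    if isinstance(entry, PlantedDesign):
        return entry
    return PlantedDesign.from_dict(entry)


def _simulate(config: PipelineConfig, seed: int) -> Cohort:
    sim = dict(config.simulation)
    n = int(sim.get("n", 1592))
    spec = DemographicSpec()
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    if "designs" in sim:
        import pandas as pd

        halves = []
        catalog = None
        for k, gender in enumerate(("M", "F")):
            design = _resolve_design(sim["designs"][gender])
            params = build_planted_ising(design)
            n_g = int(sim.get(f"n_{gender}", n // 2))
            half = simulate_cohort(
                design, n=n_g, seed=int(seeds[k]), spec=spec, params=params,
                gender=gender, id_prefix=f"{gender}",
            )
            catalog = half.catalog
            halves.append(half.df)
        df = pd.concat(halves, ignore_index=True)
        return Cohort(df, catalog)
    design = _resolve_design(sim.get("design"))
    params = build_planted_ising(design)
    return simulate_cohort(design, n=n, seed=int(seeds[0]), spec=spec, params=params)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest dict (also written to outdir).

    On a stage failure the partial outputs are preserved, the manifest
    records the failed stage, and the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": [],
        "failed_stage": None,
    }
    t_all = time.perf_counter()
    stage = "load"

    def log(stage_name, **info):
        manifest["stages"].append({"stage": stage_name, **info})

    try:
        t0 = time.perf_counter()
        if config.input is not None:
            cohort = read_cohort(config.input)
        else:
            cohort = _simulate(config, seed=config.seed)
        cohort = filter_multimorbid(cohort, config.min_diseases)
        cohort.to_csv(outdir / "cohort.csv")
        summarize_prevalence(cohort, stratify="gender").to_csv(
            outdir / "prevalence.csv", index=False
        )
        log(stage, n=cohort.n, p=len(cohort.catalog),
            seconds=round(time.perf_counter() - t0, 3))

        strata: list[tuple[str, Cohort]] = []
        if config.stratify:
            for level in ("M", "F"):
                sub = cohort.stratum("gender", level)
                if sub.n:
                    strata.append((level, sub))
        strata.append(("pooled", cohort))

        mgm_seeds = np.random.SeedSequence(config.seed + 1).generate_state(
            len(strata)
        ) % (2**31)
        partitions = {}
        networks = {}
        for k, (level, sub) in enumerate(strata):
            stage = f"mgm[{level}]"
            t0 = time.perf_counter()
            sdir = outdir / level
            sdir.mkdir(exist_ok=True)
            res = DiseaseNetworkModel(sub, config.mgm_config(int(mgm_seeds[k]))).fit()
            write_network(res.network, sdir / "network.graphml", "graphml")
            write_network(res.network, sdir / "edges.tsv", "edgelist_tsv")
            res.summary().to_csv(sdir / "fit_report.csv", index=False)
            networks[level] = res.network
            log(stage, n=sub.n, edges=res.network.n_edges,
                seconds=round(time.perf_counter() - t0, 3))

            stage = f"analyze[{level}]"
            t0 = time.perf_counter()
            part = detect_communities(res.network)
            part.to_json(sdir / "partition.json")
            partitions[level] = part
            cent = compute_centralities(
                res.network, weighted=config.weighted_centralities
            )
            cent.to_csv(sdir / "centrality.csv")
            rank_bridges(cent, metric=config.metric).to_csv(sdir / "bridges.csv")
            log(stage, Q=part.Q, communities=part.n_communities,
                seconds=round(time.perf_counter() - t0, 3))

            stage = f"assign[{level}]"
            t0 = time.perf_counter()
            assignment = assign_patterns(sub, part, min_count=config.min_count)
            assignment.to_csv(sdir / "assignment.csv")
            log(stage, complex_rate=float(assignment.complex_flags.mean()),
                seconds=round(time.perf_counter() - t0, 3))

        stage = "compare"
        t0 = time.perf_counter()
        pooled_assignment = assign_patterns(
            cohort, partitions["pooled"], min_count=config.min_count
        )
        comparison = compare_prevalence(pooled_assignment, strata="gender")
        comparison.to_csv(outdir / "comparison.csv", index=False)
        log(stage, seconds=round(time.perf_counter() - t0, 3))

        stage = "regress"
        t0 = time.perf_counter()
        if config.predictors is not None:
            predictors = tuple(config.predictors)
        else:
            cent = compute_centralities(
                networks["pooled"], weighted=config.weighted_centralities
            )
            ranked = rank_bridges(cent, metric=config.metric,
                                  top_k=config.top_k_bridges)
            predictors = tuple(ranked.index)
        spec = ModelSpec(predictors=predictors)
        fits = fit_logistic(cohort, pooled_assignment.complex_flags.astype(float), spec)
        regression_report(fits).to_csv(outdir / "regression.csv", index=False)
        log(stage, predictors=list(predictors),
            seconds=round(time.perf_counter() - t0, 3))
    except Exception:
        manifest["failed_stage"] = stage
        manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
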