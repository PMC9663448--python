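"""End-to-end orchestration: dataset -> matrices -> models -> reports.

A pipeline run reads (or simulates) a dataset directory, validates and
filters the networks, builds the requested predictor distance matrices and
the three response matrices (species turnover, interaction dissimilarity,
structural dissimilarity), fits one GAM-MRM per configured model, and writes
tables, JSON results, and a reproducibility manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .betadiv import pairwise_beta, shared_pairs_subset
from .distmat import DistanceMatrix, build_predictor_matrices
from .gammrm import GammrmResult, ModelSpec, deviance_partition, gam_mrm, jackknife_by_study
from .netio import InteractionMatrix, drop_zero_margins, read_metadata, read_network, validate_network, write_validation_reports
from .structure import structural_dissimilarity, structural_profile
from .synthdata import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = (
    "ecoregion", "biome", "footprint", "spatial", "elevation",
    "hours", "months", "years", "intensity", "methods",
)

RESPONSES = ("beta_s", "beta_wn", "structural")


@dataclass(frozen=True)
class PipelineConfig:
    dataset: str | None = None  # directory with networks/ and metadata.csv
    simulate: SimulationConfig | None = None
    out_dir: str = "results/pipeline"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    models: Mapping[str, dict] = field(default_factory=dict)  # response -> spec dict
    n_perm: int = 1000
    basis_dim: int = 10
    seed: int = 0
    fast_perm: bool = False
    min_species_per_guild: int = 3
    min_total_species: int = 0
    partition_variables: tuple[str, ...] = ()
    jackknife: bool = False
    rewiring: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        for key in ("predictors", "partition_variables"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if (self.dataset is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'dataset' or 'simulate'")
        available = set(self.predictors)
        models = dict(self.models) or default_models(self.predictors)
        for resp, spec in models.items():
            if resp not in RESPONSES:
                raise ValueError(f"unknown response {resp!r}")
            used = tuple(spec.get("parametric", ())) + tuple(spec.get("smooth", ()))
            undefined = [u for u in used if u not in available]
            if undefined:
                raise ValueError(
                    f"model {resp!r} references undefined predictor recipes {undefined}"
                )
        for v in self.partition_variables:
            if all(
                v not in tuple(s.get("parametric", ())) + tuple(s.get("smooth", ()))
                for s in models.values()
            ):
                raise ValueError(f"partition variable {v!r} not used by any model")


def default_models(predictors: Sequence[str]) -> dict[str, dict]:
    parametric = [p for p in ("ecoregion", "biome") if p in predictors]
    smooth = [p for p in predictors if p not in ("ecoregion", "biome")]
    spec = {"parametric": parametric, "smooth": smooth}
    return {resp: dict(spec) for resp in RESPONSES}


def load_dataset(directory: str | Path) -> tuple[list[InteractionMatrix], pd.DataFrame]:
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.csv")
    nets = []
    for path in sorted((directory / "networks").glob("*.csv")):
        nets.append(read_network(path))
    return nets, meta


def prepare_networks(
    nets: Sequence[InteractionMatrix],
    metadata: pd.DataFrame,
    min_species_per_guild: int = 3,
    min_total_species: int = 0,
) -> tuple[list[InteractionMatrix], pd.DataFrame, pd.DataFrame]:
    """Clean, validate and filter networks; align metadata to survivors."""
    cleaned = [drop_zero_margins(n) for n in nets]
    reports = [
        validate_network(n, min_species_per_guild, min_total_species) for n in cleaned
    ]
    passed_ids = {r.network_id for r in reports if r.passed}
    kept = [n for n in cleaned if n.network_id in passed_ids]
    meta = metadata[metadata["network_id"].isin(passed_ids)].reset_index(drop=True)
    missing_meta = [n.network_id for n in kept if n.network_id not in set(meta["network_id"])]
    if missing_meta:
        logger.warning("networks without metadata excluded: %s", missing_meta)
        kept = [n for n in kept if n.network_id in set(meta["network_id"])]
    report_frame = write_validation_reports(reports)
    return kept, meta, report_frame


def build_responses(
    nets: Sequence[InteractionMatrix], seed: int = 0
) -> dict[str, DistanceMatrix]:
    profiles = [structural_profile(n, seed=seed) for n in nets]
    return {
        "beta_s": pairwise_beta(nets, "species"),
        "beta_wn": pairwise_beta(nets, "interaction"),
        "structural": structural_dissimilarity(profiles),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        ds = simulate_dataset(config.simulate)
        nets, meta = list(ds.networks), ds.metadata
    else:
        nets, meta = load_dataset(config.dataset)
    nets, meta, reports = prepare_networks(
        nets, meta, config.min_species_per_guild, config.min_total_species
    )
    reports.to_csv(out / "validation.tsv", sep="\t", index=False)
    logger.info("retained %d networks", len(nets))

    predictors = build_predictor_matrices(meta, include=config.predictors)
    responses = build_responses(nets, seed=config.seed)
    for name, dm in {**predictors, **responses}.items():
        dm.to_csv(out / f"dist_{name}.csv")

    models = dict(config.models) or default_models(config.predictors)
    bundle: dict = {"models": {}, "n_networks": len(nets)}
    for resp, raw in models.items():
        spec = ModelSpec(
            response=resp,
            parametric_terms=tuple(raw.get("parametric", ())),
            smooth_terms=tuple(raw.get("smooth", ())),
            basis_dim=config.basis_dim,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        data = {resp: responses[resp], **predictors}
        result = gam_mrm(data, spec, fast_perm=config.fast_perm)
        frame = result.to_frame()
        frame.to_csv(out / f"model_{resp}.tsv", sep="\t", index=False)
        bundle["models"][resp] = _result_dict(result)
        if config.partition_variables:
            usable = [
                v for v in config.partition_variables
                if v in spec.parametric_terms + spec.smooth_terms
            ]
            part = deviance_partition(data, spec, usable)
            part_json = {
                "variables": list(part.variables_of_interest),
                "components": {
                    "+".join(sorted(k)): v for k, v in part.components.items()
                },
                "full_deviance_explained": part.full_deviance_explained,
                "attributable": part.attributable,
            }
            (out / f"partition_{resp}.json").write_text(json.dumps(part_json, indent=1))
            bundle["models"][resp]["partition"] = part_json
    if config.jackknife:
        def rebuild(sub_nets, sub_meta):
            preds = build_predictor_matrices(sub_meta, include=config.predictors)
            resp = build_responses(sub_nets, seed=config.seed)
            return {**preds, **resp}

        for resp, raw in models.items():
            spec = ModelSpec(
                response=resp,
                parametric_terms=tuple(raw.get("parametric", ())),
                smooth_terms=tuple(raw.get("smooth", ())),
                basis_dim=config.basis_dim,
                n_perm=0,
                seed=config.seed,
            )
            jk = jackknife_by_study(nets, meta, rebuild, spec)
            jk.to_csv(out / f"jackknife_{resp}.tsv", sep="\t", index=False)
    if config.rewiring:
        rew = shared_pairs_subset(nets, predictors)
        rew.to_csv(out / "rewiring_pairs.tsv", sep="\t", index=False)
        bundle["n_rewiring_pairs"] = int(len(rew))

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "results.json").write_text(json.dumps(bundle, indent=1, default=str))
    return bundle


def _result_dict(result: GammrmResult) -> dict:
    return {
        "response": result.response,
        "intercept": {
            "estimate": result.intercept_estimate,
            "t": result.intercept_t,
            "p_perm": result.intercept_p_perm,
        },
        "terms": [dataclasses.asdict(t) for t in result.terms],
        "deviance_explained": result.deviance_explained,
        "n_pairs": result.n_pairs,
        "n_perm": result.n_perm,
        "seed": result.seed,
    }


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["models"] = {k: dict(v) for k, v in (config.models or {}).items()}
    return d
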