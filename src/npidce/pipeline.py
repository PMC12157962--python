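"""End-to-end pipeline: design → simulate (or ingest) → fit → report.

A single master seed feeds every stage through spawned sub-seeds; running
the same configuration twice yields bit-identical outputs and manifests.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .design import (
    AttributeSpace,
    DesignDims,
    generate_design,
    sample_size_requirements,
)
from .errors import ConfigError
from .io import (
    mxl_result_to_dict,
    read_choice_data,
    write_dataset,
    write_design,
    write_encoded_design,
)
from .mmml import fit_mmml, membership_odds_ratios, select_k
from .mxl import DEFAULT_RANDOM_SET, fit_mxl
from .simulate import (
    ChoiceDataset,
    SimulationConfig,
    TasteClass,
    simulate_choices,
    simulate_profiles,
)
from .wtp import compute_wtp, preference_summary

log = logging.getLogger("npidce")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``truth`` / ``data_path``."""

    space: AttributeSpace = field(default_factory=AttributeSpace.canonical)
    n_blocks: int = 20
    tasks_per_block: int = 7
    alts_per_task: int = 2
    n_respondents: int = 1552
    truth: SimulationConfig | None = None
    data_path: str | None = None
    profiles_path: str | None = None
    random_set: tuple[str, ...] = DEFAULT_RANDOM_SET
    membership_covariates: tuple[str, ...] | None = None
    R: int = 500
    k_range: tuple[int, ...] = (1, 2, 3)
    n_starts: int = 5
    maxiter: int = 400
    seed: int = 0
    out_dir: str = "npidce_run"

    def __post_init__(self) -> None:
        if (self.truth is None) == (self.data_path is None):
            raise ConfigError(
                "exactly one of simulation truth and input data path must be set"
            )


def _parse_beta(space: AttributeSpace, raw) -> np.ndarray:
    names = space.predictor_names
    if isinstance(raw, dict):
        unknown = set(raw) - set(names)
        if unknown:
            raise ConfigError(f"unknown predictors in truth: {sorted(unknown)}")
        return np.array([float(raw.get(n, 0.0)) for n in names])
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (len(names),):
        raise ConfigError(f"beta must have length {len(names)}")
    return arr


def load_config(path) -> PipelineConfig:
    """Read a YAML/JSON pipeline configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    space = (
        AttributeSpace.from_dict(raw["space"]) if "space" in raw else AttributeSpace.canonical()
    )
    truth = None
    if "truth" in raw:
        t = raw["truth"]
        classes = []
        for c in t["classes"]:
            beta = _parse_beta(space, c["beta"])
            sigma = _parse_beta(space, c.get("sigma", {}))
            classes.append(TasteClass(beta=beta, sigma=sigma))
        gamma = np.asarray(t["gamma"], dtype=float) if "gamma" in t else None
        truth = SimulationConfig(
            classes=tuple(classes),
            gamma=gamma,
            membership_covariates=tuple(t["membership_covariates"])
            if "membership_covariates" in t
            else None,
        )
    kwargs = {
        k: raw[k]
        for k in (
            "n_blocks",
            "tasks_per_block",
            "alts_per_task",
            "n_respondents",
            "data_path",
            "profiles_path",
            "R",
            "n_starts",
            "maxiter",
            "seed",
            "out_dir",
        )
        if k in raw
    }
    if "random_set" in raw:
        kwargs["random_set"] = tuple(raw["random_set"])
    if "membership_covariates" in raw:
        kwargs["membership_covariates"] = tuple(raw["membership_covariates"])
    if "k_range" in raw:
        kwargs["k_range"] = tuple(raw["k_range"])
    return PipelineConfig(space=space, truth=truth, **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) recording
    sub-seeds, settings, sample-size checks and convergence flags.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sub = {
        name: int(s)
        for name, s in zip(
            ("design", "profiles", "choices", "mxl", "mmml", "wtp"),
            rng.integers(2**31, size=6),
        )
    }
    manifest: dict = {
        "package": {"name": "npidce", "version": __version__},
        "master_seed": config.seed,
        "sub_seeds": sub,
        "settings": {
            "n_blocks": config.n_blocks,
            "tasks_per_block": config.tasks_per_block,
            "alts_per_task": config.alts_per_task,
            "R": config.R,
            "k_range": list(config.k_range),
            "random_set": list(config.random_set),
            "n_starts": config.n_starts,
        },
        "stages": {},
    }

    dims = DesignDims(
        config.n_blocks, config.tasks_per_block, config.alts_per_task, config.space.max_levels
    )
    need = sample_size_requirements(dims)
    manifest["sample_size"] = dict(need._asdict())

    # --- design ----------------------------------------------------------
    log.info("stage design: B=%d a=%d t=%d", *dims[:3])
    design = generate_design(config.space, dims, seed=sub["design"])
    write_design(design, out / "design.csv")
    write_encoded_design(design, out / "design_encoded.csv")
    manifest["stages"]["design"] = {"seed": sub["design"], "blocks": dims.n_blocks}

    # --- data ------------------------------------------------------------
    if config.truth is not None:
        profiles = simulate_profiles(config.n_respondents, seed=sub["profiles"])
        dataset = simulate_choices(design, profiles, config.truth, seed=sub["choices"])
        write_dataset(dataset, out / "dataset.csv", out / "profiles.csv")
        manifest["stages"]["simulate"] = {
            "n_respondents": config.n_respondents,
            "classes": len(config.truth.classes),
        }
        n = config.n_respondents
    else:
        dataset = read_choice_data(
            config.data_path, config.space, profiles_path=config.profiles_path
        )
        manifest["stages"]["ingest"] = {
            "path": str(config.data_path),
            "n_respondents": dataset.n_respondents,
            "n_excluded": getattr(dataset, "n_excluded", 0),
        }
        n = dataset.n_respondents
    if n < need.recommended_n:
        warnings.warn(
            f"sample size {n} is below the recommendation "
            f"(Orme rule {need.orme_n}, 20-per-block rule {need.block_rule_n})"
        )
        manifest["sample_size"]["warning"] = True

    # --- mixed logit ------------------------------------------------------
    log.info("stage mxl: R=%d", config.R)
    mxl_res = fit_mxl(
        dataset, random_set=config.random_set, R=config.R, seed=sub["mxl"],
        maxiter=config.maxiter,
    )
    mxl_res.summary_frame().to_csv(out / "mxl_summary.csv", index=False)
    (out / "mxl_result.json").write_text(json.dumps(mxl_result_to_dict(mxl_res), indent=1))
    preference_summary(mxl_res).to_csv(out / "mxl_preferences.csv", index=False)
    try:
        compute_wtp(mxl_res, seed=sub["wtp"]).to_csv(out / "mxl_wtp.csv", index=False)
    except Exception as e:  # ill-posed WTP must not sink the run
        log.warning("MXL WTP skipped: %s", e)
    manifest["stages"]["mxl"] = {
        "seed": sub["mxl"],
        "loglik": mxl_res.loglik,
        "converged": mxl_res.converged,
    }

    # --- latent classes ---------------------------------------------------
    if config.k_range and (max(config.k_range) > 1 and dataset.profiles is not None):
        log.info("stage mmml: k_range=%s", config.k_range)
        best_k, table, fits = select_k(
            dataset,
            k_range=config.k_range,
            random_set=config.random_set,
            R=config.R,
            seed=sub["mmml"],
            covariates=config.membership_covariates,
            n_starts=config.n_starts,
            maxiter=config.maxiter,
            return_fits=True,
        )
        table.to_csv(out / "bic_table.csv", index=False)
        best = (
            fit_mmml(
                dataset,
                K=best_k,
                random_set=config.random_set,
                R=config.R,
                seed=sub["mmml"],
                covariates=config.membership_covariates,
                n_starts=config.n_starts,
                maxiter=config.maxiter,
            )
            if best_k > 1
            else None
        )
        manifest["stages"]["mmml"] = {
            "seed": sub["mmml"],
            "best_k": best_k,
            "bic": {str(int(r["K"])): float(r["bic"]) for _, r in table.iterrows()},
        }
        if best is not None:
            best.summary_frame().to_csv(out / f"mmml_k{best_k}_summary.csv", index=False)
            best.posterior_frame().to_csv(out / "mmml_posteriors.csv", index=False)
            if best.se_gamma is not None:
                membership_odds_ratios(best).to_csv(
                    out / "membership_odds_ratios.csv", index=False
                )
            preference_summary(best).to_csv(out / "mmml_preferences.csv", index=False)
            for c in range(best.K):
                try:
                    compute_wtp(best.class_result(c), seed=sub["wtp"]).to_csv(
                        out / f"mmml_class{c + 1}_wtp.csv", index=False
                    )
                except Exception as e:
                    log.warning("class %d WTP skipped: %s", c + 1, e)
            manifest["stages"]["mmml"]["shares"] = best.shares.tolist()
            manifest["stages"]["mmml"]["converged"] = best.converged

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
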