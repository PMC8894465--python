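"""End-to-end analysis pipeline over synthetic inputs.

Four stages, each writing TSV tables plus a JSON summary:

- ``architecture``: group contrast (moderately segregated, overlap-rich
  networks vs strongly segregated ones) on segregation and normalized
  overlap scores with Welch two-tailed t-tests.
- ``sweep``: the (p_in, p_out) planted-partition sweep relating
  segregation to overlap.
- ``tr``: ensemble-averaged topological-reinforcement trajectory with
  per-step segregation, overlap, efficiencies and activated ratio.
- ``cohort``: synthetic-cohort analysis — per-subject normalized
  overlap, mean dynamic flexibility, and Pearson correlations of
  overlap with flexibility and with the three behavior scores.

Every stage draws its randomness from the one top-level seed, and the
summary records the seed and a config hash, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import child_seeds
from .dynamic_flexibility import dynamic_communities, flexibility, sliding_window_fc
from .link_communities import normalized_overlap_score
from .stats import compare_groups, pearson
from .synthetic_data import CohortSpec, generate_cohort
from .synthetic_networks import ModularSpec, generate_modular, sweep_architecture
from .tr_model import tr_ensemble_mean

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]

BEHAVIOR_NAMES = ("pattern_completion", "card_sorting", "flanker")


def default_config() -> dict:
    """Pipeline defaults; every value mirrors a documented methods choice."""
    return {
        "seed": 0,
        "outdir": "commarch_out",
        "stages": ["architecture", "sweep", "tr", "cohort"],
        "architecture": {
            "n_per_group": 20,
            "N": 100,
            "M": 5,
            "p_in_moderate": 0.45,
            "p_in_segregated": 0.95,
            "p_out_moderate": 0.08,
            "p_out_segregated": 0.02,
            "n_null": 10,
        },
        "sweep": {
            "N": 100,
            "M": 5,
            "p_in_start": 0.7,
            "p_in_stop": 1.0,
            "p_in_step": 0.02,
            "p_out_start": 0.01,
            "p_out_stop": 0.35,
            "p_out_step": 0.02,
            "replicates": 5,
        },
        "tr": {
            "ensemble": 50,
            "N": 164,
            "mean_degree": 16.0,
            "steps": 60,
            "theta": 0.5,
            "seed_fraction": 0.32,
            "diffusion_reps": 20,
        },
        "cohort": {
            "n_subjects": 100,
            "N_structural": 164,
            "T": 4800,
            "n_null": 10,
            "window_seconds": 30.0,
            "step_samples": 1,
            "flexibility_subjects": None,  # None = all subjects
        },
    }


def _grid(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def _stage_architecture(cfg: dict, seed: int, outdir: Path) -> dict:
    seeds = child_seeds(seed, 2 * cfg["n_per_group"] + 1)
    moderate = [
        generate_modular(ModularSpec(N=cfg["N"], M=cfg["M"], p_in=cfg["p_in_moderate"],
                                     p_out=cfg["p_out_moderate"], seed=int(s)))
        for s in seeds[: cfg["n_per_group"]]
    ]
    segregated = [
        generate_modular(ModularSpec(N=cfg["N"], M=cfg["M"], p_in=cfg["p_in_segregated"],
                                     p_out=cfg["p_out_segregated"], seed=int(s)))
        for s in seeds[cfg["n_per_group"] : 2 * cfg["n_per_group"]]
    ]
    comp = compare_groups(moderate, segregated, seed=int(seeds[-1]), n_null=cfg["n_null"])
    table = pd.DataFrame(
        {
            "group": ["moderate"] * cfg["n_per_group"] + ["segregated"] * cfg["n_per_group"],
            "segregation": np.concatenate([comp.segregation_a, comp.segregation_b]),
            "normalized_overlap": np.concatenate([comp.overlap_a, comp.overlap_b]),
        }
    )
    table.to_csv(outdir / "architecture_groups.tsv", sep="\t", index=False)
    return {
        "mean_segregation_moderate": float(comp.segregation_a.mean()),
        "mean_segregation_segregated": float(comp.segregation_b.mean()),
        "mean_overlap_moderate": float(comp.overlap_a.mean()),
        "mean_overlap_segregated": float(comp.overlap_b.mean()),
        "t_segregation": comp.t_segregation,
        "p_segregation": comp.p_segregation,
        "t_overlap": comp.t_overlap,
        "p_overlap": comp.p_overlap,
    }


def _stage_sweep(cfg: dict, seed: int, outdir: Path) -> dict:
    df = sweep_architecture(
        N=cfg["N"],
        M=cfg["M"],
        p_in_grid=_grid(cfg["p_in_start"], cfg["p_in_stop"], cfg["p_in_step"]),
        p_out_grid=_grid(cfg["p_out_start"], cfg["p_out_stop"], cfg["p_out_step"]),
        replicates=cfg["replicates"],
        seed=seed,
    )
    df.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    peak = df.loc[df["overlap"].idxmax()]
    return {
        "n_cells": int(len(df)),
        "overlap_peak_segregation": float(peak["segregation"]),
        "segregation_range": [float(df["segregation"].min()), float(df["segregation"].max())],
    }


def _stage_tr(cfg: dict, seed: int, outdir: Path) -> dict:
    df = tr_ensemble_mean(
        n_networks=cfg["ensemble"],
        N=cfg["N"],
        mean_degree=cfg["mean_degree"],
        n_steps=cfg["steps"],
        seed=seed,
        theta=cfg["theta"],
        seed_fraction=cfg["seed_fraction"],
        diffusion_reps=cfg["diffusion_reps"],
    )
    df.to_csv(outdir / "tr_trajectory.tsv", sep="\t", index=False)
    return {
        "segregation_start": float(df["segregation"].iloc[0]),
        "segregation_end": float(df["segregation"].iloc[-1]),
        "overlap_argmax_step": int(df.loc[df["overlap"].idxmax(), "step"]),
        "global_eff_argmax_step": int(df.loc[df["global_eff"].idxmax(), "step"]),
        "local_eff_argmax_step": int(df.loc[df["local_eff"].idxmax(), "step"]),
        "activated_ratio_argmax_step": int(df.loc[df["activated_ratio"].idxmax(), "step"]),
    }


def _stage_cohort(cfg: dict, seed: int, outdir: Path) -> dict:
    seeds = child_seeds(seed, 3)
    spec = CohortSpec(
        n_subjects=cfg["n_subjects"],
        N_structural=cfg["N_structural"],
        T=cfg["T"],
        n_null=cfg["n_null"],
        seed=int(seeds[0]),
    )
    cohort = generate_cohort(spec)
    analysis_seeds = child_seeds(int(seeds[1]), 2 * len(cohort))
    overlaps, flex_vals = [], []
    n_flex = cfg["flexibility_subjects"] or len(cohort)
    for i, subj in enumerate(cohort):
        res = normalized_overlap_score(subj.structural, n_null=cfg["n_null"],
                                       seed=int(analysis_seeds[2 * i]))
        overlaps.append(res.normalized_overlap)
        if i < n_flex:
            dc = sliding_window_fc(
                subj.panel,
                window_seconds=cfg["window_seconds"],
                step_seconds=cfg["step_samples"] * spec.sampling_interval,
            )
            labels = dynamic_communities(dc, seed=int(analysis_seeds[2 * i + 1]))
            flex_vals.append(flexibility(labels).mean_flexibility)
        else:
            flex_vals.append(np.nan)
    behaviors = np.array([s.behavior_scores for s in cohort])
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "normalized_overlap": overlaps,
            "mean_flexibility": flex_vals,
            **{name: behaviors[:, k] for k, name in enumerate(BEHAVIOR_NAMES)},
        }
    )
    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    out: dict = {}
    mask = ~np.isnan(flex_vals)
    r, p = pearson(np.array(overlaps)[mask], np.array(flex_vals)[mask])
    out["r_overlap_flexibility"] = r
    out["p_overlap_flexibility"] = p
    for k, name in enumerate(BEHAVIOR_NAMES):
        r, p = pearson(overlaps, behaviors[:, k])
        out[f"r_overlap_{name}"] = r
        out[f"p_overlap_{name}"] = p
    return out


_STAGES = {
    "architecture": _stage_architecture,
    "sweep": _stage_sweep,
    "tr": _stage_tr,
    "cohort": _stage_cohort,
}


def run_pipeline(config: dict) -> dict:
    """Run the selected stages; returns (and writes) the summary dict."""
    cfg = default_config()
    for key, value in config.items():
        if isinstance(value, dict) and key in cfg:
            cfg[key] = {**cfg[key], **value}
        else:
            cfg[key] = value
    stages = cfg.get("stages") or []
    if not stages:
        raise ValueError("no stages selected")
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    stage_seeds = {name: int(s) for name, s in zip(sorted(_STAGES), child_seeds(cfg["seed"], len(_STAGES)))}
    summary = {"seed": cfg["seed"], "config_hash": config_hash, "stages": {}}
    for name in stages:
        logger.info("running stage %s", name)
        try:
            summary["stages"][name] = _STAGES[name](cfg[name], stage_seeds[name], outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
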