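"""Pipeline orchestration: configuration, seed fan-out, stage execution.

A single top-level seed is fanned out deterministically to per-stage seeds
(cohort, sessions, MCMC, volumes, permutations) via ``numpy``'s
``SeedSequence`` spawning, so each stage is independently reproducible and
no hidden RNG state crosses stage boundaries.  ``run_pipeline`` executes
synthetic cohort -> task sessions -> interoceptive measures -> behavioural
statistics -> connectivity, writing tabular outputs, a Markdown report and a
manifest with content hashes of every artefact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behavioural_stats, connectivity, synthetic_data
from .fdt_engine import StaircaseConfig, run_session
from .hmeta import HMetaConfig, fit_hmeta
from .interoception_measures import (
    SubjectMeasures,
    bin_confidence,
    dprime_criterion,
    measures_table,
    metacognitive_bias,
    sdt_counts,
)

logger = logging.getLogger("respimeta")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seeds"]


@dataclass(frozen=True)
class CohortConfig:
    n: int = 65
    n_female: int = 32
    n_male: int = 33

    def __post_init__(self) -> None:
        if self.n_female + self.n_male != self.n:
            raise ValueError("cohort.n must equal cohort.n_female + cohort.n_male")


@dataclass(frozen=True)
class ObserverConfig:
    accuracy_at_threshold: float = 0.75
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.5 < self.accuracy_at_threshold < 1.0:
            raise ValueError("observer.accuracy_at_threshold must be in (0.5, 1)")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("observer.lapse_rate must be in [0, 0.1]")


@dataclass(frozen=True)
class ConnectivityConfig:
    enabled: bool = True
    shape: tuple[int, int, int] = (16, 16, 8)
    n_timepoints: int = 80
    noise_sd: float = 1.0
    baseline: float = 0.4
    effect: float = 0.08
    measure: str = "metacog_bias"
    covariate_set: str = "measure_only"
    n_perm: int = 300

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("connectivity.n_perm must be >= 100")
        if self.n_timepoints < 10:
            raise ValueError("connectivity.n_timepoints must be >= 10")


@dataclass(frozen=True)
class StageToggles:
    measures: bool = True
    behaviour: bool = True
    connectivity: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    cohort: CohortConfig = CohortConfig()
    staircase: StaircaseConfig = StaircaseConfig()
    observer: ObserverConfig = ObserverConfig()
    hmeta: HMetaConfig = HMetaConfig()
    connectivity: ConnectivityConfig = ConnectivityConfig()
    stages: StageToggles = StageToggles()
    alpha: float = 0.05

    def resolved_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "cohort": CohortConfig,
    "staircase": StaircaseConfig,
    "observer": ObserverConfig,
    "hmeta": HMetaConfig,
    "connectivity": ConnectivityConfig,
    "stages": StageToggles,
}


def validate_config(path_or_dict: str | Path | dict) -> PipelineConfig:
    """Load and validate a pipeline config; unknown keys are rejected with
    the offending key named."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in ("seed", "out_dir", "alpha"):
            kwargs[key] = value
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            allowed = set(cls.__dataclass_fields__)
            for sub in value:
                if sub not in allowed:
                    raise ValueError(f"unknown config key: {key}.{sub}")
            if key == "connectivity" and "shape" in value:
                value = {**value, "shape": tuple(value["shape"])}
            try:
                kwargs[key] = cls(**value)
            except (ValueError, TypeError) as err:
                raise ValueError(f"invalid section {key!r}: {err}") from err
        else:
            raise ValueError(f"unknown config key: {key}")
    return PipelineConfig(**kwargs)


def stage_seeds(master: int) -> dict[str, int]:
    """Deterministic fan-out of the master seed into per-stage seeds (<2^31)."""
    names = ["cohort", "sessions", "mcmc", "volumes", "permutations"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def behavioural_stage(
    cohort: pd.DataFrame,
    staircase: StaircaseConfig,
    observer_cfg: ObserverConfig,
    sessions_seed: int,
) -> tuple[pd.DataFrame, list, list]:
    """Run one FDT session per subject and compute the type-1 measures.

    Returns the per-subject measures table (mratio column filled later by
    the hierarchical fit), the trial sessions, and the per-subject
    confidence-count tables for subjects eligible for the meta-d' fit."""
    session_ss = np.random.SeedSequence(sessions_seed).spawn(len(cohort))
    sessions, rows, conf_counts = [], [], []
    for (_, row), child in zip(cohort.iterrows(), session_ss):
        obs = synthetic_data.make_observer(
            row,
            accuracy_at_threshold=observer_cfg.accuracy_at_threshold,
            lapse_rate=observer_cfg.lapse_rate,
        )
        result = run_session(
            synthetic_data.make_responder(obs),
            staircase,
            seed=np.random.default_rng(child),
        )
        sessions.append(result)
        counts = sdt_counts(result.analyzed_trials)
        d, c = dprime_criterion(counts)
        rows.append(
            SubjectMeasures(
                subject_id=str(row["id"]),
                d_prime=d,
                criterion_c=c,
                metacog_bias=metacognitive_bias(result.analyzed_trials),
                mratio=None,
                is_filters=result.final_level,
                valid=result.validity_flag,
            )
        )
        conf_counts.append(bin_confidence(result.analyzed_trials))
    return measures_table(rows), sessions, conf_counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict[str, Any] = {
        "config_hash": config.resolved_hash(),
        "seeds": seeds,
    }
    t0 = time.time()
    cohort = synthetic_data.sample_cohort_traits(
        config.cohort.n,
        (config.cohort.n_female, config.cohort.n_male),
        seed=seeds["cohort"],
    )
    synthetic_data.write_cohort(cohort, out / "cohort.tsv")
    logger.info("cohort stage done (%.1fs)", time.time() - t0)

    measures = None
    if config.stages.measures:
        measures, sessions, conf_counts = behavioural_stage(
            cohort, config.staircase, config.observer, seeds["sessions"]
        )
        fit_mask = (measures["d_prime"] > 0).to_numpy()
        posterior = fit_hmeta(
            [c for c, keep in zip(conf_counts, fit_mask) if keep],
            measures.loc[fit_mask, "d_prime"].to_numpy(),
            measures.loc[fit_mask, "criterion_c"].to_numpy(),
            config.hmeta,
            seed=seeds["mcmc"],
        )
        mratio_col = np.full(len(measures), np.nan)
        mratio_col[fit_mask] = posterior.subject_mratio_mean
        measures["mratio"] = mratio_col
        measures.to_csv(out / "measures.tsv", sep="\t", index=False)
        (out / "posterior.json").write_text(
            json.dumps(posterior.summary_dict(), indent=1)
        )
        report["behaviour"] = {
            "mean_filters": float(measures["is_filters"].mean()),
            "mean_confidence": float(measures["metacog_bias"].mean()),
            "mean_dprime": float(measures["d_prime"].mean()),
            "mean_criterion": float(measures["criterion_c"].mean()),
            "group_mratio": posterior.group_mratio_mean,
            "mcmc_converged": posterior.converged,
            "mean_total_trials": float(np.mean([s.total_trials for s in sessions])),
            "n_valid": int(measures["valid"].sum()),
        }
        logger.info("measures stage done (%.1fs)", time.time() - t0)

    if config.stages.behaviour and measures is not None:
        merged = measures.merge(cohort[["id", "gad7"]], on="id")
        corr = behavioural_stats.pearson_matrix(
            merged,
            ["is_filters", "criterion_c", "metacog_bias", "mratio", "gad7"],
            alpha=config.alpha,
        )
        corr.R.to_csv(out / "correlations_R.tsv", sep="\t")
        corr.p_raw.to_csv(out / "correlations_p.tsv", sep="\t")
        corr.p_fdr.to_csv(out / "correlations_p_fdr.tsv", sep="\t")
        spec = behavioural_stats.PowerSpec()
        report["stats"] = {
            "n_significant_uncorrected": int(corr.significant.to_numpy().sum() // 2),
            "n_significant_fdr": int(
                ((corr.p_fdr.to_numpy() < config.alpha)
                 & ~np.eye(len(corr.variables), dtype=bool)).sum() // 2
            ),
            "power_minimal_n": behavioural_stats.minimal_n(spec),
        }
        logger.info("behaviour stage done (%.1fs)", time.time() - t0)

    if config.stages.connectivity and config.connectivity.enabled:
        ccfg = config.connectivity
        geometry = _scaled_geometry(ccfg.shape)
        grids = synthetic_data.simulate_volume_cohort(
            cohort,
            geometry,
            synthetic_data.CouplingSpec(
                covariate=ccfg.measure, baseline=ccfg.baseline, effect=ccfg.effect
            ),
            noise_sd=ccfg.noise_sd,
            n_timepoints=ccfg.n_timepoints,
            seed=seeds["volumes"],
        )
        maps = []
        for grid in grids:
            sl = connectivity.extract_seed_series(grid, grid.seed_left)
            sr = connectivity.extract_seed_series(grid, grid.seed_right)
            fe = connectivity.fixed_effects_hemispheres(
                connectivity.first_level_fc(grid, sl),
                connectivity.first_level_fc(grid, sr),
            )
            maps.append(fe["mean"].beta)
        design = connectivity.build_group_design(
            cohort, ccfg.measure, ccfg.covariate_set
        )
        res = connectivity.permutation_fwe(
            np.stack(maps),
            design,
            "measure_positive",
            n_perm=ccfg.n_perm,
            seed=seeds["permutations"],
        )
        sig = res.fwe_p < 0.05
        target = grids[0].target_mask
        report["connectivity"] = {
            "n_significant_voxels": int(sig.sum()),
            "n_significant_in_target": int((sig & target).sum()),
            "n_target_voxels": int(target.sum()),
            "n_permutations": res.n_permutations,
            "min_fwe_p": float(res.fwe_p.min()),
        }
        logger.info("connectivity stage done (%.1fs)", time.time() - t0)

    report["elapsed_seconds"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    _write_markdown_report(report, out / "report.md")
    _write_manifest(out)
    return report


def _scaled_geometry(shape: tuple[int, int, int]) -> synthetic_data.VolumeGeometry:
    """Place the default cuboid layout proportionally inside ``shape``."""
    x, y, z = shape
    return synthetic_data.VolumeGeometry(
        shape=shape,
        seed_size=(2, 2, 2),
        seed_left_corner=(1, 1, 1),
        seed_right_corner=(x - 3, 1, 1),
        target_corner=(x // 2 - 1, y - 4, z // 2),
        target_size=(3, 3, 2),
    )


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    if "behaviour" in report:
        b = report["behaviour"]
        lines += [
            "## Behavioural summary",
            f"- mean filters at threshold: {b['mean_filters']:.2f}",
            f"- mean confidence (metacognitive bias): {b['mean_confidence']:.2f}",
            f"- mean d': {b['mean_dprime']:.2f}, mean c: {b['mean_criterion']:.2f}",
            f"- group Mratio: {b['group_mratio']:.3f} "
            f"(MCMC converged: {b['mcmc_converged']})",
            f"- mean trials to completion: {b['mean_total_trials']:.1f}",
            "",
        ]
    if "stats" in report:
        s = report["stats"]
        lines += [
            "## Behavioural statistics",
            f"- pairs significant at p<0.05 (uncorrected): {s['n_significant_uncorrected']}",
            f"- pairs surviving FDR: {s['n_significant_fdr']}",
            f"- minimal n for 80% power (f^2=0.15): {s['power_minimal_n']}",
            "",
        ]
    if "connectivity" in report:
        cnx = report["connectivity"]
        lines += [
            "## Connectivity",
            f"- significant voxels (FWE p<0.05): {cnx['n_significant_voxels']}"
            f" ({cnx['n_significant_in_target']} inside the target region of "
            f"{cnx['n_target_voxels']} voxels)",
            f"- permutations: {cnx['n_permutations']}",
            "",
        ]
    path.write_text("\n".join(lines))


def _write_manifest(out: Path) -> None:
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
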