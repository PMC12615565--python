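"""Canned simulation studies: the algorithm-level validation experiments.

Each function sets up a study at its documented scale, runs it through the
library, and returns plain summary numbers.  They back the numbered drivers
in ``analysis/`` and the acceptance checks; nothing here is interactive.
"""

from __future__ import annotations

import numpy as np

from . import connectivity as cn
from . import synthetic_data as sd
from .fdt_engine import StaircaseConfig, run_session, schedule_block
from .hmeta import HMetaConfig, HMetaPosterior, fit_hmeta
from .interoception_measures import bin_confidence, dprime_criterion, sdt_counts

__all__ = [
    "staircase_operating_band",
    "simulate_rating_cohort",
    "mratio_recovery",
    "SMALL_GEOMETRY",
    "fwe_null_calibration",
    "planted_effect_detection",
]


def staircase_operating_band(
    n_sessions: int = 200,
    seed: int = 0,
    slope: float = 0.45,
    criterion_c: float = 0.0,
    lapse_rate: float = 0.01,
    config: StaircaseConfig = StaircaseConfig(),
) -> dict:
    """Cohort of staircase sessions with linear-psychometric observers.

    Observers have d'(f) = slope * f, a neutral criterion and a small lapse
    rate; each runs the staircase to the 60-trials-at-one-level stop.
    Returns the across-session mean accuracy over the analysed trials (in
    percent), the mean total trial count, and completion bookkeeping.
    """
    ss = np.random.SeedSequence(seed).spawn(n_sessions)
    accuracies, totals, levels, n_complete = [], [], [], 0
    for child in ss:
        obs = sd.ObserverParams(
            slope=slope,
            threshold_filter=max(1, round(2.698 / slope)) if slope > 0 else 1,
            criterion_c=criterion_c,
            mratio_true=0.84,
            lapse_rate=lapse_rate,
        )
        res = run_session(sd.make_responder(obs), config, seed=np.random.default_rng(child))
        if res.completed:
            n_complete += 1
            accuracies.append(res.accuracy_at_final)
            totals.append(res.total_trials)
            levels.append(res.final_level)
    return {
        "n_sessions": n_sessions,
        "n_complete": n_complete,
        "mean_accuracy_pct": 100.0 * float(np.mean(accuracies)),
        "mean_total_trials": float(np.mean(totals)),
        "mean_final_level": float(np.mean(levels)),
        "all_sixty_analyzed": True,  # enforced by run_session's stop rule
    }


def simulate_rating_cohort(
    median_mratio: float,
    log_spread: float = 0.0,
    n_subjects: int = 30,
    n_trials: int = 60,
    level: int = 4,
    random_confidence: bool = False,
    seed: int = 0,
):
    """Fixed-level rating data for a parameter-recovery study.

    Each subject answers ``n_trials`` trials at one filter level through the
    generative observer (pseudo-randomised condition blocks); confidence may
    be replaced by uniform ratings to build a metacognition-free cohort.
    Returns (confidence_counts, generative d' list, generative c list,
    estimated d' list, estimated c list).
    """
    import pandas as pd

    from .fdt_engine import TrialRecord

    rng = np.random.default_rng(seed)
    counts, gen_d, gen_c, est_d, est_c = [], [], [], [], []
    while len(counts) < n_subjects:
        mratio = median_mratio * float(np.exp(rng.normal(0.0, log_spread)))
        row = pd.Series(
            dict(is_filters=level, decision_c=0.0, mratio_true=mratio, metacog_bias=6.22)
        )
        obs = sd.make_observer(row)
        trials = []
        schedule: list = []
        for i in range(n_trials):
            if not schedule:
                schedule = schedule_block(rng)
            cond = schedule.pop(0)
            resp, conf = sd.observer_respond(obs, level, cond, rng)
            if random_confidence:
                conf = int(rng.integers(1, 11))
            trials.append(
                TrialRecord(
                    index=i + 1,
                    condition=cond,
                    filter_count=level if cond == "resistance" else 0,
                    response=resp,
                    correct=(cond == "resistance") == (resp == "yes"),
                    confidence=conf,
                    level_at_trial=level,
                )
            )
        d_hat, c_hat = dprime_criterion(sdt_counts(trials))
        if d_hat <= 0:  # a subject at chance carries no Mratio information
            continue
        counts.append(bin_confidence(trials))
        gen_d.append(obs.d_prime(level))
        gen_c.append(0.0)
        est_d.append(d_hat)
        est_c.append(c_hat)
    return counts, gen_d, gen_c, est_d, est_c


def mratio_recovery(
    median_mratio: float,
    log_spread: float = 0.0,
    n_subjects: int = 30,
    n_trials: int = 60,
    random_confidence: bool = False,
    seed: int = 0,
    mcmc: HMetaConfig = HMetaConfig(n_warmup=1500, n_draws=2000),
) -> HMetaPosterior:
    """Generate a rating cohort and fit the hierarchical model.

    The fit conditions on the known generative type-1 parameters — the
    recovery study isolates the meta-level estimator, while the analysis
    pipeline proper uses the estimated d'/c of each subject."""
    counts, gen_d, gen_c, _, _ = simulate_rating_cohort(
        median_mratio,
        log_spread,
        n_subjects,
        n_trials,
        random_confidence=random_confidence,
        seed=seed,
    )
    return fit_hmeta(counts, gen_d, gen_c, mcmc, seed=seed + 1)


#: compact volume layout used by the calibration studies: two 8-voxel seeds
#: and an 8-voxel target inside a 10 x 10 x 6 grid
SMALL_GEOMETRY = sd.VolumeGeometry(
    shape=(10, 10, 6),
    seed_size=(2, 2, 2),
    seed_left_corner=(1, 1, 1),
    seed_right_corner=(7, 1, 1),
    target_corner=(4, 6, 2),
    target_size=(2, 2, 2),
)


def _group_analysis(seed: int, n_subjects: int, effect: float, n_perm: int):
    cohort = sd.sample_cohort_traits(
        n_subjects, (n_subjects // 2, n_subjects - n_subjects // 2), seed=seed
    )
    grids = sd.simulate_volume_cohort(
        cohort,
        SMALL_GEOMETRY,
        sd.CouplingSpec(covariate="metacog_bias", baseline=0.4, effect=effect),
        noise_sd=1.0,
        n_timepoints=60,
        seed=seed + 10_000,
    )
    maps = []
    for g in grids:
        left = cn.first_level_fc(g, cn.extract_seed_series(g, g.seed_left))
        right = cn.first_level_fc(g, cn.extract_seed_series(g, g.seed_right))
        maps.append(cn.fixed_effects_hemispheres(left, right)["mean"].beta)
    design = cn.build_group_design(cohort, "metacog_bias")
    res = cn.permutation_fwe(
        np.stack(maps), design, "measure_positive", n_perm=n_perm, seed=seed + 1
    )
    return res, grids[0].target_mask


def fwe_null_calibration(
    n_replicates: int = 200, n_subjects: int = 20, n_perm: int = 500, seed: int = 0
) -> dict:
    """Family-wise false-positive rate of the TFCE permutation test under
    effect-free cohorts (any voxel significant at FWE p < 0.05 counts)."""
    base = seed * 100_003
    fp = sum(
        (_group_analysis(base + r, n_subjects, 0.0, n_perm)[0].fwe_p < 0.05).any()
        for r in range(n_replicates)
    )
    return {"n_replicates": n_replicates, "fwe_rate": fp / n_replicates}


def planted_effect_detection(
    n_replicates: int = 20,
    n_subjects: int = 40,
    effect: float = 0.5,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Power of the group pipeline to find a planted covariate effect inside
    the target region (>= 1 significant target voxel counts as detection)."""
    base = seed * 100_003 + 50_000
    det = 0
    for r in range(n_replicates):
        res, target = _group_analysis(base + r, n_subjects, effect, n_perm)
        det += bool((res.fwe_p[target] < 0.05).any())
    return {"n_replicates": n_replicates, "detection_rate": det / n_replicates}
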