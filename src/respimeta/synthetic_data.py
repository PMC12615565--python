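"""Synthetic study data with the statistical structure the analyses assume.

Three generators:

* a cohort of questionnaire/behavioural traits drawn through a Gaussian
  copula so that stated marginal means/SDs/bounds and pairwise Pearson
  correlations are both honoured;
* trial-capable observers: equal-variance SDT deciders whose sensitivity
  grows linearly with the number of resistance filters, with confidence
  ratings produced by the same meta-d' type-2 model later fitted (a
  self-consistent generative model, so parameter recovery is well-posed);
* small 4D volume time series with two seed regions sharing a smooth latent
  signal and a target region whose coupling to that latent scales with a
  subject-level covariate — the minimal structure a seed-based connectivity
  group analysis needs.

Everything is reproducible bit-for-bit from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .interoception_measures import type2_probabilities

__all__ = [
    "TraitMarginal",
    "TraitSpec",
    "DEFAULT_TRAIT_SPEC",
    "ObserverParams",
    "VolumeGeometry",
    "VolumeGrid",
    "CouplingSpec",
    "sample_cohort_traits",
    "make_observer",
    "observer_respond",
    "expected_accuracy",
    "simulate_volume_cohort",
    "save_volume",
    "load_volume",
    "write_cohort",
    "read_cohort",
]

_N_CONF_CRITERIA = 9  # 10-point rating scale -> 9 type-2 criteria per response
_BASE_SPACING = 0.25


# ---------------------------------------------------------------------------
# cohort traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitMarginal:
    """Marginal distribution of one trait: (truncated) normal or lognormal,
    optionally rounded to integers, clipped to instrument bounds.

    ``mean``/``sd`` are the target moments of the *truncated* marginal, not
    of the parent normal: the parent location/scale are solved so that the
    distribution actually delivered has the configured mean and SD despite
    the instrument bounds."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf
    integer: bool = False
    kind: Literal["truncnorm", "lognormal"] = "truncnorm"

    def _parent_params(self) -> tuple[float, float]:
        return _matched_parent_params(self)

    def _solve_parent_params(self) -> tuple[float, float]:
        if not (np.isfinite(self.lo) or np.isfinite(self.hi)):
            return self.mean, self.sd

        def moments(loc: float, scale: float) -> tuple[float, float]:
            a, b = (self.lo - loc) / scale, (self.hi - loc) / scale
            m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
            return float(m), float(np.sqrt(v))

        from scipy.optimize import fsolve

        def gap(params: np.ndarray) -> list[float]:
            m, s = moments(params[0], float(np.exp(params[1])))
            return [m - self.mean, s - self.sd]

        sol = fsolve(gap, np.array([self.mean, np.log(self.sd)]), full_output=False)
        return float(sol[0]), float(np.exp(sol[1]))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "lognormal":
            x = np.exp(self.mean + self.sd * norm.ppf(u))
        else:
            loc, scale = self._parent_params()
            a = (self.lo - loc) / scale
            b = (self.hi - loc) / scale
            x = truncnorm.ppf(u, a, b, loc=loc, scale=scale)
        if self.integer:
            x = np.clip(np.rint(x), self.lo, self.hi)
        return x


@dataclass(frozen=True)
class TraitSpec:
    marginals: dict[str, TraitMarginal]
    correlation: np.ndarray  # in the order of `marginals`

    def __post_init__(self) -> None:
        k = len(self.marginals)
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError(
                "correlation matrix is not positive semi-definite "
                f"(min eigenvalue {np.linalg.eigvalsh(R).min():.3g})"
            )
        for name, m in self.marginals.items():
            if np.isfinite(m.lo) and np.isfinite(m.hi) and not m.lo < m.hi:
                raise ValueError(f"infeasible bounds for trait {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.marginals)


def _default_spec() -> TraitSpec:
    marginals = {
        # GAD-7 trait anxiety: cohort mean 2.85 (SD 2.49), instrument range 0-21
        "gad7": TraitMarginal(2.85, 2.49, 0, 21, integer=True),
        # MAIA (0-5) and PANAS (10-50): instrument-typical community values
        "maia": TraitMarginal(3.2, 0.6, 0.0, 5.0),
        "panas_p": TraitMarginal(32.0, 7.0, 10, 50, integer=True),
        "panas_n": TraitMarginal(16.0, 5.5, 10, 50, integer=True),
        # filters at perceptual threshold: cohort mean 3.69 (SD 1.84), >= 1
        "is_filters": TraitMarginal(3.69, 1.84, 1, 12, integer=True),
        # SDT decision bias: cohort mean 0.09 (SD 0.33)
        "decision_c": TraitMarginal(0.09, 0.33),
        # mean confidence (1-10 scale): cohort mean 6.22 (SD 1.37)
        "metacog_bias": TraitMarginal(6.22, 1.37, 1.0, 10.0),
        # generative Mratio: median 0.84; between-subject log-SD 0.25 (the
        # printed group SD 0.05 is posterior-shrunk, not a population spread)
        "mratio_true": TraitMarginal(np.log(0.84), 0.25, kind="lognormal"),
    }
    names = list(marginals)
    R = np.eye(len(names))

    def _set(a: str, b: str, r: float) -> None:
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = r

    _set("gad7", "metacog_bias", -0.26)
    _set("gad7", "is_filters", 0.27)
    _set("metacog_bias", "maia", 0.30)
    _set("metacog_bias", "panas_p", 0.37)
    _set("metacog_bias", "panas_n", -0.22)
    return TraitSpec(marginals, R)


@lru_cache(maxsize=256)
def _matched_parent_params(marginal: "TraitMarginal") -> tuple[float, float]:
    return marginal._solve_parent_params()


DEFAULT_TRAIT_SPEC = _default_spec()


def sample_cohort_traits(
    n: int,
    gender_split: tuple[int, int] = (32, 33),
    trait_spec: TraitSpec = DEFAULT_TRAIT_SPEC,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort table via a Gaussian copula.

    Latent multivariate-normal scores with the requested correlation matrix
    are pushed through each trait's marginal quantile function (a
    rank-preserving transform, so target Pearson correlations survive up to
    mild attenuation from truncation/rounding).
    """
    n_f, n_m = gender_split
    if n_f + n_m != n:
        raise ValueError(f"gender split {gender_split} does not sum to n={n}")
    rng = np.random.default_rng(seed)
    names = trait_spec.names
    L = np.linalg.cholesky(trait_spec.correlation + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ L.T
    u = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
    data = {
        name: trait_spec.marginals[name].ppf(u[:, i]) for i, name in enumerate(names)
    }
    genders = np.array(["F"] * n_f + ["M"] * n_m)
    rng.shuffle(genders)
    table = pd.DataFrame({"id": [f"s{i + 1:03d}" for i in range(n)], "gender": genders})
    for name in names:
        col = data[name]
        m = trait_spec.marginals[name]
        table[name] = col.astype(int) if m.integer else col
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# generative observers
# ---------------------------------------------------------------------------

@dataclass
class ObserverParams:
    """Equal-variance SDT observer with linear psychometric scaling.

    Sensitivity is d'(f) = slope * f for f resistance filters; the sham
    condition is stimulus-absent.  Confidence comes from the meta-d' type-2
    model with criteria at c' +/- criteria_scale * 0.25 * (1..9); the scale is
    calibrated so the expected mean confidence at ``threshold_filter`` matches
    the subject's metacognitive-bias trait.
    """

    slope: float
    threshold_filter: int
    criterion_c: float
    mratio_true: float
    lapse_rate: float = 0.01
    n_rating_levels: int = 10
    criteria_scale: float = 1.0
    _p2_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.mratio_true < 0:
            raise ValueError("mratio_true must be >= 0")

    def d_prime(self, filter_count: int) -> float:
        return self.slope * filter_count

    def meta_d(self, filter_count: int) -> float:
        return self.mratio_true * self.d_prime(filter_count)

    def type2_table(self, level: int) -> np.ndarray:
        """Rating probabilities (2, 2, 10) at a staircase level, cached."""
        if level not in self._p2_cache:
            meta_d = self.meta_d(level)
            c_scaled = self.criterion_c * self.mratio_true
            offs = self.criteria_scale * _BASE_SPACING * np.arange(1, _N_CONF_CRITERIA + 1)
            self._p2_cache[level] = type2_probabilities(
                meta_d, c_scaled, c_scaled - offs[::-1], c_scaled + offs
            )
        return self._p2_cache[level]


def expected_accuracy(params: ObserverParams, filter_count: int) -> float:
    """Expected proportion correct at a level (equal resistance/sham mix)."""
    d = params.d_prime(filter_count)
    c = params.criterion_c
    hit = norm.sf(c - d / 2.0)
    cr = norm.cdf(c + d / 2.0)
    acc = 0.5 * (hit + cr)
    return float((1 - params.lapse_rate) * acc + params.lapse_rate * 0.5)


def _expected_mean_confidence(params: ObserverParams, level: int) -> float:
    d = params.d_prime(level)
    c = params.criterion_c
    p_yes = np.array([norm.sf(c + d / 2.0), norm.sf(c - d / 2.0)])  # by stimulus
    p2 = params.type2_table(level)
    ratings = np.arange(1, 11)
    m = 0.0
    for stim in (0, 1):
        for resp, p_resp in ((0, 1 - p_yes[stim]), (1, p_yes[stim])):
            m += 0.5 * p_resp * float(p2[stim, resp] @ ratings)
    return (1 - params.lapse_rate) * m + params.lapse_rate * 5.5


def make_observer(
    row: pd.Series,
    accuracy_at_threshold: float = 0.75,
    lapse_rate: float = 0.01,
) -> ObserverParams:
    """Build the generative observer for one cohort row.

    The slope is set so that unbiased accuracy at ``is_filters`` filters is
    ``accuracy_at_threshold`` (default 75%, the centre of the staircase's
    operating band): slope = 2 z(acc) / is_filters.  The confidence-criteria
    scale is then solved so the observer's expected mean confidence at that
    level equals its metacognitive-bias trait.  Deterministic given the row.
    """
    is_filters = int(row["is_filters"])
    if is_filters < 1:
        raise ValueError("is_filters must be >= 1")
    slope = 2.0 * norm.ppf(accuracy_at_threshold) / is_filters
    params = ObserverParams(
        slope=slope,
        threshold_filter=is_filters,
        criterion_c=float(row["decision_c"]),
        mratio_true=float(row["mratio_true"]),
        lapse_rate=lapse_rate,
    )
    target = float(np.clip(row["metacog_bias"], 1.05, 9.95))

    def gap(log_scale: float) -> float:
        trial = replace(params, criteria_scale=float(np.exp(log_scale)), _p2_cache={})
        return _expected_mean_confidence(trial, is_filters) - target

    lo, hi = -4.0, 4.0
    if gap(lo) < 0:  # even collapsed criteria cannot reach the target: max confidence
        scale = np.exp(lo)
    elif gap(hi) > 0:
        scale = np.exp(hi)
    else:
        scale = float(np.exp(brentq(gap, lo, hi, xtol=1e-6)))
    return replace(params, criteria_scale=scale, _p2_cache={})


def observer_respond(
    params: ObserverParams,
    filter_count: int,
    condition: Literal["resistance", "sham"],
    rng: np.random.Generator,
) -> tuple[Literal["yes", "no"], int]:
    """Answer one trial: type-1 decision from an evidence sample, confidence
    from the response-conditional meta-d' rating distribution.

    Sham trials draw from the stimulus-absent distribution regardless of the
    current staircase level (the sham filter is empty)."""
    if rng.uniform() < params.lapse_rate:
        resp: Literal["yes", "no"] = "yes" if rng.uniform() < 0.5 else "no"
        return resp, int(rng.integers(1, 11))
    d = params.d_prime(filter_count)
    mu = d / 2.0 if condition == "resistance" else -d / 2.0
    x = rng.normal(mu, 1.0)
    yes = x > params.criterion_c
    p2 = params.type2_table(filter_count)
    stim = 1 if condition == "resistance" else 0
    probs = p2[stim, 1 if yes else 0]
    conf = int(rng.choice(10, p=probs)) + 1
    return ("yes" if yes else "no"), conf


def make_responder(params: ObserverParams):
    """Adapt an observer to the fdt_engine Responder protocol."""

    def respond(filter_count: int, condition: str, rng: np.random.Generator):
        return observer_respond(params, filter_count, condition, rng)

    return respond


# ---------------------------------------------------------------------------
# synthetic volumes
# ---------------------------------------------------------------------------

def _block(shape: tuple[int, int, int], corner: tuple[int, int, int],
           size: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    m[sl] = True
    return m


@dataclass(frozen=True)
class VolumeGeometry:
    """Cuboid seed/target layout inside a voxel-index grid (no affine)."""

    shape: tuple[int, int, int] = (24, 24, 12)
    seed_size: tuple[int, int, int] = (3, 3, 3)
    seed_left_corner: tuple[int, int, int] = (3, 5, 4)
    seed_right_corner: tuple[int, int, int] = (18, 5, 4)
    target_corner: tuple[int, int, int] = (10, 15, 5)
    target_size: tuple[int, int, int] = (4, 4, 3)

    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        left = _block(self.shape, self.seed_left_corner, self.seed_size)
        right = _block(self.shape, self.seed_right_corner, self.seed_size)
        target = _block(self.shape, self.target_corner, self.target_size)
        if np.any(left & right):
            raise ValueError("seed masks overlap")
        return left, right, target


@dataclass
class VolumeGrid:
    """One subject's 4D series plus seed and target masks (voxel space)."""

    data: np.ndarray  # (x, y, z, t)
    seed_left: np.ndarray
    seed_right: np.ndarray
    target_mask: np.ndarray
    tr_seconds: float = 2.3

    def __post_init__(self) -> None:
        sp = self.data.shape[:3]
        for name in ("seed_left", "seed_right", "target_mask"):
            m = getattr(self, name)
            if m.shape != sp:
                raise ValueError(f"{name} shape {m.shape} != data spatial shape {sp}")
            if not m.any():
                raise ValueError(f"{name} is empty")
        if np.any(self.seed_left & self.seed_right):
            raise ValueError("seed masks must be disjoint")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class CouplingSpec:
    """How target coupling scales with a cohort covariate:
    beta_s = baseline + effect * (covariate_s - cohort mean)."""

    covariate: str = "metacog_bias"
    baseline: float = 0.4
    effect: float = 0.0


def simulate_volume_cohort(
    cohort: pd.DataFrame,
    geometry: VolumeGeometry = VolumeGeometry(),
    coupling: CouplingSpec = CouplingSpec(),
    noise_sd: float = 1.0,
    n_timepoints: int = 120,
    latent_smooth_tr: float = 2.0,
    seed: int = 0,
) -> list[VolumeGrid]:
    """Simulate one 4D volume per subject.

    Both seed regions carry a shared smooth latent time series (temporally
    smoothed, standardised white noise) plus independent voxel noise; target
    voxels follow beta_s x latent plus noise, with beta_s set by the subject's
    covariate; all remaining voxels are pure noise.
    """
    if coupling.covariate not in cohort.columns:
        raise KeyError(f"covariate {coupling.covariate!r} not in cohort table")
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    left, right, target = geometry.masks()
    cov = cohort[coupling.covariate].to_numpy(dtype=float)
    betas = coupling.baseline + coupling.effect * (cov - cov.mean())
    rng = np.random.default_rng(seed)
    grids: list[VolumeGrid] = []
    for beta in betas:
        latent = gaussian_filter1d(rng.standard_normal(n_timepoints), latent_smooth_tr)
        latent = (latent - latent.mean()) / latent.std()
        data = np.zeros(geometry.shape + (n_timepoints,))
        if noise_sd > 0:
            data += rng.normal(0.0, noise_sd, size=data.shape)
        else:
            # keep the RNG stream aligned so noise_sd=0 stays comparable
            rng.normal(0.0, 1.0, size=data.shape)
        data[left | right] += latent
        data[target] += beta * latent
        grids.append(VolumeGrid(data, left, right, target))
    return grids


def save_volume(grid: VolumeGrid, prefix: str | Path) -> None:
    """Write data as <prefix>.nii.gz and masks as <prefix>_masks.nii.gz
    (integer labels: 1 = left seed, 2 = right seed, 3 = target)."""
    prefix = Path(prefix)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(grid.data.astype(np.float32), affine),
             str(prefix) + ".nii.gz")
    labels = np.zeros(grid.data.shape[:3], dtype=np.int16)
    labels[grid.seed_left] = 1
    labels[grid.seed_right] = 2
    labels[grid.target_mask] = 3
    nib.save(nib.Nifti1Image(labels, affine), str(prefix) + "_masks.nii.gz")


def load_volume(prefix: str | Path, tr_seconds: float = 2.3) -> VolumeGrid:
    prefix = Path(prefix)
    data = np.asarray(nib.load(str(prefix) + ".nii.gz").dataobj, dtype=float)
    labels = np.asarray(nib.load(str(prefix) + "_masks.nii.gz").dataobj)
    return VolumeGrid(
        data, labels == 1, labels == 2, labels == 3, tr_seconds=tr_seconds
    )
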