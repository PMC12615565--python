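"""Seed-based functional-connectivity inference on synthetic volumes.

The chain mirrors a standard resting-state seed analysis: a seed region's
mean time series (mask thresholded at 90% probability) is regressed against
every voxel alongside its temporal derivative (first level); left- and
right-seed coupling maps are combined voxel-wise by fixed effects
(inverse-variance weighted mean, plus L-R difference contrasts); the subject
maps then enter a group GLM whose explanatory variables are demeaned and
split by gender, optionally with a trait-anxiety covariate; and inference is
by permutation of the group model (Freedman-Lane residual scheme) with
threshold-free cluster enhancement and family-wise error correction from the
max-statistic null.

Everything operates in voxel-index space; registration/atlas handling is out
of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.linalg import null_space

from .synthetic_data import VolumeGrid

__all__ = [
    "FirstLevelMap",
    "GroupDesign",
    "TFCEResult",
    "extract_seed_series",
    "first_level_fc",
    "fixed_effects_hemispheres",
    "build_group_design",
    "group_contrast_tmap",
    "tfce",
    "permutation_fwe",
]


@dataclass
class FirstLevelMap:
    beta: np.ndarray  # 3D coupling to the seed regressor
    variance: np.ndarray  # 3D sampling variance of beta
    z: np.ndarray  # 3D z-statistic
    regressors: tuple[str, ...] = ("intercept", "seed", "seed_derivative")


@dataclass
class GroupDesign:
    X: np.ndarray  # subjects x EVs
    ev_names: list[str]
    contrasts: dict[str, np.ndarray]
    covariate_set: str


@dataclass
class TFCEResult:
    enhanced: np.ndarray
    E: float
    H: float
    dh: float
    neighbourhood: int
    stat_map: np.ndarray | None = None
    fwe_p: np.ndarray | None = None
    n_permutations: int = 0
    perm_max_null: np.ndarray | None = field(default=None, repr=False)


def extract_seed_series(
    volume: VolumeGrid | np.ndarray,
    seed_mask: np.ndarray,
    probability_threshold: float = 0.90,
) -> np.ndarray:
    """Mean time series over the in-mask voxels.

    ``seed_mask`` may be probabilistic; it is thresholded at
    ``probability_threshold`` and binarised first (boolean masks pass
    through unchanged since True >= 0.9)."""
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    binary = np.asarray(seed_mask, dtype=float) >= probability_threshold
    n_vox = int(binary.sum())
    if n_vox == 0:
        raise ValueError(
            f"seed mask empty after thresholding at {probability_threshold} "
            f"(0 of {seed_mask.size} voxels survive)"
        )
    return data[binary].mean(axis=0)


def _temporal_derivative(series: np.ndarray) -> np.ndarray:
    deriv = np.zeros_like(series)
    deriv[1:] = np.diff(series)
    return deriv


def first_level_fc(volume: VolumeGrid, seed_series: np.ndarray) -> FirstLevelMap:
    """Voxel-wise GLM of the volume on [intercept, seed, seed derivative].

    ``beta``/``z`` refer to the seed regressor."""
    series = np.asarray(seed_series, dtype=float)
    T = volume.n_timepoints
    if series.shape != (T,):
        raise ValueError(f"seed series length {series.shape} != {T} timepoints")
    if np.ptp(series) == 0:
        raise ValueError("seed series is constant: design is rank deficient")
    X = np.column_stack([np.ones(T), series, _temporal_derivative(series)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient first-level design")
    shape = volume.data.shape[:3]
    Y = volume.data.reshape(-1, T).T  # (T, V)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    df = T - X.shape[1]
    sigma2 = np.einsum("tv,tv->v", resid, resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    var_beta = sigma2 * xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_beta > 0, B[1] / np.sqrt(var_beta), 0.0)
    z = _t_to_z(t, df)
    return FirstLevelMap(
        beta=B[1].reshape(shape),
        variance=var_beta.reshape(shape),
        z=z.reshape(shape),
    )


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t-statistics to z-scores through matched tail probabilities."""
    z = np.empty_like(t, dtype=float)
    pos = t >= 0
    z[pos] = -stats.norm.ppf(np.clip(stats.t.sf(t[pos], df), 1e-300, 1.0))
    z[~pos] = stats.norm.ppf(np.clip(stats.t.cdf(t[~pos], df), 1e-300, 1.0))
    return z


def fixed_effects_hemispheres(
    left: FirstLevelMap, right: FirstLevelMap
) -> dict[str, FirstLevelMap]:
    """Voxel-wise fixed-effects combination of the two hemisphere-seed maps.

    Returns the inverse-variance weighted mean map plus the two difference
    contrasts (L-R and R-L).  Zero-variance voxels (noiseless inputs) fall
    back to an unweighted average."""
    if left.beta.shape != right.beta.shape:
        raise ValueError("hemisphere maps have mismatched shapes")
    eps = 1e-30
    wl = 1.0 / np.maximum(left.variance, eps)
    wr = 1.0 / np.maximum(right.variance, eps)
    mean_beta = (wl * left.beta + wr * right.beta) / (wl + wr)
    mean_var = 1.0 / (wl + wr)
    diff = left.beta - right.beta
    diff_var = left.variance + right.variance
    with np.errstate(divide="ignore", invalid="ignore"):
        z_mean = np.where(mean_var > 0, mean_beta / np.sqrt(mean_var), 0.0)
        z_diff = np.where(diff_var > 0, diff / np.sqrt(diff_var), 0.0)
    fe = ("fixed_effects",)
    return {
        "mean": FirstLevelMap(mean_beta, mean_var, z_mean, fe),
        "left_minus_right": FirstLevelMap(diff, diff_var, z_diff, fe),
        "right_minus_left": FirstLevelMap(-diff, diff_var, -z_diff, fe),
    }


def build_group_design(
    cohort: pd.DataFrame,
    measure_name: str,
    covariate_set: str = "measure_only",
) -> GroupDesign:
    """Group-level design with gender-split, demeaned explanatory variables.

    EVs: male intercept, female intercept, the measure demeaned within males
    (zero for females) and within females (zero for males); with
    ``covariate_set='measure_plus_gad7'`` two further gender-split GAD-7 EVs
    control for trait anxiety.  Contrasts: positive and negative main effect
    of the measure (summed over genders) and the gender interaction."""
    if measure_name not in cohort.columns:
        raise KeyError(f"measure {measure_name!r} not in cohort")
    if covariate_set not in ("measure_only", "measure_plus_gad7"):
        raise ValueError(f"unknown covariate_set {covariate_set!r}")
    male = (cohort["gender"] == "M").to_numpy()
    female = (cohort["gender"] == "F").to_numpy()

    def split_demean(col: str) -> tuple[np.ndarray, np.ndarray]:
        v = cohort[col].to_numpy(dtype=float)
        ev_m, ev_f = np.zeros_like(v), np.zeros_like(v)
        if male.any():
            ev_m[male] = v[male] - v[male].mean()
        if female.any():
            ev_f[female] = v[female] - v[female].mean()
        return ev_m, ev_f

    ev_m, ev_f = split_demean(measure_name)
    cols = [male.astype(float), female.astype(float), ev_m, ev_f]
    names = ["intercept_male", "intercept_female",
             f"{measure_name}_male", f"{measure_name}_female"]
    if covariate_set == "measure_plus_gad7":
        g_m, g_f = split_demean("gad7")
        cols += [g_m, g_f]
        names += ["gad7_male", "gad7_female"]
    X = np.column_stack(cols)
    p = X.shape[1]

    def c(weights: dict[str, float]) -> np.ndarray:
        v = np.zeros(p)
        for k, w in weights.items():
            v[names.index(k)] = w
        return v

    mm, mf = f"{measure_name}_male", f"{measure_name}_female"
    contrasts = {
        "measure_positive": c({mm: 1.0, mf: 1.0}),
        "measure_negative": c({mm: -1.0, mf: -1.0}),
    }
    if male.any() and female.any():
        contrasts["gender_interaction"] = c({mm: 1.0, mf: -1.0})
    else:
        warnings.warn("single-gender cohort: gender interaction contrast omitted")
        # drop the all-zero EVs of the absent gender to keep the design full rank
        keep = [i for i in range(p) if np.any(X[:, i])]
        X = X[:, keep]
        names = [names[i] for i in keep]
        contrasts = {k: v[keep] for k, v in contrasts.items()}
    return GroupDesign(X=X, ev_names=names, contrasts=contrasts,
                       covariate_set=covariate_set)


def _contrast_partition(X: np.ndarray, contrast: np.ndarray):
    """Rotate the design so the contrast is a single interest regressor.

    Returns (interest column, nuisance block) per the usual partitioning:
    X1 = X c (c'c)^-1, Z = X N with N a basis of the null space of c'."""
    c = np.asarray(contrast, dtype=float).reshape(-1)
    X1 = X @ (c / (c @ c))
    N = null_space(c[None, :])
    Z = X @ N
    # drop numerically null nuisance columns
    keep = np.linalg.norm(Z, axis=0) > 1e-10 * max(1.0, np.linalg.norm(X))
    return X1[:, None], Z[:, keep]


def group_contrast_tmap(
    maps: np.ndarray, design: GroupDesign, contrast: str | np.ndarray
) -> np.ndarray:
    """Ordinary-least-squares group t-map for a contrast.

    ``maps``: array (subjects, x, y, z) of fixed-effects coupling maps."""
    c = design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast)
    n = maps.shape[0]
    Y = maps.reshape(n, -1)
    t, _ = _ols_contrast_t(design.X, c, Y)
    return t.reshape(maps.shape[1:])


def _ols_precompute(X: np.ndarray, c: np.ndarray):
    pinv = np.linalg.pinv(X)
    df = X.shape[0] - np.linalg.matrix_rank(X)
    g = float(c @ np.linalg.pinv(X.T @ X) @ c)
    return pinv, df, g


def _ols_contrast_t(X: np.ndarray, c: np.ndarray, Y: np.ndarray, pre=None):
    pinv, df, g = pre if pre is not None else _ols_precompute(X, c)
    B = pinv @ Y
    resid = Y - X @ B
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sigma2 * g > 0, (c @ B) / np.sqrt(sigma2 * g), 0.0)
    return t, df


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


def _threshold_stack_structure(neighbourhood: int) -> np.ndarray:
    """4D label structure: spatial connectivity within a threshold slab,
    no connectivity across slabs (so one label() call handles all steps)."""
    s = np.zeros((3, 3, 3, 3), dtype=bool)
    s[1] = _STRUCTURES[neighbourhood]
    return s


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    neighbourhood: int = 26,
) -> TFCEResult:
    """Threshold-free cluster enhancement of a (positive-excursion) map.

    enhanced(p) = sum over thresholds h = dh, 2dh, ... <= stat(p) of
    extent(h, p)^E * h^H * dh, with extent the size of the connected
    suprathreshold component containing p.  Negative-direction inference is
    done by enhancing the negated map separately."""
    stat = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    if neighbourhood not in _STRUCTURES:
        raise ValueError("neighbourhood must be 6, 18 or 26")
    peak = float(stat.max(initial=0.0))
    enhanced = np.zeros_like(stat)
    if peak <= 0:
        return TFCEResult(enhanced, E, H, dh or 0.0, neighbourhood, stat_map=stat)
    if dh is None:
        dh = peak / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    heights = np.arange(dh, peak + 1e-12, dh)
    # all thresholds at once: stack suprathreshold masks along a leading axis
    # and label with no connectivity across it (the tiny slack keeps the peak
    # voxel inside its own top step despite float rounding)
    stack = stat[None, ...] >= (heights - 1e-9 * peak)[:, None, None, None]
    labels, n_lab = ndimage.label(stack, structure=_threshold_stack_structure(neighbourhood))
    if n_lab:
        sizes = np.bincount(labels.ravel()).astype(float)
        sizes[0] = 0.0
        contrib = sizes[labels] ** E * (heights**H * dh)[:, None, None, None]
        contrib[~stack] = 0.0
        enhanced = contrib.sum(axis=0)
    return TFCEResult(enhanced, E, H, dh, neighbourhood, stat_map=stat)


def permutation_fwe(
    maps: np.ndarray,
    design: GroupDesign,
    contrast: str | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    neighbourhood: int = 26,
    scheme: str = "freedman_lane",
) -> TFCEResult:
    """Permutation FWE inference on the TFCE-enhanced group contrast.

    The observed contrast t-map is TFCE-enhanced; the null distribution of
    the image-wide maximum enhancement is built by permuting reduced-model
    residuals (Freedman-Lane) or raw rows (``scheme='rows'``), and the
    per-voxel FWE p-value is the plus-one permutation estimator
    (1 + #{max_perm >= enhanced}) / (1 + n_perm)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    c = design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast)
    n = maps.shape[0]
    if n < design.X.shape[1] + 2:
        raise ValueError("too few subjects for the design")
    shape = maps.shape[1:]
    Y = maps.reshape(n, -1)
    X1, Z = _contrast_partition(design.X, c)
    Xf = np.hstack([X1, Z])
    c_full = np.zeros(Xf.shape[1])
    c_full[0] = 1.0
    pre = _ols_precompute(Xf, c_full)
    t_obs, _ = _ols_contrast_t(Xf, c_full, Y, pre)
    obs = tfce(t_obs.reshape(shape), E, H, dh, neighbourhood)

    rng = np.random.default_rng(seed)
    if math.factorial(n) <= n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations available; "
            "enumerating exhaustively"
        )
        perms = [np.array(p) for p in iter_permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    if Z.shape[1]:
        Hz = Z @ np.linalg.pinv(Z)
        fitted_z = Hz @ Y
        resid_z = Y - fitted_z
    else:
        fitted_z = np.zeros_like(Y)
        resid_z = Y
    max_null = np.empty(len(perms))
    for i, perm in enumerate(perms):
        if scheme == "freedman_lane":
            y_star = fitted_z + resid_z[perm]
        elif scheme == "rows":
            y_star = Y[perm]
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        t_perm, _ = _ols_contrast_t(Xf, c_full, y_star, pre)
        enh = tfce(t_perm.reshape(shape), E, H, dh, neighbourhood)
        max_null[i] = enh.enhanced.max()
    fwe_p = (1.0 + (max_null[None, :] >= obs.enhanced.reshape(-1, 1)).sum(axis=1)) / (
        1.0 + len(perms)
    )
    return TFCEResult(
        enhanced=obs.enhanced,
        E=E, H=H, dh=obs.dh, neighbourhood=neighbourhood,
        stat_map=t_obs.reshape(shape),
        fwe_p=fwe_p.reshape(shape),
        n_permutations=len(perms),
        perm_max_null=max_null,
    )
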