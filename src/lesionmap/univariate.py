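"""Mass-univariate voxel-based lesion-symptom mapping (VLSM).

At every voxel lesioned in at least ``min_lesioned`` subjects (and intact in
at least ``min_intact``), the behavioral outcome is regressed on
[intercept, lesion indicator, covariates] and the lesion coefficient's
t-value is stored. Familywise error is controlled by a max-statistic
permutation test that shuffles the outcome across subjects while holding
lesions and covariates fixed; a cluster-extent null at a primary uncorrected
threshold is recorded alongside.

The per-voxel fit uses Frisch-Waugh residualization: outcome and lesion
columns are projected off the covariate space once, after which each
permutation refit is a single matrix product over all voxels.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import DEFAULT_COVARIATES, build_covariates, drop_constant_columns
from .mask import LesionMask, check_same_grid

__all__ = [
    "DesignSpec",
    "StatMap",
    "Cluster",
    "PermutationResult",
    "SubgroupResult",
    "voxelwise_glm",
    "permutation_correct",
    "extract_clusters",
    "clusters_from_mask",
    "subgroup_rerun",
]

log = logging.getLogger(__name__)

_PERM_CHUNK = 128  # permutations processed per matrix product


@dataclass(frozen=True)
class DesignSpec:
    """Outcome, covariates, inclusion threshold and permutation settings."""

    outcome: str = "self_generated"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    min_lesioned: int = 5
    min_intact: int = 2
    n_permutations: int = 1000
    alpha: float = 0.05
    tail: str = "lower"  # "lower" (damage -> deficit) or "two-sided"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_lesioned < 2:
            raise ValueError("min_lesioned must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tail not in ("lower", "two-sided"):
            raise ValueError(f"tail must be 'lower' or 'two-sided', got {self.tail!r}")


@dataclass
class StatMap:
    """Voxelwise t-map with inclusion bookkeeping and cached refit state."""

    stat: np.ndarray  # 3-D float, NaN outside the inclusion mask
    inclusion: np.ndarray  # 3-D bool
    counts: np.ndarray  # 3-D int, per-voxel lesioned-subject counts
    affine: np.ndarray
    df: int = 0
    n_excluded_rank: int = 0
    # cached pieces enabling fast permutation refits
    _incl_flat: np.ndarray | None = field(default=None, repr=False)
    _Xr: np.ndarray | None = field(default=None, repr=False)
    _sxx: np.ndarray | None = field(default=None, repr=False)
    _Q: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_included(self) -> int:
        return int(self.inclusion.sum())


@dataclass(frozen=True)
class Cluster:
    """A face-connected component of suprathreshold voxels."""

    voxels: np.ndarray  # (k, 3) int indices
    volume_cm3: float
    center_of_mass_mm: np.ndarray
    peak_stat: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def to_mask(self, shape: tuple[int, int, int], affine: np.ndarray) -> LesionMask:
        data = np.zeros(shape, dtype=bool)
        data[tuple(self.voxels.T)] = True
        return LesionMask(data, affine)


@dataclass
class PermutationResult:
    """Null distributions and per-voxel FWER p-values from permutation."""

    fwer_p: np.ndarray  # 3-D, NaN outside inclusion
    significant: np.ndarray  # 3-D bool, fwer_p <= alpha
    critical_t: float  # t-scale critical value at 1 - alpha
    primary_threshold_t: float  # cluster-forming uncorrected threshold
    cluster_extent_critical: int  # voxels; null (1 - alpha) quantile
    null_max_score: np.ndarray
    null_max_cluster: np.ndarray
    n_permutations_used: int
    exhaustive: bool
    alpha: float
    tail: str


def _lesion_matrix(masks: list[LesionMask]) -> np.ndarray:
    return np.stack([m.data.ravel() for m in masks]).astype(float)


def _score(t: np.ndarray, tail: str) -> np.ndarray:
    """Exceedance score: larger means more significant in the tested direction."""
    return -t if tail == "lower" else np.abs(t)


def _t_from_residualized(
    Xr: np.ndarray, sxx: np.ndarray, Yr: np.ndarray, df: int, y_sq: np.ndarray
) -> np.ndarray:
    """t of the lesion coefficient for each voxel (rows) x outcome (cols).

    ``y_sq`` carries the pre-projection sum of squares per outcome column so
    outcomes that are constant up to float residue yield t = 0, not 0/0 noise.
    """
    num = Xr.T @ Yr
    b = num / sxx[:, None]
    yty = np.einsum("ij,ij->j", Yr, Yr)
    rss = np.maximum(yty[None, :] - b * num, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx[:, None])
        t = b / se
    t[np.isnan(t)] = 0.0  # 0/0: constant outcome after projection
    t[:, yty <= y_sq * 1e-20] = 0.0
    return t


def voxelwise_glm(
    masks: list[LesionMask],
    behavior: pd.DataFrame,
    spec: DesignSpec,
) -> StatMap:
    """Fit the per-voxel GLM and return the lesion-coefficient t-map.

    Voxels where the lesion indicator is collinear with the covariates are
    excluded (NaN) and counted in ``n_excluded_rank``. A rank-deficient
    covariate design excludes every voxel.
    """
    check_same_grid(masks)
    if len(behavior) != len(masks):
        raise ValueError(
            f"behavior rows ({len(behavior)}) do not match masks ({len(masks)})"
        )
    n = len(masks)
    shape = masks[0].shape
    affine = masks[0].affine
    vox_mm3 = masks[0].voxel_volume_mm3

    X = _lesion_matrix(masks)
    counts = X.sum(axis=0).astype(int)
    incl = (counts >= spec.min_lesioned) & ((n - counts) >= spec.min_intact)

    y = behavior[spec.outcome].to_numpy(dtype=float)
    C = build_covariates(behavior, spec.covariates)
    C, _ = drop_constant_columns(C, spec.covariates)
    Z = np.column_stack([np.ones(n), C])
    p_full = Z.shape[1] + 1  # + lesion column
    df = n - p_full

    stat = np.full(np.prod(shape), np.nan)
    statmap = StatMap(
        stat=stat.reshape(shape),
        inclusion=np.zeros(shape, dtype=bool),
        counts=counts.reshape(shape),
        affine=affine,
        df=max(df, 0),
    )

    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        log.warning(
            "covariate design is rank deficient; all %d candidate voxels excluded",
            int(incl.sum()),
        )
        statmap.n_excluded_rank = int(incl.sum())
        return statmap
    if df <= 0:
        raise ValueError(
            f"not enough subjects ({n}) for {p_full} design columns"
        )

    incl_flat = np.flatnonzero(incl)
    if incl_flat.size == 0:
        log.warning("no voxel meets the inclusion thresholds")
        return statmap

    Q, _ = np.linalg.qr(Z)
    Xi = X[:, incl_flat]
    Xr = Xi - Q @ (Q.T @ Xi)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    ok = sxx > 1e-10 * n
    n_rank = int((~ok).sum())
    if n_rank:
        log.warning("%d voxels excluded: lesion column collinear with covariates", n_rank)
    incl_flat = incl_flat[ok]
    Xr = Xr[:, ok]
    sxx = sxx[ok]

    yr = (y - Q @ (Q.T @ y))[:, None]
    t = _t_from_residualized(Xr, sxx, yr, df, np.array([y @ y]))[:, 0]

    stat[incl_flat] = t
    inclusion = np.zeros(np.prod(shape), dtype=bool)
    inclusion[incl_flat] = True

    statmap.stat = stat.reshape(shape)
    statmap.inclusion = inclusion.reshape(shape)
    statmap.n_excluded_rank = n_rank
    statmap.df = df
    statmap._incl_flat = incl_flat
    statmap._Xr = Xr
    statmap._sxx = sxx
    statmap._Q = Q
    statmap._y = y
    statmap.voxel_volume_mm3 = vox_mm3  # type: ignore[attr-defined]
    return statmap


def _permutation_indices(
    n: int, n_permutations: int, seed: int
) -> tuple[np.ndarray, bool]:
    """Permutation index matrix; exhaustive when n! fits in the budget."""
    n_distinct = math.factorial(n)
    if n_distinct <= n_permutations:
        log.info(
            "n_permutations=%d >= %d distinct permutations; enumerating exhaustively",
            n_permutations,
            n_distinct,
        )
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])
    return perms, False


def _max_cluster_size(
    exceed_cols: np.ndarray, incl_flat: np.ndarray, shape: tuple[int, ...]
) -> np.ndarray:
    """Largest face-connected suprathreshold component per column."""
    struct = ndimage.generate_binary_structure(3, 1)
    out = np.zeros(exceed_cols.shape[1], dtype=int)
    vol = np.zeros(shape, dtype=bool)
    for b in range(exceed_cols.shape[1]):
        vol.ravel()[incl_flat] = exceed_cols[:, b]
        labels, n_lab = ndimage.label(vol, structure=struct)
        if n_lab:
            out[b] = int(np.bincount(labels.ravel())[1:].max())
        vol.ravel()[incl_flat] = False
    return out


def permutation_correct(statmap: StatMap, spec: DesignSpec) -> PermutationResult:
    """Max-statistic FWER correction with a cluster-extent null.

    Each permutation shuffles the outcome vector (lesions and covariates
    fixed) and refits the map. P-values follow the (B+1)-denominator
    convention for sampled permutations and exact counts under exhaustive
    enumeration.
    """
    if statmap._Xr is None or statmap._y is None:
        raise ValueError("statmap lacks refit state; produce it with voxelwise_glm")
    shape = statmap.stat.shape
    n = len(statmap._y)
    incl_flat = statmap._incl_flat
    tail = spec.tail

    fwer_p = np.full(shape, np.nan)
    if incl_flat is None or incl_flat.size == 0:
        return PermutationResult(
            fwer_p=fwer_p,
            significant=np.zeros(shape, dtype=bool),
            critical_t=np.nan,
            primary_threshold_t=np.nan,
            cluster_extent_critical=0,
            null_max_score=np.array([]),
            null_max_cluster=np.array([], dtype=int),
            n_permutations_used=0,
            exhaustive=False,
            alpha=spec.alpha,
            tail=tail,
        )

    t_obs = statmap.stat.ravel()[incl_flat]
    s_obs = _score(t_obs, tail)
    # ties with the observed statistic (e.g. permutations that only reorder
    # within groups) must count as exceedances; tolerate float-level noise
    s_tie = s_obs - 1e-10 * (1.0 + np.abs(s_obs))

    df = statmap.df
    if tail == "lower":
        primary_t = float(stats.t.ppf(spec.alpha, df))
    else:
        primary_t = float(abs(stats.t.ppf(spec.alpha / 2.0, df)))
    primary_score = _score(np.array([primary_t]), tail)[0]

    perms, exhaustive = _permutation_indices(n, spec.n_permutations, spec.seed)
    B = len(perms)
    null_max_score = np.empty(B)
    null_max_cluster = np.empty(B, dtype=int)
    exceed_count = np.zeros(incl_flat.size)

    y = statmap._y
    Q = statmap._Q
    for start in range(0, B, _PERM_CHUNK):
        idx = perms[start : start + _PERM_CHUNK]
        Y = y[idx.T]  # (n, chunk)
        Yr = Y - Q @ (Q.T @ Y)
        T = _t_from_residualized(
            statmap._Xr, statmap._sxx, Yr, df, np.full(Y.shape[1], y @ y)
        )
        S = _score(T, tail)
        m = S.max(axis=0)
        null_max_score[start : start + len(idx)] = m
        exceed_count += (m[None, :] >= s_tie[:, None]).sum(axis=1)
        null_max_cluster[start : start + len(idx)] = _max_cluster_size(
            S >= primary_score, incl_flat, shape
        )

    if exhaustive:
        p_vox = exceed_count / B
    else:
        p_vox = (1.0 + exceed_count) / (B + 1.0)

    fwer_p.ravel()[incl_flat] = p_vox
    significant = np.zeros(np.prod(shape), dtype=bool)
    significant[incl_flat] = p_vox <= spec.alpha

    score_crit = float(np.quantile(null_max_score, 1.0 - spec.alpha))
    critical_t = -score_crit if tail == "lower" else score_crit
    cluster_crit = int(np.ceil(np.quantile(null_max_cluster, 1.0 - spec.alpha)))

    return PermutationResult(
        fwer_p=fwer_p,
        significant=significant.reshape(shape),
        critical_t=critical_t,
        primary_threshold_t=primary_t,
        cluster_extent_critical=cluster_crit,
        null_max_score=null_max_score,
        null_max_cluster=null_max_cluster,
        n_permutations_used=B,
        exhaustive=exhaustive,
        alpha=spec.alpha,
        tail=tail,
    )


def clusters_from_mask(
    data: np.ndarray, affine: np.ndarray, stat: np.ndarray | None = None, tail: str = "lower"
) -> list["Cluster"]:
    """Face-connected components of a boolean volume, largest first."""
    struct = ndimage.generate_binary_structure(3, 1)
    labels, n_lab = ndimage.label(np.asarray(data, dtype=bool), structure=struct)
    vox_mm3 = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    clusters = []
    for lab in range(1, n_lab + 1):
        voxels = np.argwhere(labels == lab)
        homog = np.c_[voxels, np.ones(len(voxels))]
        com = (np.asarray(affine) @ homog.T).T[:, :3].mean(axis=0)
        if stat is not None:
            vals = stat[tuple(voxels.T)]
            peak = float(np.nanmin(vals) if tail == "lower" else np.nanmax(np.abs(vals)))
        else:
            peak = float("nan")
        clusters.append(
            Cluster(
                voxels=voxels,
                volume_cm3=len(voxels) * vox_mm3 / 1000.0,
                center_of_mass_mm=com,
                peak_stat=peak,
            )
        )
    clusters.sort(key=lambda c: (-c.n_voxels, c.peak_stat))
    return clusters


def extract_clusters(statmap: StatMap, threshold: float, tail: str = "lower") -> list[Cluster]:
    """Threshold the t-map and return face-connected clusters, largest first.

    For the lower tail, voxels with ``t <= threshold`` exceed; for
    two-sided, ``|t| >= threshold``.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    with np.errstate(invalid="ignore"):
        if tail == "lower":
            exceed = statmap.stat <= threshold
        else:
            exceed = np.abs(statmap.stat) >= threshold
    exceed &= statmap.inclusion
    return clusters_from_mask(exceed, statmap.affine, stat=statmap.stat, tail=tail)


@dataclass
class SubgroupResult:
    statmap: StatMap
    permutation: PermutationResult
    clusters: list[Cluster]
    significant_mask: LesionMask
    dice: float
    center_of_mass_distance_mm: float


def subgroup_rerun(
    masks: list[LesionMask],
    behavior: pd.DataFrame,
    keep: np.ndarray,
    spec: DesignSpec,
    reference_cluster: LesionMask,
) -> SubgroupResult:
    """Re-run the VLSM on a cohort subset and compare against a reference cluster.

    ``keep`` is a boolean vector over subjects. Reports the Dice overlap and
    the Euclidean distance between centers of mass (of the largest
    significant cluster) against ``reference_cluster``.
    """
    from .cohort import dice as _dice  # local import avoids a cycle

    keep = np.asarray(keep, dtype=bool)
    if keep.sum() == 0:
        raise ValueError("subgroup filter keeps no subjects")
    if keep.sum() < spec.min_lesioned + 2:
        raise ValueError(
            f"subgroup of {int(keep.sum())} subjects is below min_lesioned + 2"
        )
    sub_masks = [m for m, k in zip(masks, keep) if k]
    sub_behavior = behavior.loc[keep].reset_index(drop=True)

    statmap = voxelwise_glm(sub_masks, sub_behavior, spec)
    perm = permutation_correct(statmap, spec)
    sig_mask = LesionMask(perm.significant, statmap.affine)
    clusters = clusters_from_mask(perm.significant, statmap.affine, statmap.stat, spec.tail)

    d = _dice(sig_mask, reference_cluster)
    if clusters and reference_cluster.n_voxels > 0:
        com_sub = clusters[0].center_of_mass_mm
        com_ref = reference_cluster.center_of_mass_mm()
        dist = float(np.linalg.norm(com_sub - com_ref))
    else:
        dist = float("nan")
    return SubgroupResult(
        statmap=statmap,
        permutation=perm,
        clusters=clusters,
        significant_mask=sig_mask,
        dice=d,
        center_of_mass_distance_mm=dist,
    )
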