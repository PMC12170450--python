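"""Multivariate lesion-symptom mapping via support vector regression.

Nuisance covariates are regressed out of the behavioral outcome, each
subject's binary lesion row is scaled by 1/sqrt(lesion size) (direct total
lesion volume control), and a single epsilon-SVR over all included voxels is
fit. Voxel weights are the dual-coefficient back-projection
``w_v = sum_i alpha_i x_iv`` — the exact primal weight for the linear kernel
and a sensitivity map for rbf. Voxelwise significance comes from refitting
under outcome permutations with fixed hyperparameters.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel
from sklearn.svm import SVR

from .design import DEFAULT_COVARIATES, build_covariates, drop_constant_columns
from .mask import LesionMask, check_same_grid
from .univariate import Cluster, clusters_from_mask, _lesion_matrix

__all__ = [
    "MlsmSpec",
    "WeightMap",
    "MlsmResult",
    "residualize",
    "dtlvc",
    "fit_svr_map",
    "mlsm_permute",
    "run_mlsm",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MlsmSpec:
    """SVR hyperparameters plus inclusion/permutation settings.

    The linear kernel is the default because its back-projection equals the
    primal weight vector exactly; rbf is available for fidelity to the
    original toolbox family. The default C errs on the regularized side:
    with unit-norm dtlvc rows, larger C lets permuted fits interpolate the
    shuffled outcome, which washes out the permutation contrast.
    """

    kernel: str = "linear"
    C: float = 0.3
    epsilon: float = 0.1
    gamma: float = 1.0
    n_permutations: int = 1000
    min_lesioned: int = 5
    alpha: float = 0.05
    seed: int = 0
    tail: str = "two-sided"  # "two-sided" (|w|) or "lower" (damage -> negative w)
    outcome: str = "self_generated"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.min_lesioned < 2:
            raise ValueError("min_lesioned must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tail not in ("two-sided", "lower"):
            raise ValueError(f"tail must be 'two-sided' or 'lower', got {self.tail!r}")


@dataclass
class WeightMap:
    """Back-projected SVR weights on the brain grid."""

    weight: np.ndarray  # 3-D float, NaN outside inclusion
    inclusion: np.ndarray  # 3-D bool
    affine: np.ndarray
    _incl_flat: np.ndarray | None = field(default=None, repr=False)


def residualize(outcome: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of OLS of ``outcome`` on [intercept, covariates].

    The result is orthogonal to every covariate column and to the intercept.
    Raises on rank deficiency, naming the offending columns.
    """
    y = np.asarray(outcome, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != len(y):
        raise ValueError(f"covariate rows {C.shape[0]} != outcome length {len(y)}")
    Z = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify dependent columns via rank-revealing QR pivoting on growth
        bad = []
        kept = np.ones((len(y), 1))
        for j in range(C.shape[1]):
            trial = np.column_stack([kept, C[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(j)
            else:
                kept = trial
        raise ValueError(
            f"covariate matrix rank deficient; collinear columns (0-based): {bad}"
        )
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def dtlvc(lesions: np.ndarray) -> np.ndarray:
    """Direct total lesion volume control: scale rows by 1/sqrt(row sum).

    For a binary row this makes the Euclidean norm exactly 1, removing the
    lesion-size gradient from the feature space.
    """
    X = np.asarray(lesions, dtype=float)
    sizes = X.sum(axis=1)
    zero = np.flatnonzero(sizes == 0)
    if zero.size:
        raise ValueError(
            f"subject(s) {zero.tolist()} have no lesioned voxel among included voxels"
        )
    return X / np.sqrt(sizes)[:, None]


def _kernel(X: np.ndarray, spec: MlsmSpec) -> np.ndarray:
    if spec.kernel == "linear":
        return linear_kernel(X)
    return rbf_kernel(X, gamma=spec.gamma)


def _fit_weights_precomputed(
    K: np.ndarray, X: np.ndarray, y: np.ndarray, spec: MlsmSpec
) -> np.ndarray:
    """Fit epsilon-SVR on a precomputed kernel; back-project dual coefs."""
    svr = SVR(kernel="precomputed", C=spec.C, epsilon=spec.epsilon)
    svr.fit(K, y)
    if svr.support_.size == 0:
        return np.zeros(X.shape[1])
    return (svr.dual_coef_ @ X[svr.support_]).ravel()


def fit_svr_map(lesions_scaled: np.ndarray, outcome: np.ndarray, spec: MlsmSpec) -> np.ndarray:
    """Per-voxel back-projected SVR weights for one outcome vector.

    A degenerate (constant) outcome yields an all-zero map with a warning.
    """
    X = np.asarray(lesions_scaled, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if X.shape[1] < 1:
        raise ValueError("no included voxels")
    if np.ptp(y) == 0:
        warnings.warn("outcome is constant; returning an all-zero weight map")
        return np.zeros(X.shape[1])
    return _fit_weights_precomputed(_kernel(X, spec), X, y, spec)


def mlsm_permute(
    lesions_scaled: np.ndarray, outcome: np.ndarray, spec: MlsmSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-value per voxel for the observed weight.

    Two-sided by default: p = (1 + #{|w_perm| >= |w_obs|}) / (B + 1). With
    ``spec.tail == 'lower'`` the comparison is ``w_perm <= w_obs`` (damage
    drives weights negative). Returns ``(p, w_obs)``. Sampled permutations
    use the (B+1)-denominator convention; when n! fits within the budget all
    distinct permutations are enumerated and counts are exact.
    """
    X = np.asarray(lesions_scaled, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    K = _kernel(X, spec)
    w_obs = fit_svr_map(X, y, spec)

    n_distinct = math.factorial(n)
    if n_distinct <= spec.n_permutations:
        log.info("enumerating all %d permutations exhaustively", n_distinct)
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        exhaustive = True
    else:
        rng = np.random.default_rng(spec.seed)
        perms = np.stack([rng.permutation(n) for _ in range(spec.n_permutations)])
        exhaustive = False

    count = np.zeros(X.shape[1])
    for idx in perms:
        w_perm = _fit_weights_precomputed(K, X, y[idx], spec)
        if spec.tail == "lower":
            count += w_perm <= w_obs
        else:
            count += np.abs(w_perm) >= np.abs(w_obs)
    if exhaustive:
        p = count / len(perms)
    else:
        p = (1.0 + count) / (len(perms) + 1.0)
    return p, w_obs


@dataclass
class MlsmResult:
    weight_map: WeightMap
    p_map: np.ndarray  # 3-D, NaN outside inclusion
    significant: np.ndarray  # 3-D bool
    clusters: list[Cluster]
    n_subjects_zero_row: int


def run_mlsm(
    masks: list[LesionMask],
    behavior: pd.DataFrame,
    spec: MlsmSpec,
) -> MlsmResult:
    """Full SVR-MLSM pipeline on a harmonized cohort.

    Subjects whose lesion lies entirely outside the included voxels keep an
    all-zero (unscalable) feature row; they are counted and warned about
    rather than dropped, so the cohort stays aligned with the behavior table.
    """
    check_same_grid(masks)
    if len(behavior) != len(masks):
        raise ValueError("behavior rows do not match masks")
    shape = masks[0].shape
    affine = masks[0].affine

    X_full = _lesion_matrix(masks)
    counts = X_full.sum(axis=0)
    incl_flat = np.flatnonzero(counts >= spec.min_lesioned)
    if incl_flat.size == 0:
        raise ValueError("no voxel meets the lesion-count inclusion threshold")
    Xi = X_full[:, incl_flat]

    y = behavior[spec.outcome].to_numpy(dtype=float)
    C = build_covariates(behavior, spec.covariates)
    C, _ = drop_constant_columns(C, spec.covariates)
    y_resid = residualize(y, C)

    row_sizes = Xi.sum(axis=1)
    nonzero = row_sizes > 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        log.warning(
            "%d subject(s) have no lesioned voxel among included voxels; "
            "their feature rows stay zero",
            n_zero,
        )
    X_scaled = np.zeros_like(Xi)
    X_scaled[nonzero] = dtlvc(Xi[nonzero])

    p_flat, w_flat = mlsm_permute(X_scaled, y_resid, spec)

    weight = np.full(np.prod(shape), np.nan)
    weight[incl_flat] = w_flat
    p_map = np.full(np.prod(shape), np.nan)
    p_map[incl_flat] = p_flat
    inclusion = np.zeros(np.prod(shape), dtype=bool)
    inclusion[incl_flat] = True
    significant = np.zeros(np.prod(shape), dtype=bool)
    significant[incl_flat] = p_flat <= spec.alpha

    wm = WeightMap(
        weight=weight.reshape(shape),
        inclusion=inclusion.reshape(shape),
        affine=affine,
        _incl_flat=incl_flat,
    )
    sig3 = significant.reshape(shape)
    clusters = clusters_from_mask(sig3, affine, stat=weight.reshape(shape), tail=spec.tail)
    return MlsmResult(
        weight_map=wm,
        p_map=p_map.reshape(shape),
        significant=sig3,
        clusters=clusters,
        n_subjects_zero_row=n_zero,
    )
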