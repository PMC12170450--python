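"""LSM-ROI construction, subject classification, and cohort statistics.

Covers Dice overlap, cluster intersection, the 1.5-SD classification rules
for ROI resections and disproportionate self-generated-speech deficits,
2x2 contingency tables with relative-risk (Katz log CI) and odds-ratio
(Woolf log CI) estimates, Pearson chi-square independence tests, Mann-Whitney
rank-sum tests with exact small-sample enumeration, and per-region damage
percentages against a labeled atlas.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mask import LesionMask

__all__ = [
    "ContingencyTable",
    "EffectEstimate",
    "dice",
    "intersect_rois",
    "classify_roi_resection",
    "classify_deficit",
    "contingency",
    "relative_risk",
    "odds_ratio",
    "chi_square_independence",
    "rank_sum",
    "region_damage_percent",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: exposure = ROI resection, outcome = deficit."""

    a: int  # ROI resection and deficit
    b: int  # ROI resection, no deficit
    c: int  # no ROI resection, deficit
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    measure: str  # "RR" or "OR"
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError(
                f"inconsistent estimate: {self.ci_low} <= {self.point} <= {self.ci_high}"
            )


def dice(mask_a: LesionMask, mask_b: LesionMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 0 if both empty."""
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks are on different grids")
    na, nb = mask_a.n_voxels, mask_b.n_voxels
    if na + nb == 0:
        warnings.warn("both masks empty; Dice defined as 0")
        return 0.0
    inter = int(np.logical_and(mask_a.data, mask_b.data).sum())
    return 2.0 * inter / (na + nb)


def intersect_rois(cluster_a: LesionMask, cluster_b: LesionMask) -> LesionMask:
    """Voxelwise AND of two cluster masks (the LSM-ROI)."""
    if not cluster_a.same_grid(cluster_b):
        raise ValueError("cluster masks are on different grids")
    data = np.logical_and(cluster_a.data, cluster_b.data)
    if not data.any():
        warnings.warn("cluster intersection is empty")
    return LesionMask(data, cluster_a.affine)


def _sd_flags(values: np.ndarray, k: float = 1.5) -> tuple[np.ndarray, float]:
    """Flags for values >= mean + k * sample SD (ddof=1)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 subjects for an SD-based threshold")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        warnings.warn("zero standard deviation; no subject flagged")
        return np.zeros(len(values), dtype=bool), math.inf
    thr = float(np.mean(values)) + k * sd
    return values >= thr, thr


def classify_roi_resection(
    masks: list[LesionMask], lsm_roi: LesionMask
) -> tuple[np.ndarray, np.ndarray]:
    """Flag subjects whose resection Dice with the LSM-ROI is >= mean + 1.5 SD.

    Returns ``(flags, dsc)`` with the per-subject Dice vector.
    """
    dscs = np.array([dice(m, lsm_roi) for m in masks])
    flags, _ = _sd_flags(dscs)
    return flags, dscs


def classify_deficit(harmonized: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Flag disproportionate self-generated-speech deficits.

    d_i = overall_i - self_generated_i; flagged when d_i >= mean + 1.5 SD
    (threshold computed over the full cohort) and no apraxia of speech is
    present.
    """
    for col in ("overall", "self_generated", "aos_present"):
        if col not in harmonized.columns:
            raise ValueError(f"harmonized table lacks column {col!r}")
    d = (harmonized["overall"] - harmonized["self_generated"]).to_numpy(dtype=float)
    flags, _ = _sd_flags(d)
    aos = harmonized["aos_present"].to_numpy(dtype=bool)
    return flags & ~aos, d


def contingency(roi_flags: np.ndarray, deficit_flags: np.ndarray) -> ContingencyTable:
    """Cross-tabulate ROI-resection and deficit flags into a 2x2 table."""
    r = np.asarray(roi_flags, dtype=bool)
    s = np.asarray(deficit_flags, dtype=bool)
    if len(r) != len(s):
        raise ValueError("flag vectors differ in length")
    return ContingencyTable(
        a=int((r & s).sum()),
        b=int((r & ~s).sum()),
        c=int((~r & s).sum()),
        d=int((~r & ~s).sum()),
    )


def _z(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2.0))


def relative_risk(
    t: ContingencyTable, level: float = 0.95, continuity_correction: bool = False
) -> EffectEstimate:
    """Risk ratio [a/(a+b)] / [c/(c+d)] with the Katz log-method CI."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if continuity_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a + b == 0 or c + d == 0 or a == 0 or c == 0:
        raise ValueError(
            "relative risk undefined for zero margins or zero event counts; "
            "consider continuity_correction=True"
        )
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    z = _z(level)
    return EffectEstimate(
        measure="RR",
        point=rr,
        ci_low=math.exp(math.log(rr) - z * se),
        ci_high=math.exp(math.log(rr) + z * se),
        level=level,
    )


def odds_ratio(
    t: ContingencyTable, level: float = 0.95, continuity_correction: bool = False
) -> EffectEstimate:
    """Odds ratio ad/(bc) with the Woolf log-method CI."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if continuity_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ValueError(
            "odds ratio undefined with a zero cell; consider continuity_correction=True"
        )
    orr = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = _z(level)
    return EffectEstimate(
        measure="OR",
        point=orr,
        ci_low=math.exp(math.log(orr) - z * se),
        ci_high=math.exp(math.log(orr) + z * se),
        level=level,
    )


def chi_square_independence(
    labels_a: "pd.Series | np.ndarray | list",
    labels_b: "pd.Series | np.ndarray | list",
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on the r x c table.

    No continuity correction; levels with a zero marginal (possible with
    categorical inputs carrying unused categories) are dropped with a
    warning. Returns ``(statistic, df, p)``.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    table = pd.crosstab(a, b, dropna=False)
    zero_rows = table.sum(axis=1) == 0
    zero_cols = table.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn(
            f"dropping zero-marginal levels: rows {list(table.index[zero_rows])}, "
            f"cols {list(table.columns[zero_cols])}"
        )
        table = table.loc[~zero_rows, ~zero_cols]
    obs = table.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 levels on each variable")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p


#: exact enumeration is used when C(n, n_a) is at most this
_EXACT_LIMIT = 20000


def rank_sum(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (of group A) with midranks; two-sided p.

    Small samples (C(n, n_a) <= 20000) get an exact permutation p-value by
    enumerating group assignments: p = P(|U' - mu| >= |U - mu|) under the
    null, where mu = n_a n_b / 2. Larger samples use the tie-corrected
    normal approximation.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    n = na + nb
    if math.comb(n, na) <= _EXACT_LIMIT:
        obs_dev = abs(u - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), na):
            u_perm = float(ranks[list(idx)].sum() - na * (na + 1) / 2.0)
            count += abs(u_perm - mu) >= obs_dev - 1e-12
            total += 1
        return u, count / total

    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 == 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(sigma2)
    return u, float(2.0 * stats.norm.sf(abs(z)))


def region_damage_percent(
    mask: LesionMask, atlas: np.ndarray, label: int
) -> float:
    """Percent of the atlas region with the given label covered by the mask."""
    atlas = np.asarray(atlas)
    if atlas.shape != mask.shape:
        raise ValueError(
            f"atlas shape {atlas.shape} does not match mask grid {mask.shape}"
        )
    region = atlas == label
    size = int(region.sum())
    if size == 0:
        raise ValueError(f"label {label} not present in atlas")
    return 100.0 * int(np.logical_and(mask.data, region).sum()) / size
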