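"""Covariate design-matrix construction shared by the LSM modules."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["build_covariates", "drop_constant_columns", "DEFAULT_COVARIATES"]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    "overall",
    "aos_present",
    "instrument",
    "days_post_surgery",
    "lesion_cm3",
)


def build_covariates(
    behavior: pd.DataFrame, covariates: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Numeric covariate matrix (no intercept) from a harmonized table.

    Booleans become 0/1; ``instrument`` becomes an indicator for QAB;
    any other non-numeric column is rejected.
    """
    cols = []
    for name in covariates:
        if name not in behavior.columns:
            raise ValueError(f"covariate {name!r} not in behavior table")
        col = behavior[name]
        if name == "instrument":
            cols.append((col.astype(str) == "QAB").to_numpy(dtype=float))
        elif col.dtype == bool:
            cols.append(col.to_numpy(dtype=float))
        else:
            arr = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            if np.isnan(arr).any():
                raise ValueError(f"covariate {name!r} is not numeric or has missing values")
            cols.append(arr)
    if not cols:
        return np.empty((len(behavior), 0))
    return np.column_stack(cols)


def drop_constant_columns(
    C: np.ndarray, names: tuple[str, ...] | list[str]
) -> tuple[np.ndarray, list[str]]:
    """Remove zero-variance covariate columns (collinear with the intercept).

    Returns the reduced matrix and the kept names; drops are logged.
    """
    if C.shape[1] == 0:
        return C, list(names)
    keep = np.ptp(C, axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        log.warning("dropping constant covariate column(s): %s", dropped)
    return C[:, keep], [n for n, k in zip(names, keep) if k]
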