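"""Shared-space conversion of WAB and QAB subscores.

All four derived metrics live on a 0-10 scale where 0 is most impaired and
10 is unimpaired:

* self_generated — WAB spontaneous-speech Fluency as-is; QAB mean of the
  Reduced Length & Complexity, Reduced Speech Rate, and Overall Communication
  Impairment connected-speech ratings, rescaled 0-4 -> 0-10.
* overall — WAB Aphasia Quotient / 10; QAB Overall as-is.
* repetition — both instruments' repetition summaries, already 0-10.
* naming — WAB Object Naming and QAB Picture Naming, both pre-scaled to 0-10
  upstream (raw maxima differ across battery versions, so normalization to
  0-10 is the caller's responsibility and is validated here only as a range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RawAssessment",
    "HarmonizedScores",
    "harmonize",
    "harmonize_table",
    "validate_harmonization",
    "METRICS",
]

METRICS = ("self_generated", "overall", "repetition", "naming")

_WAB_FIELDS = {
    "fluency": (0.0, 10.0),
    "aphasia_quotient": (0.0, 100.0),
    "repetition": (0.0, 10.0),
    "object_naming": (0.0, 10.0),
}
_QAB_FIELDS = {
    "reduced_length_complexity": (0.0, 4.0),
    "reduced_speech_rate": (0.0, 4.0),
    "overall_communication_impairment": (0.0, 4.0),
    "overall": (0.0, 10.0),
    "repetition_summary": (0.0, 10.0),
    "picture_naming": (0.0, 10.0),
}


@dataclass(frozen=True)
class RawAssessment:
    """Raw subscores for one subject on a single instrument.

    Exactly the subscores of the declared instrument must be provided;
    the other instrument's fields stay ``None``.
    """

    instrument: str  # "WAB" or "QAB"
    aos_present: bool = False
    days_post_surgery: int = 0
    # WAB
    fluency: float | None = None
    aphasia_quotient: float | None = None
    repetition: float | None = None
    object_naming: float | None = None
    # QAB
    reduced_length_complexity: float | None = None
    reduced_speech_rate: float | None = None
    overall_communication_impairment: float | None = None
    overall: float | None = None
    repetition_summary: float | None = None
    picture_naming: float | None = None

    def __post_init__(self) -> None:
        if self.instrument not in ("WAB", "QAB"):
            raise ValueError(f"instrument must be 'WAB' or 'QAB', got {self.instrument!r}")
        if self.days_post_surgery < 0:
            raise ValueError("days_post_surgery must be nonnegative")
        own = _WAB_FIELDS if self.instrument == "WAB" else _QAB_FIELDS
        other = _QAB_FIELDS if self.instrument == "WAB" else _WAB_FIELDS
        for name, (lo, hi) in own.items():
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"{self.instrument} assessment missing subscore {name!r}")
            if not lo <= float(v) <= hi:
                raise ValueError(
                    f"subscore {name!r} = {v} outside its {lo}-{hi} scale"
                )
        for name in other:
            if getattr(self, name) is not None:
                raise ValueError(
                    f"subscore {name!r} does not belong to instrument {self.instrument}"
                )


@dataclass(frozen=True)
class HarmonizedScores:
    self_generated: float
    overall: float
    repetition: float
    naming: float
    aos_present: bool

    def __post_init__(self) -> None:
        for name in METRICS:
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise ValueError(f"harmonized metric {name} = {v} outside [0, 10]")


def harmonize(raw: RawAssessment) -> HarmonizedScores:
    """Map one raw assessment into the shared 0-10 metric space."""
    if raw.instrument == "WAB":
        return HarmonizedScores(
            self_generated=float(raw.fluency),
            overall=float(raw.aphasia_quotient) / 10.0,
            repetition=float(raw.repetition),
            naming=float(raw.object_naming),
            aos_present=raw.aos_present,
        )
    ratings = (
        float(raw.reduced_length_complexity),
        float(raw.reduced_speech_rate),
        float(raw.overall_communication_impairment),
    )
    # mean of the three 0-4 ratings, rescaled to 0-10 (x 10/4)
    self_generated = sum(ratings) / 3.0 * 2.5
    return HarmonizedScores(
        self_generated=self_generated,
        overall=float(raw.overall),
        repetition=float(raw.repetition_summary),
        naming=float(raw.picture_naming),
        aos_present=raw.aos_present,
    )


_WAB_COLS = {
    "fluency": "wab_fluency",
    "aphasia_quotient": "wab_aq",
    "repetition": "wab_repetition",
    "object_naming": "wab_naming",
}
_QAB_COLS = {
    "reduced_length_complexity": "qab_length_complexity",
    "reduced_speech_rate": "qab_speech_rate",
    "overall_communication_impairment": "qab_comm_impairment",
    "overall": "qab_overall",
    "repetition_summary": "qab_repetition",
    "picture_naming": "qab_naming",
}


def _row_to_assessment(row: pd.Series, instrument: str) -> RawAssessment:
    cols = _WAB_COLS if instrument == "WAB" else _QAB_COLS
    kwargs = {field: float(row[col]) for field, col in cols.items()}
    return RawAssessment(
        instrument=instrument,
        aos_present=bool(row.get("aos", False)),
        days_post_surgery=int(row.get("days_post_surgery", 0)),
        **kwargs,
    )


def harmonize_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Add harmonized metric columns to a raw behavior table.

    Returns a copy with ``self_generated``, ``overall``, ``repetition``,
    ``naming`` and boolean ``aos_present`` columns appended.
    """
    if "instrument" not in behavior.columns:
        raise ValueError("behavior table lacks an 'instrument' column")
    out = behavior.copy()
    derived = {m: [] for m in METRICS}
    aos_flags = []
    for _, row in behavior.iterrows():
        instrument = str(row["instrument"])
        scores = harmonize(_row_to_assessment(row, instrument))
        for m in METRICS:
            derived[m].append(getattr(scores, m))
        aos_flags.append(scores.aos_present)
    for m in METRICS:
        out[m] = derived[m]
    out["aos_present"] = aos_flags
    return out


def validate_harmonization(paired: pd.DataFrame) -> dict[str, float]:
    """Pearson r between WAB- and QAB-derived versions of each shared metric.

    ``paired`` must carry both instruments' raw subscore columns for the same
    subjects (see :func:`lesionmap.synthetic.generate_paired_assessments`).
    """
    if len(paired) < 3:
        raise ValueError(f"need >= 3 paired rows, got {len(paired)}")
    wab = np.empty((len(paired), 4))
    qab = np.empty((len(paired), 4))
    for i, (_, row) in enumerate(paired.iterrows()):
        w = harmonize(_row_to_assessment(row, "WAB"))
        q = harmonize(_row_to_assessment(row, "QAB"))
        wab[i] = [getattr(w, m) for m in METRICS]
        qab[i] = [getattr(q, m) for m in METRICS]
    result: dict[str, float] = {}
    for j, m in enumerate(METRICS):
        if np.ptp(wab[:, j]) == 0 or np.ptp(qab[:, j]) == 0:
            raise ValueError(
                f"correlation undefined for metric {m!r}: a column has zero variance"
            )
        result[m] = float(stats.pearsonr(wab[:, j], qab[:, j]).statistic)
    return result
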