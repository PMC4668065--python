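"""Total Oocyte Score (TOS) rule engine.

A mature (MII) oocyte is scored on six morphologic parameters, each worth
-1 (worst), 0 (average) or +1 (best):

* overall morphology / shape      -- judged ordinal level
* cytoplasm (granularity, inclusions) -- judged ordinal level
* perivitelline space (PVS)       -- judged ordinal level
* first polar body (PB)           -- judged ordinal level
* oocyte diameter                 -- measured in microns
* zona pellucida (ZP) thickness   -- measured in microns

The TOS is the sum of the six parameter scores, so it lies in [-6, +6].
The patient-specific score (PTOS) is the mean TOS over a patient's scored
mature oocytes; cycles with fewer than two mature oocytes are excluded.

Measured parameters are banded: diameter scores +1 strictly inside
(130, 150) um, -1 below 120 or above 160 um, and 0 on the closed
complement [120, 130] u [150, 160]; ZP thickness scores +1 inside
(12, 18) um, -1 below 10 or above 20 um, and 0 on [10, 12] u [18, 20].
Boundary measurements deliberately take the middle score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "OocyteAssessment",
    "ScoredOocyte",
    "PatientScore",
    "ValidationError",
    "ExclusionError",
    "score_categorical",
    "score_size",
    "score_zp",
    "compute_tos",
    "compute_ptos",
    "read_oocyte_table",
    "score_oocyte_table",
    "ptos_from_scored_table",
]

#: canonical ordinal levels and their scores
LEVELS: Mapping[str, int] = {"worst": -1, "average": 0, "best": 1}

_LEVEL_ALIASES = {
    "worst": "worst", "-1": "worst", "average": "average", "0": "average",
    "best": "best", "1": "best", "+1": "best",
}

CATEGORICAL_FIELDS = ("morphology", "cytoplasm", "pvs", "pb")


class ValidationError(ValueError):
    """An input field violates the scoring domain."""


class ExclusionError(ValueError):
    """A patient fails a study inclusion criterion (fewer than 2 mature oocytes)."""


def _normalize_level(value, field: str) -> str:
    """Map either verbal ('worst'/'average'/'best') or numeric (-1/0/+1)
    encodings onto the canonical verbal level."""
    if isinstance(value, str):
        key = value.strip().lower()
    elif isinstance(value, (int, np.integer)):
        key = str(int(value))
    elif isinstance(value, float) and float(value).is_integer():
        key = str(int(value))
    else:
        key = repr(value)
    try:
        return _LEVEL_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"{field}: unrecognized level {value!r}; expected one of "
            f"worst/average/best or -1/0/1"
        ) from None


@dataclass(frozen=True)
class OocyteAssessment:
    """One oocyte's six raw morphologic observations.

    Categorical levels may be given verbally or as -1/0/+1; they are
    normalized to 'worst'/'average'/'best' on construction.
    """

    patient_id: str
    oocyte_id: str
    morphology_level: str
    cytoplasm_level: str
    pvs_level: str
    pb_level: str
    diameter_um: float
    zp_thickness_um: float

    def __post_init__(self):
        for field in ("morphology_level", "cytoplasm_level", "pvs_level", "pb_level"):
            object.__setattr__(self, field, _normalize_level(getattr(self, field), field))
        if not self.diameter_um > 0:
            raise ValidationError(f"diameter_um must be positive, got {self.diameter_um}")
        if not self.zp_thickness_um > 0:
            raise ValidationError(
                f"zp_thickness_um must be positive, got {self.zp_thickness_um}"
            )


@dataclass(frozen=True)
class ScoredOocyte:
    """The six -1/0/+1 parameter scores and their sum (TOS)."""

    assessment: OocyteAssessment
    morphology_score: int
    size_score: int
    cytoplasm_score: int
    pvs_score: int
    zp_score: int
    pb_score: int
    tos: int

    @property
    def scores(self) -> tuple[int, ...]:
        return (
            self.morphology_score, self.size_score, self.cytoplasm_score,
            self.pvs_score, self.zp_score, self.pb_score,
        )


@dataclass(frozen=True)
class PatientScore:
    """Patient-specific TOS: mean TOS over >=2 scored mature oocytes."""

    patient_id: str
    ptos: float
    n_oocytes: int


def score_categorical(level, field: str = "level") -> int:
    """Score a judged ordinal level: worst -> -1, average -> 0, best -> +1."""
    return LEVELS[_normalize_level(level, field)]


def score_size(diameter_um: float) -> int:
    """Score oocyte diameter in microns.

    +1 for 130 < d < 150 (normal range); -1 for d < 120 or d > 160
    (abnormally small or large); 0 on [120, 130] u [150, 160].
    """
    d = float(diameter_um)
    if not d > 0:
        raise ValidationError(f"diameter_um must be positive, got {diameter_um}")
    if 130 < d < 150:
        return 1
    if d < 120 or d > 160:
        return -1
    return 0


def score_zp(zp_thickness_um: float) -> int:
    """Score zona pellucida thickness in microns.

    +1 for 12 < t < 18; -1 for t < 10 or t > 20 (very thin or thick);
    0 on [10, 12] u [18, 20].
    """
    t = float(zp_thickness_um)
    if not t > 0:
        raise ValidationError(f"zp_thickness_um must be positive, got {zp_thickness_um}")
    if 12 < t < 18:
        return 1
    if t < 10 or t > 20:
        return -1
    return 0


def compute_tos(assessment: OocyteAssessment) -> ScoredOocyte:
    """Score all six parameters and sum them into the TOS."""
    s_morph = score_categorical(assessment.morphology_level, "morphology_level")
    s_size = score_size(assessment.diameter_um)
    s_cyto = score_categorical(assessment.cytoplasm_level, "cytoplasm_level")
    s_pvs = score_categorical(assessment.pvs_level, "pvs_level")
    s_zp = score_zp(assessment.zp_thickness_um)
    s_pb = score_categorical(assessment.pb_level, "pb_level")
    tos = s_morph + s_size + s_cyto + s_pvs + s_zp + s_pb
    return ScoredOocyte(
        assessment=assessment,
        morphology_score=s_morph,
        size_score=s_size,
        cytoplasm_score=s_cyto,
        pvs_score=s_pvs,
        zp_score=s_zp,
        pb_score=s_pb,
        tos=tos,
    )


def compute_ptos(scored: Sequence[ScoredOocyte] | Iterable[ScoredOocyte]) -> PatientScore:
    """Average the TOS over one patient's scored oocytes.

    Raises ExclusionError for fewer than 2 oocytes (the study's inclusion
    criterion) and ValidationError if the oocytes span several patients.
    """
    scored = list(scored)
    if len(scored) < 2:
        raise ExclusionError(
            f"patient has {len(scored)} scored mature oocyte(s); "
            "at least 2 are required"
        )
    patient_ids = {s.assessment.patient_id for s in scored}
    if len(patient_ids) != 1:
        raise ValidationError(f"mixed patient_ids in PTOS input: {sorted(patient_ids)}")
    tos_values = [s.tos for s in scored]
    return PatientScore(
        patient_id=patient_ids.pop(),
        ptos=float(np.mean(tos_values)),
        n_oocytes=len(scored),
    )


# ---------------------------------------------------------------------------
# table interface (CSV, one row per oocyte)

OOCYTE_COLUMNS = [
    "patient_id", "oocyte_id", "morphology", "cytoplasm", "pvs", "pb",
    "diameter_um", "zp_um",
]

SCORE_COLUMNS = [
    "morphology_score", "size_score", "cytoplasm_score", "pvs_score",
    "zp_score", "pb_score", "tos",
]


def read_oocyte_table(path) -> pd.DataFrame:
    """Read a per-oocyte CSV; categorical columns accept either encoding."""
    df = pd.read_csv(path, dtype={"patient_id": str, "oocyte_id": str})
    missing = [c for c in OOCYTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"oocyte table missing columns: {missing}")
    return df


def score_oocyte_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a per-oocyte table.

    Returns a copy with the six parameter-score columns and `tos` appended.
    Equivalent to applying :func:`compute_tos` row by row.
    """
    missing = [c for c in OOCYTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"oocyte table missing columns: {missing}")
    out = df.copy()
    for field in CATEGORICAL_FIELDS:
        out[f"{field}_score"] = [score_categorical(v, field) for v in df[field]]
    d = np.asarray(df["diameter_um"], dtype=float)
    t = np.asarray(df["zp_um"], dtype=float)
    if np.any(~(d > 0)):
        raise ValidationError("diameter_um must be positive for every oocyte")
    if np.any(~(t > 0)):
        raise ValidationError("zp_um must be positive for every oocyte")
    out["size_score"] = np.select(
        [(d > 130) & (d < 150), (d < 120) | (d > 160)], [1, -1], default=0
    )
    out["zp_score"] = np.select(
        [(t > 12) & (t < 18), (t < 10) | (t > 20)], [1, -1], default=0
    )
    out["tos"] = (
        out["morphology_score"] + out["size_score"] + out["cytoplasm_score"]
        + out["pvs_score"] + out["zp_score"] + out["pb_score"]
    )
    return out[list(df.columns) + SCORE_COLUMNS]


def ptos_from_scored_table(
    scored: pd.DataFrame, min_oocytes: int = 2, transferred_only: bool = False
) -> pd.DataFrame:
    """Patient-level PTOS table from a scored oocyte table.

    Patients with fewer than `min_oocytes` scored oocytes are dropped
    (the study's exclusion rule). With ``transferred_only`` the average is
    restricted to oocytes flagged as having produced a transferred embryo
    (requires a boolean ``transferred`` column).
    """
    df = scored
    if transferred_only:
        if "transferred" not in df.columns:
            raise ValidationError("transferred_only requires a 'transferred' column")
        df = df[df["transferred"].astype(bool)]
    grouped = df.groupby("patient_id", sort=True)["tos"]
    out = grouped.agg(ptos="mean", n_oocytes="size").reset_index()
    out = out[out["n_oocytes"] >= min_oocytes].reset_index(drop=True)
    out["ptos"] = out["ptos"].astype(float)
    return out
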