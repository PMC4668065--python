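"""Day-3 embryo grading from blastomere count and fragmentation.

Grades run 1 (very poor) to 5 (excellent) and are assigned by a cascade
evaluated from Grade 5 downward; the first matching rule wins:

=====  ==========================  ==================
Grade  blastomeres (day 3)         fragmentation
=====  ==========================  ==================
5      >= 8                        < 5%
4      >= 6                        <= 5%
3      >= 6                        <= 20%
2      >= 4                        <= 40%
1      anything else (fallback)
=====  ==========================  ==================

The printed clinical ranges ("6-8 cells", "4-8 cells") are read as
minimum cell-count conditions so that every (cell count, fragmentation)
pair receives exactly one grade and the function is monotone: grade never
decreases with more cells and never increases with more fragmentation.
Embryos beyond 8 cells (10-, 12-cell) are treated like 8-cell ones.

The binary quality outcome used in the association models is simply
"reached >= 8 cells on day 3".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .oocyte_scoring import ValidationError

__all__ = [
    "grade_embryo",
    "eight_cell_outcome",
    "grade_embryo_table",
    "read_embryo_table",
    "EMBRYO_COLUMNS",
]

EMBRYO_COLUMNS = ["patient_id", "oocyte_id", "cell_count", "fragmentation_pct", "transferred"]


def grade_embryo(cell_count: int, fragmentation_pct: float) -> int:
    """Assign the day-3 grade (1-5) for one embryo."""
    c = int(cell_count)
    f = float(fragmentation_pct)
    if c < 1:
        raise ValidationError(f"cell_count must be >= 1, got {cell_count}")
    if not (0 <= f <= 100):
        raise ValidationError(f"fragmentation_pct must be in [0, 100], got {f}")
    if c >= 8 and f < 5:
        return 5
    if c >= 6 and f <= 5:
        return 4
    if c >= 6 and f <= 20:
        return 3
    if c >= 4 and f <= 40:
        return 2
    return 1


def eight_cell_outcome(cell_count: int) -> bool:
    """True iff the embryo reached at least 8 blastomeres on day 3."""
    c = int(cell_count)
    if c < 0:
        raise ValidationError(f"cell_count must be >= 0, got {cell_count}")
    return c >= 8


def _grade_vectorized(cells: np.ndarray, frag: np.ndarray) -> np.ndarray:
    return np.select(
        [
            (cells >= 8) & (frag < 5),
            (cells >= 6) & (frag <= 5),
            (cells >= 6) & (frag <= 20),
            (cells >= 4) & (frag <= 40),
        ],
        [5, 4, 3, 2],
        default=1,
    )


def read_embryo_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "oocyte_id": str})
    missing = [c for c in EMBRYO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"embryo table missing columns: {missing}")
    return df


def grade_embryo_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append `grade` and `eight_cell_flag` to a per-embryo table."""
    missing = [c for c in ("cell_count", "fragmentation_pct") if c not in df.columns]
    if missing:
        raise ValidationError(f"embryo table missing columns: {missing}")
    cells = np.asarray(df["cell_count"], dtype=int)
    frag = np.asarray(df["fragmentation_pct"], dtype=float)
    if np.any(cells < 1):
        raise ValidationError("cell_count must be >= 1 for every embryo")
    if np.any((frag < 0) | (frag > 100)):
        raise ValidationError("fragmentation_pct must be in [0, 100] for every embryo")
    out = df.copy()
    out["grade"] = _grade_vectorized(cells, frag)
    out["eight_cell_flag"] = cells >= 8
    return out
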