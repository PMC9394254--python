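"""SAM valence/arousal ratings -> nine emotion classes.

Each affective axis is rated on the 1-9 Self-Assessment Manikin scale and
binned into three levels (boundaries at 4 and 7, half-open: [1,4), [4,7),
[7,9]); the 3x3 grid of (valence level, arousal level) pairs yields nine
emotion classes.  Ordinals, not names, drive all computation: the ordinal is
``3 * arousal_index + valence_index`` with valence increasing left-to-right
and arousal bottom-to-top.  The cell names are a configurable table with a
documented default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "SamRating",
    "EmotionClass",
    "VALENCE_LEVELS",
    "AROUSAL_LEVELS",
    "DEFAULT_NAME_TABLE",
    "bin_level",
    "map_emotion",
    "label_ratings_csv",
]

VALENCE_LEVELS = ("negative", "neutral", "positive")
AROUSAL_LEVELS = ("passive", "neutral", "active")

# Rows indexed by arousal level (passive, neutral, active), columns by
# valence level (negative, neutral, positive).
DEFAULT_NAME_TABLE: tuple[tuple[str, str, str], ...] = (
    ("depressed", "calm", "relaxed"),
    ("miserable", "neutral", "pleased"),
    ("distressed", "excited", "happy"),
)


@dataclass(frozen=True)
class SamRating:
    """A (valence, arousal) pair on the 1-9 SAM scale."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for axis, value in (("valence", self.valence), ("arousal", self.arousal)):
            if not 1.0 <= float(value) <= 9.0:
                raise ValueError(f"{axis} rating {value} outside [1, 9]")


@dataclass(frozen=True)
class EmotionClass:
    """A cell of the 3x3 valence/arousal grid."""

    valence_level: str
    arousal_level: str
    ordinal: int
    name: str

    def __post_init__(self) -> None:
        expected = 3 * AROUSAL_LEVELS.index(self.arousal_level) + VALENCE_LEVELS.index(
            self.valence_level
        )
        if self.ordinal != expected:
            raise ValueError(
                f"ordinal {self.ordinal} inconsistent with "
                f"({self.valence_level}, {self.arousal_level})"
            )


def bin_level(value: float, axis: Literal["valence", "arousal"]) -> str:
    """Bin a 1-9 rating into its three-level name for the given axis.

    1-3 -> negative/passive, 4-6 -> neutral, 7-9 -> positive/active; for
    real-valued ratings the boundaries are half-open at 4 and 7.
    """
    if axis == "valence":
        names = VALENCE_LEVELS
    elif axis == "arousal":
        names = AROUSAL_LEVELS
    else:
        raise ValueError(f"unknown axis {axis!r}")
    value = float(value)
    if not 1.0 <= value <= 9.0:
        raise ValueError(f"{axis} rating {value} outside [1, 9]")
    if value < 4.0:
        return names[0]
    if value < 7.0:
        return names[1]
    return names[2]


def map_emotion(
    rating: SamRating,
    name_table: Sequence[Sequence[str]] = DEFAULT_NAME_TABLE,
) -> EmotionClass:
    """Map a SAM rating to its 3x3-grid emotion class."""
    v_level = bin_level(rating.valence, "valence")
    a_level = bin_level(rating.arousal, "arousal")
    v_idx = VALENCE_LEVELS.index(v_level)
    a_idx = AROUSAL_LEVELS.index(a_level)
    return EmotionClass(
        valence_level=v_level,
        arousal_level=a_level,
        ordinal=3 * a_idx + v_idx,
        name=name_table[a_idx][v_idx],
    )


def label_ratings_csv(in_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Label a ratings CSV (epoch_id, valence, arousal) and write the result.

    The emitted CSV has columns epoch_id, ordinal, valence_level,
    arousal_level, name.
    """
    ratings = pd.read_csv(in_path)
    missing = {"epoch_id", "valence", "arousal"} - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings file missing columns: {sorted(missing)}")
    rows = []
    for rec in ratings.itertuples(index=False):
        cls = map_emotion(SamRating(rec.valence, rec.arousal))
        rows.append(
            {
                "epoch_id": rec.epoch_id,
                "ordinal": cls.ordinal,
                "valence_level": cls.valence_level,
                "arousal_level": cls.arousal_level,
                "name": cls.name,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(out_path, index=False)
    return out
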