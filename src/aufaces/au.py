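"""Action units and the 7-way expression label vocabulary.

The package works with the 20 action units (AUs) of the Facial Action
Coding System that are associated with one or more of the six basic
emotions, numbered by their FACS ids.  Every face-synthesis and probing
routine takes its coordinates in this 20-dimensional AU-intensity space.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

#: FACS ids of the 20 emotion-linked action units, ascending.
AU_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 9, 10, 11, 12, 15, 16, 17, 20, 22, 23, 24, 25, 26, 27)

#: Human-readable FACS names, keyed by AU id.
AU_NAMES: dict[int, str] = {
    1: "inner brow raiser",
    2: "outer brow raiser",
    4: "brow lowerer",
    5: "upper lid raiser",
    6: "cheek raiser",
    7: "lid tightener",
    9: "nose wrinkler",
    10: "upper lip raiser",
    11: "nasolabial furrow deepener",
    12: "lip corner puller",
    15: "lip corner depressor",
    16: "lower lip depressor",
    17: "chin raiser",
    20: "lip stretcher",
    22: "lip funneler",
    23: "lip tightener",
    24: "lip pressor",
    25: "lips part",
    26: "jaw drop",
    27: "mouth stretch",
}

#: Fixed expression label order: ties and matrix axes always follow it.
EXPRESSIONS: tuple[str, ...] = (
    "neutral",
    "happy",
    "fearful",
    "sad",
    "angry",
    "surprised",
    "disgusted",
)

N_AUS = len(AU_IDS)
N_EXPRESSIONS = len(EXPRESSIONS)


class AUVector(Mapping):
    """An assignment of an intensity in [0, 1] to each of the 20 AUs.

    Immutable mapping from AU id to intensity.  Unknown AU ids and
    out-of-range intensities are rejected at construction.
    """

    __slots__ = ("_values",)

    def __init__(self, intensities: Mapping[int, float] | None = None):
        values = dict.fromkeys(AU_IDS, 0.0)
        if intensities is not None:
            for au, v in intensities.items():
                if au not in values:
                    raise KeyError(f"unknown action unit AU#{au}; valid ids: {AU_IDS}")
                v = float(v)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"AU#{au} intensity {v} outside [0, 1]")
                values[au] = v
        self._values = values

    @classmethod
    def zeros(cls) -> "AUVector":
        return cls()

    @classmethod
    def single(cls, au: int, intensity: float) -> "AUVector":
        """All AUs off except `au` at `intensity`."""
        return cls({au: intensity})

    def __getitem__(self, au: int) -> float:
        return self._values[au]

    def __iter__(self):
        return iter(AU_IDS)

    def __len__(self) -> int:
        return N_AUS

    def as_array(self) -> np.ndarray:
        """Intensities as a length-20 array in :data:`AU_IDS` order."""
        return np.array([self._values[a] for a in AU_IDS])

    def __repr__(self) -> str:  # pragma: no cover
        on = {a: round(v, 3) for a, v in self._values.items() if v > 0}
        return f"AUVector({on or 'all zero'})"

    def __eq__(self, other) -> bool:
        return isinstance(other, AUVector) and self._values == other._values

    def __hash__(self) -> int:
        return hash(tuple(self._values[a] for a in AU_IDS))


def expression_index(label: str) -> int:
    """Index of `label` in the fixed vocabulary; raises on unknown labels."""
    try:
        return EXPRESSIONS.index(label)
    except ValueError:
        raise ValueError(f"unknown expression label {label!r}; expected one of {EXPRESSIONS}") from None
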