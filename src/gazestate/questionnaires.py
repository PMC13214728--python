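"""Questionnaire scale definitions and item scoring.

Four subjective instruments assess the three learner states: NASA-TLX
(six 21-point workload subscales), the Flow State Scale (10 items, 1-5),
the Distractibility subscale of the Attention Questionnaire (13 items,
1-7, four reflected), and the multidimensional cognitive-load scale for
virtual environments (MCLSVE; intrinsic/extraneous/germane subscales on
11-point items).  A scale score is the mean of its (reverse-coded where
reflected) item responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ResponseError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    n_items: int
    item_min: float
    item_max: float
    # 0-based indices of reverse-coded items
    reflected: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.item_min >= self.item_max or self.n_items < 1:
            raise ResponseError(f"invalid scale definition {self.name!r}")
        if any(i < 0 or i >= self.n_items for i in self.reflected):
            raise ResponseError("reflected index out of range")


DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    "nasa_tlx": ScaleDefinition("nasa_tlx", n_items=6, item_min=0, item_max=20),
    "fss": ScaleDefinition("fss", n_items=10, item_min=1, item_max=5),
    # items phrased as concentration ability are reverse-coded
    "distractibility": ScaleDefinition(
        "distractibility", n_items=13, item_min=1, item_max=7, reflected=(0, 5, 6, 12)
    ),
    "il": ScaleDefinition("il", n_items=3, item_min=0, item_max=10),
    "el": ScaleDefinition("el", n_items=11, item_min=0, item_max=10),
    "gl": ScaleDefinition("gl", n_items=4, item_min=0, item_max=10),
}


def score_questionnaire(responses, scale: ScaleDefinition) -> float:
    """Scale score = mean of item responses after reverse-coding.

    Reflected items are coded as ``item_max + item_min - response``, so a
    response at the scale midpoint is invariant under reflection.
    """
    r = np.asarray(responses, dtype=float)
    if r.shape != (scale.n_items,):
        raise ResponseError(
            f"{scale.name}: expected {scale.n_items} responses, got {r.shape}"
        )
    if np.any(r < scale.item_min) or np.any(r > scale.item_max):
        raise ResponseError(f"{scale.name}: response outside item bounds")
    coded = r.copy()
    idx = list(scale.reflected)
    coded[idx] = scale.item_max + scale.item_min - coded[idx]
    return float(coded.mean())
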