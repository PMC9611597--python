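"""Survey item registry: the ten empowerment items and their nominal levels.

The instrument covers three dimensions of agency:

* five attitude items on whether wife-beating is justified in a given
  scenario (burning food, refusing sex, arguing, neglecting children,
  going out without telling) — levels ``yes`` / ``no`` / ``dont_know``;
* four household decision-making items (family visits, large purchases,
  own health care, spending the partner's earnings) — who usually
  decides, with ``no_earnings`` as an extra admissible level for the
  earnings item;
* one item on whether a wife is justified in refusing sex when her
  husband has other partners.

Level order within each item is part of the public contract: it fixes
the deterministic tie-break used by the mode-update step of k-modes
(lowest-ordered level wins a plurality tie) and the integer codes used
internally everywhere.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

VIOLENCE_LEVELS = ("yes", "no", "dont_know")
DECISION_LEVELS = ("self", "with_partner", "partner", "other")
SPEND_LEVELS = ("self", "with_partner", "partner", "other", "no_earnings")

ITEMS = (
    "v_burns",
    "v_refuse",
    "v_argue",
    "v_neglect",
    "v_goout",
    "d_visit",
    "d_purchase",
    "d_health",
    "d_spend",
    "refuse_sex",
)

ITEM_LEVELS: dict[str, tuple[str, ...]] = {
    "v_burns": VIOLENCE_LEVELS,
    "v_refuse": VIOLENCE_LEVELS,
    "v_argue": VIOLENCE_LEVELS,
    "v_neglect": VIOLENCE_LEVELS,
    "v_goout": VIOLENCE_LEVELS,
    "d_visit": DECISION_LEVELS,
    "d_purchase": DECISION_LEVELS,
    "d_health": DECISION_LEVELS,
    "d_spend": SPEND_LEVELS,
    "refuse_sex": VIOLENCE_LEVELS,
}

#: number of admissible levels per item, in ITEMS order
N_LEVELS = np.array([len(ITEM_LEVELS[it]) for it in ITEMS], dtype=np.int8)

_CODE = {it: {lv: i for i, lv in enumerate(ITEM_LEVELS[it])} for it in ITEMS}


class ResponseVector(NamedTuple):
    """One respondent's complete answers to the ten items (no missing values)."""

    v_burns: str
    v_refuse: str
    v_argue: str
    v_neglect: str
    v_goout: str
    d_visit: str
    d_purchase: str
    d_health: str
    d_spend: str
    refuse_sex: str

    def validate(self) -> "ResponseVector":
        for item, value in zip(ITEMS, self):
            if value not in ITEM_LEVELS[item]:
                raise ValueError(
                    f"inadmissible level {value!r} for item {item!r}; "
                    f"expected one of {ITEM_LEVELS[item]}"
                )
        return self

    def to_codes(self) -> np.ndarray:
        """Integer codes (length 10, int8) in declared level order."""
        self.validate()
        return np.array(
            [_CODE[it][v] for it, v in zip(ITEMS, self)], dtype=np.int8
        )

    @classmethod
    def from_codes(cls, codes) -> "ResponseVector":
        codes = np.asarray(codes)
        if codes.shape != (10,):
            raise ValueError("expected 10 item codes")
        return cls(*[ITEM_LEVELS[it][int(c)] for it, c in zip(ITEMS, codes)])


def encode_responses(vectors) -> np.ndarray:
    """Stack ResponseVectors (or 10-string sequences) into an (n, 10) code matrix."""
    rows = [
        v.to_codes() if isinstance(v, ResponseVector) else ResponseVector(*v).to_codes()
        for v in vectors
    ]
    return np.array(rows, dtype=np.int8)


def decode_responses(codes: np.ndarray) -> list[ResponseVector]:
    return [ResponseVector.from_codes(row) for row in np.asarray(codes)]
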