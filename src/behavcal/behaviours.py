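"""Core enumerations: devices, wear positions and the six directed behaviours.

The calibration protocol has each child perform six directed behaviours that
span the intensity spectrum of a typical preschool day, from watching a
cartoon (essentially motionless but awake) up to a competitive sprinting
game.  The behaviours carry a strict intensity rank that every binarisation
scheme in :mod:`behavcal.roc_calibration` builds on.
"""

from __future__ import annotations

import enum


class Device(str, enum.Enum):
    """Actigraph model worn by the child."""

    MW8 = "MW8"  # MotionWatch 8, uni-axial, 50 Hz, counts/epoch
    GT3X = "GT3X"  # ActiGraph GT3X, tri-axial vector magnitude

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Position(str, enum.Enum):
    """Body position of the device."""

    WRIST = "wrist"  # non-dominant wrist
    HIP = "hip"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Behaviour(str, enum.Enum):
    """The six directed behaviours, defined in ascending intensity order.

    ``rank`` runs 1 (sedentary screen time, the most immobile behaviour)
    to 6 (sprinting).  The order is a strict total order; composite
    intensity classes are contiguous suffixes of it.
    """

    SEDENTARY_SCREEN_TIME = "sedentary_screen_time"
    RECUMBENT_LISTENING = "recumbent_listening"
    SEDENTARY_CRAFTS = "sedentary_crafts"
    PLAY_ON_FLOOR = "play_on_floor"
    FLOORBALL_WALK = "floorball_walk"
    SPRINTING = "sprinting"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def rank(self) -> int:
        """Intensity rank, 1 = most immobile ... 6 = most vigorous."""
        return _RANKS[self]


_RANKS = {b: i + 1 for i, b in enumerate(Behaviour)}

#: All behaviours in ascending intensity order.
BEHAVIOURS_ASCENDING: tuple[Behaviour, ...] = tuple(Behaviour)

#: Behaviours in descending intensity order (vigorous first), the order in
#: which calibration tables are conventionally printed.
BEHAVIOURS_DESCENDING: tuple[Behaviour, ...] = tuple(reversed(Behaviour))

#: Body-in-motion behaviours (light, moderate and vigorous activity).
MOBILE_BEHAVIOURS = frozenset(
    {Behaviour.PLAY_ON_FLOOR, Behaviour.FLOORBALL_WALK, Behaviour.SPRINTING}
)

#: Motionless or sedentary behaviours.
STATIONARY_BEHAVIOURS = frozenset(Behaviour) - MOBILE_BEHAVIOURS


def coerce_behaviour(value: "str | Behaviour") -> Behaviour:
    """Return ``value`` as a :class:`Behaviour`, accepting snake_case names."""
    if isinstance(value, Behaviour):
        return value
    try:
        return Behaviour(value)
    except ValueError:
        names = ", ".join(b.value for b in Behaviour)
        raise ValueError(f"unknown behaviour {value!r}; expected one of: {names}") from None


def coerce_device(value: "str | Device") -> Device:
    if isinstance(value, Device):
        return value
    try:
        return Device(str(value).upper())
    except ValueError:
        raise ValueError(f"unknown device {value!r}; expected MW8 or GT3X") from None


def coerce_position(value: "str | Position") -> Position:
    if isinstance(value, Position):
        return value
    try:
        return Position(str(value).lower())
    except ValueError:
        raise ValueError(f"unknown position {value!r}; expected wrist or hip") from None
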