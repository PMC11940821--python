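"""Published calibration moments for the four device/position channels.

``REFERENCE_MOMENTS`` holds the per-behaviour mean and standard deviation of
activity counts per 30-s epoch observed in a directed-activity calibration
study of thirty 3-year-old children wearing a MotionWatch 8 (uni-axial) and
an ActiGraph GT3X (tri-axial vector magnitude) simultaneously at the
non-dominant wrist and at the hip.  These moments parameterise the default
synthetic cohort and the closed-form Gaussian surrogate used to sanity-check
ROC calibration.

``REFERENCE_CUTOFFS`` holds the cut-off tables (counts/30 s) published from
the same study, useful as realistic inputs for epoch classification.
"""

from __future__ import annotations

from .behaviours import Behaviour, Device, Position

#: (device, position, behaviour) -> (mean, sd) of counts per 30-s epoch.
REFERENCE_MOMENTS: dict[tuple[Device, Position, Behaviour], tuple[float, float]] = {
    # wrist-worn ActiGraph GT3X (vector magnitude)
    (Device.GT3X, Position.WRIST, Behaviour.SPRINTING): (9017.8, 2745.2),
    (Device.GT3X, Position.WRIST, Behaviour.FLOORBALL_WALK): (4677.3, 1875.3),
    (Device.GT3X, Position.WRIST, Behaviour.PLAY_ON_FLOOR): (2359.8, 818.6),
    (Device.GT3X, Position.WRIST, Behaviour.SEDENTARY_CRAFTS): (1329.0, 736.1),
    (Device.GT3X, Position.WRIST, Behaviour.RECUMBENT_LISTENING): (998.0, 1198.2),
    (Device.GT3X, Position.WRIST, Behaviour.SEDENTARY_SCREEN_TIME): (540.6, 724.8),
    # wrist-worn MotionWatch 8 (uni-axial)
    (Device.MW8, Position.WRIST, Behaviour.SPRINTING): (1419.2, 457.5),
    (Device.MW8, Position.WRIST, Behaviour.FLOORBALL_WALK): (672.2, 309.8),
    (Device.MW8, Position.WRIST, Behaviour.PLAY_ON_FLOOR): (291.1, 143.9),
    (Device.MW8, Position.WRIST, Behaviour.SEDENTARY_CRAFTS): (128.9, 95.0),
    (Device.MW8, Position.WRIST, Behaviour.RECUMBENT_LISTENING): (110.7, 142.1),
    (Device.MW8, Position.WRIST, Behaviour.SEDENTARY_SCREEN_TIME): (62.9, 97.4),
    # hip-worn ActiGraph GT3X
    (Device.GT3X, Position.HIP, Behaviour.SPRINTING): (2240.0, 586.6),
    (Device.GT3X, Position.HIP, Behaviour.FLOORBALL_WALK): (1964.7, 753.4),
    (Device.GT3X, Position.HIP, Behaviour.PLAY_ON_FLOOR): (1044.1, 550.4),
    (Device.GT3X, Position.HIP, Behaviour.SEDENTARY_CRAFTS): (291.8, 317.7),
    (Device.GT3X, Position.HIP, Behaviour.RECUMBENT_LISTENING): (253.5, 479.1),
    (Device.GT3X, Position.HIP, Behaviour.SEDENTARY_SCREEN_TIME): (137.2, 260.3),
    # hip-worn MotionWatch 8
    (Device.MW8, Position.HIP, Behaviour.SPRINTING): (1172.3, 357.9),
    (Device.MW8, Position.HIP, Behaviour.FLOORBALL_WALK): (533.6, 250.5),
    (Device.MW8, Position.HIP, Behaviour.PLAY_ON_FLOOR): (80.3, 85.6),
    (Device.MW8, Position.HIP, Behaviour.SEDENTARY_CRAFTS): (16.0, 29.3),
    (Device.MW8, Position.HIP, Behaviour.RECUMBENT_LISTENING): (19.9, 47.4),
    (Device.MW8, Position.HIP, Behaviour.SEDENTARY_SCREEN_TIME): (10.2, 30.9),
}

#: Published cut-offs (counts/30 s) per channel: (vpa, mvpa, lmvpa, moa).
REFERENCE_CUTOFFS: dict[tuple[Device, Position], tuple[float, float, float, float]] = {
    (Device.MW8, Position.WRIST): (787.0, 408.0, 215.0, 118.0),
    (Device.GT3X, Position.WRIST): (4607.0, 3038.0, 1782.0, 1148.0),
    (Device.MW8, Position.HIP): (637.0, 214.0, 46.0, 22.0),
    (Device.GT3X, Position.HIP): (1509.0, 1006.0, 631.0, 183.0),
}

#: The four calibrated channels in canonical order.
CHANNELS: tuple[tuple[Device, Position], ...] = (
    (Device.MW8, Position.WRIST),
    (Device.GT3X, Position.WRIST),
    (Device.MW8, Position.HIP),
    (Device.GT3X, Position.HIP),
)
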