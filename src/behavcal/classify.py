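"""Apply a calibrated cut-off table to unlabelled epoch series.

A monotone cut-off table (vpa > mvpa > lmvpa > moa >= 0) partitions the
count axis into five bands::

    MOA        count <  moa_cut
    SED        moa_cut <= count <= lmvpa_cut
    LPA_band   lmvpa_cut < count <= mvpa_cut
    MPA_band   mvpa_cut  < count <= vpa_cut
    VPA        count > vpa_cut

The middle bands are named ``*_band`` rather than after behaviours: once
the observational context is gone, a count only locates an epoch between
thresholds, it does not identify what the child was doing.  The SED band's
lower bound is inclusive and MOA is strictly below its cut-off, matching
the calibration's "< c" convention for motionless alert.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .epoch_data import EpochSeries
from .errors import ValidationError
from .roc_calibration import CutoffTable

#: Class labels from lowest to highest intensity.
CLASS_LABELS = ("MOA", "SED", "LPA_band", "MPA_band", "VPA")


@dataclasses.dataclass
class ClassifiedSeries:
    """An epoch series plus one intensity class per epoch."""

    series: EpochSeries
    classes: np.ndarray  # dtype=object/str, same length as series.counts

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.series.counts):
            raise ValidationError("classes must align one-to-one with epochs")


@dataclasses.dataclass
class TimeInClassSummary:
    """Minutes and proportions per intensity class for one channel."""

    child_id: str
    device: str
    position: str
    minutes: dict[str, float]
    proportions: dict[str, float]
    total_minutes: float
    empty: bool = False


def validate_cutoff_table(cutoffs: CutoffTable) -> list[str]:
    """Return human-readable violations of the monotone-partition assumption."""
    violations: list[str] = []
    pairs = [
        ("vpa_cut", cutoffs.vpa_cut, "mvpa_cut", cutoffs.mvpa_cut),
        ("mvpa_cut", cutoffs.mvpa_cut, "lmvpa_cut", cutoffs.lmvpa_cut),
        ("lmvpa_cut", cutoffs.lmvpa_cut, "moa_cut", cutoffs.moa_cut),
    ]
    for hi_name, hi, lo_name, lo in pairs:
        if not hi > lo:
            violations.append(f"{hi_name} ({hi}) must be greater than {lo_name} ({lo})")
    if cutoffs.moa_cut < 0:
        violations.append(f"moa_cut ({cutoffs.moa_cut}) must be non-negative")
    return violations


def classify_epochs(series: EpochSeries, cutoffs: CutoffTable) -> ClassifiedSeries:
    """Assign each epoch of ``series`` to one of the five intensity bands."""
    if series.device != cutoffs.device or series.position != cutoffs.position:
        raise ValidationError(
            f"series channel {series.device.value}/{series.position.value} does not "
            f"match cut-off table {cutoffs.device.value}/{cutoffs.position.value}"
        )
    violations = validate_cutoff_table(cutoffs)
    if violations:
        raise ValidationError("non-monotone cut-off table: " + "; ".join(violations))
    c = series.counts
    classes = np.select(
        [
            c > cutoffs.vpa_cut,
            c > cutoffs.mvpa_cut,
            c > cutoffs.lmvpa_cut,
            c >= cutoffs.moa_cut,
        ],
        ["VPA", "MPA_band", "LPA_band", "SED"],
        default="MOA",
    )
    return ClassifiedSeries(series=series, classes=classes)


def time_in_class(classified: ClassifiedSeries) -> TimeInClassSummary:
    """Minutes and proportions spent in each intensity band.

    An empty series reports zero minutes everywhere with proportions 0 and
    the ``empty`` flag set (proportions are undefined with no epochs).
    """
    s = classified.series
    n = len(s.counts)
    minutes = {lab: 0.0 for lab in CLASS_LABELS}
    for lab, cnt in pd.Series(classified.classes).value_counts().items():
        minutes[str(lab)] = float(cnt) * s.epoch_seconds / 60.0
    total = float(n) * s.epoch_seconds / 60.0
    if n == 0:
        proportions = {lab: 0.0 for lab in CLASS_LABELS}
    else:
        proportions = {lab: minutes[lab] / total for lab in CLASS_LABELS}
    return TimeInClassSummary(
        child_id=s.child_id,
        device=s.device.value,
        position=s.position.value,
        minutes=minutes,
        proportions=proportions,
        total_minutes=total,
        empty=(n == 0),
    )
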