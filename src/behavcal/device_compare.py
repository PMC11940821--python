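"""Between-device and between-position comparisons of epoch counts.

The two device models operate on different scales (the GT3X tri-axial
vector magnitude runs roughly 6-10x higher than the uni-axial MW8), so
agreement is assessed with rank correlation and regression of one device
on the other rather than by direct count comparison.  Wrist-worn pairs
track each other approximately linearly; hip-worn pairs are better
described by a low-degree polynomial.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .behaviours import Device, Position
from .errors import ValidationError

PAIRED_COLUMNS = ("child_id", "position", "behaviour", "epoch_index", "count_mw8", "count_gt3x")


@dataclasses.dataclass
class FitResult:
    """A least-squares polynomial relating GT3X counts to MW8 counts."""

    kind: str  # "linear" or "polynomial"
    degree: int
    coefficients: np.ndarray  # ascending powers: c0 + c1*x + ...
    r_squared: float


def pair_channels(labeled: pd.DataFrame, position: Position | str) -> pd.DataFrame:
    """Align MW8 and GT3X epochs recorded at one position.

    Epochs are matched on (child, behaviour, epoch index), so the pairing
    is invariant to row order; unmatched epochs are dropped and their
    number is recorded in ``result.attrs["n_dropped"]``.
    """
    position = Position(position)
    at_pos = labeled[labeled["position"] == position]
    frames = {}
    for device in (Device.MW8, Device.GT3X):
        sub = at_pos[at_pos["device"] == device]
        if sub.empty:
            raise ValidationError(f"no {device.value} epochs at position {position.value}")
        frames[device] = sub[["child_id", "behaviour", "epoch_index", "count"]].rename(
            columns={"count": f"count_{device.value.lower()}"}
        )
    merged = frames[Device.MW8].merge(
        frames[Device.GT3X], on=["child_id", "behaviour", "epoch_index"], how="inner"
    )
    merged = merged.sort_values(["child_id", "behaviour", "epoch_index"], kind="stable")
    merged.insert(1, "position", position)
    merged = merged.reset_index(drop=True)[list(PAIRED_COLUMNS)]
    n_total = len(frames[Device.MW8]) + len(frames[Device.GT3X])
    merged.attrs["n_dropped"] = int(n_total - 2 * len(merged))
    return merged


def spearman_rho(paired: pd.DataFrame) -> float:
    """Spearman rank correlation between paired MW8 and GT3X counts.

    Uses average ranks for ties.  A constant margin makes the statistic
    undefined; NaN is returned with a warning.
    """
    if len(paired) < 3:
        raise ValidationError("need at least 3 pairs for a rank correlation")
    x = paired["count_mw8"].to_numpy(dtype=float)
    y = paired["count_gt3x"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("rank correlation undefined for a constant margin", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def fit_relationship(
    paired: pd.DataFrame, kind: str = "linear", degree: int | None = None
) -> FitResult:
    """Least-squares polynomial fit of GT3X counts on MW8 counts.

    ``kind="linear"`` fixes degree 1; ``kind="polynomial"`` defaults to
    degree 2 (the hip-pair convention) unless a degree is given.
    """
    if kind == "linear":
        degree = 1
    elif kind == "polynomial":
        degree = 2 if degree is None else int(degree)
        if degree < 2:
            raise ValidationError("polynomial fits require degree >= 2")
    else:
        raise ValidationError(f"unknown fit kind {kind!r}")
    x = paired["count_mw8"].to_numpy(dtype=float)
    y = paired["count_gt3x"].to_numpy(dtype=float)
    if len(x) <= degree + 1:
        raise ValidationError(f"need more than {degree + 1} pairs for a degree-{degree} fit")
    if np.unique(x).size <= degree:
        raise ValidationError("design matrix is rank-deficient (too few distinct x values)")
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(kind=kind, degree=degree, coefficients=coeffs, r_squared=r2)


def log1_counts(counts: np.ndarray) -> np.ndarray:
    """log10(count + 1), the plotting transform that keeps zero epochs visible."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    return np.log10(counts + 1.0)


def boxplot_stats(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-cell boxplot summary: median, quartiles and 1.5-IQR whiskers."""
    rows = []
    for (device, position, behaviour), grp in labeled.groupby(
        ["device", "position", "behaviour"], sort=True, observed=True
    ):
        c = grp["count"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(c, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "device": device,
                "position": position,
                "behaviour": behaviour,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": q1 - 1.5 * iqr,
                "whisker_high": q3 + 1.5 * iqr,
                "n_epochs": len(c),
            }
        )
    return pd.DataFrame(rows)
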