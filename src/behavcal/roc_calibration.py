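"""ROC-based cut-point calibration from behaviour-labelled epoch counts.

The six directed behaviours form a strict intensity order, so composite
intensity classes are built by collapsing adjacent behaviours and testing
them One-vs-Rest (OvR):

* ``VPA``   - sprinting vs everything else;
* ``MVPA``  - sprinting + floorball/walk vs the rest;
* ``LMVPA`` - the three mobile behaviours vs the three stationary ones
  (the mobile/stationary split);
* ``MOA``   - sedentary screen time (motionless alert) vs everything else,
  with *below*-threshold direction: low counts indicate the positive class.

For each binary problem the ROC curve is swept over observed count values,
the Youden-optimal threshold (max sensitivity + specificity - 1) is
selected, and the AUC is estimated with a DeLong or stratified-bootstrap
95% confidence interval.  The sedentary band (SED) is not fitted directly:
it is the count range between the MOA cut-off and the LMVPA cut-off.

Threshold conventions: a mobile-class epoch is predicted positive iff its
count strictly exceeds the cut-off ("> c"); the MOA class is predicted
iff the count is strictly below its cut-off ("< c").  Candidate cut-offs
are observed count values, so published integer-valued cut-offs are
representable exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behaviours import Behaviour, Device, Position, MOBILE_BEHAVIOURS
from .errors import DegenerateProblemError, ValidationError
from .synthetic_cohort import ChannelBehaviourParams

ABOVE = "above_threshold_positive"
BELOW = "below_threshold_positive"


@dataclasses.dataclass(frozen=True)
class ClassScheme:
    """A composite binary intensity class over the six behaviours."""

    name: str
    positive_set: frozenset[Behaviour]
    direction: str = ABOVE

    def __post_init__(self) -> None:
        if not self.positive_set:
            raise ValidationError("positive_set must be non-empty")
        if self.positive_set >= set(Behaviour):
            raise ValidationError("positive_set must leave at least one rest behaviour")
        if self.direction not in (ABOVE, BELOW):
            raise ValidationError(f"unknown direction {self.direction!r}")

    @property
    def negative_set(self) -> frozenset[Behaviour]:
        return frozenset(Behaviour) - self.positive_set


VPA = ClassScheme("VPA", frozenset({Behaviour.SPRINTING}))
MVPA = ClassScheme("MVPA", frozenset({Behaviour.SPRINTING, Behaviour.FLOORBALL_WALK}))
LMVPA = ClassScheme("LMVPA", frozenset(MOBILE_BEHAVIOURS))
MOA = ClassScheme("MOA", frozenset({Behaviour.SEDENTARY_SCREEN_TIME}), direction=BELOW)

#: The four OvR schemes in the order calibration tables print them.
OVR_SCHEMES: tuple[ClassScheme, ...] = (VPA, MVPA, LMVPA, MOA)

#: Merged sedentary class used by One-vs-One comparisons.
SED_BEHAVIOURS = frozenset({Behaviour.SEDENTARY_CRAFTS, Behaviour.RECUMBENT_LISTENING})


class RocPoint(NamedTuple):
    threshold: float
    sensitivity: float
    specificity: float


class YoudenResult(NamedTuple):
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclasses.dataclass
class RocResult:
    """Calibration result for one binary scheme on one channel."""

    scheme: ClassScheme
    cutoff: float  # on the original count scale
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    accuracy_band: str
    ci_method: str = "delong"

    @property
    def direction_symbol(self) -> str:
        return ">" if self.scheme.direction == ABOVE else "<"


@dataclasses.dataclass
class CutoffTable:
    """Per-channel intensity thresholds plus the derived sedentary range."""

    device: Device
    position: Position
    vpa_cut: float
    mvpa_cut: float
    lmvpa_cut: float
    moa_cut: float
    results: dict[str, RocResult] = dataclasses.field(default_factory=dict)

    @property
    def sed_range(self) -> tuple[float, float]:
        return (self.moa_cut, self.lmvpa_cut)

    def cuts(self) -> tuple[float, float, float, float]:
        return (self.vpa_cut, self.mvpa_cut, self.lmvpa_cut, self.moa_cut)


def _scores_labels(
    labeled: pd.DataFrame,
    positive: frozenset[Behaviour],
    keep: frozenset[Behaviour],
    negate: bool,
) -> tuple[np.ndarray, np.ndarray]:
    sub = labeled[labeled["behaviour"].isin(keep)]
    labels = sub["behaviour"].isin(positive).to_numpy(dtype=int)
    scores = sub["count"].to_numpy(dtype=float)
    if negate:
        scores = -scores
    return scores, labels


def binarize_ovr(labeled: pd.DataFrame, scheme: ClassScheme) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-Rest binarisation: positive-set behaviours against all others.

    Scores are raw counts; for a below-threshold scheme (MOA) they are
    negated so that higher scores always indicate the positive class.
    """
    scores, labels = _scores_labels(
        labeled, scheme.positive_set, frozenset(Behaviour), scheme.direction == BELOW
    )
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DegenerateProblemError(
            f"scheme {scheme.name}: need at least one positive and one negative epoch"
        )
    return scores, labels


def binarize_ovo(
    labeled: pd.DataFrame,
    class_a: Iterable[Behaviour],
    class_b: Iterable[Behaviour],
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-One binarisation: keep only epochs in the two classes (a = positive)."""
    a, b = frozenset(class_a), frozenset(class_b)
    if a & b:
        raise ValidationError("class_a and class_b must be disjoint")
    if not a or not b:
        raise ValidationError("both classes must be non-empty")
    scores, labels = _scores_labels(labeled, a, a | b, negate=False)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DegenerateProblemError("both classes must be present in the data")
    return scores, labels


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> list[RocPoint]:
    """Sweep the ROC curve over observed score values.

    Candidate thresholds are the unique observed scores plus sentinels
    below the minimum and above the maximum; at threshold ``t`` an epoch is
    predicted positive iff its score is strictly greater than ``t``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    if pos.size == 0 or neg.size == 0:
        raise DegenerateProblemError("need at least one epoch in each class")
    uniq = np.unique(scores)
    thresholds = np.concatenate(([uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]))
    # sens(t) = P(pos > t), spec(t) = P(neg <= t)
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size
    return [RocPoint(float(t), float(se), float(sp)) for t, se, sp in zip(thresholds, sens, spec)]


def youden_cutoff(roc: Sequence[RocPoint]) -> YoudenResult:
    """Select the threshold maximising J = sensitivity + specificity - 1.

    Ties are broken toward the smallest threshold, i.e. the most sensitive
    of the tied operating points.
    """
    if not roc:
        raise ValidationError("ROC curve is empty")
    best = None
    for pt in sorted(roc, key=lambda p: p.threshold):
        j = pt.sensitivity + pt.specificity - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, pt)
    j, pt = best
    return YoudenResult(pt.threshold, pt.sensitivity, pt.specificity, j)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive scores above random negative),
    ties counted half.  Equals the trapezoidal area under the ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateProblemError("need both classes to compute AUC")
    ranks = stats.rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Point AUC and its DeLong variance via per-observation placements."""
    pos = np.sort(np.asarray(scores, dtype=float)[labels == 1])
    neg = np.sort(np.asarray(scores, dtype=float)[labels == 0])
    m, n = pos.size, neg.size
    # placement of each positive among negatives, ties half-weighted
    v10 = (np.searchsorted(neg, pos, side="left") + np.searchsorted(neg, pos, side="right")) / (
        2.0 * n
    )
    v01 = 1.0 - (
        np.searchsorted(pos, neg, side="left") + np.searchsorted(pos, neg, side="right")
    ) / (2.0 * m)
    theta = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return theta, var


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    method: str = "delong",
    seed: int | None = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``delong`` (default) uses the asymptotic placement-variance estimator
    and is deterministic; ``bootstrap`` resamples positives and negatives
    separately (stratified) and takes percentile bounds.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError("level must be in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if method == "delong":
        if n_pos < 2 or n_neg < 2:
            raise ValidationError("DeLong CI requires at least 2 epochs per class")
        theta, var = _delong_variance(np.asarray(scores, dtype=float), labels)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return (float(np.clip(theta - half, 0.0, 1.0)), float(np.clip(theta + half, 0.0, 1.0)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        scores = np.asarray(scores, dtype=float)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        reps = np.empty(n_boot)
        boot_labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
        for b in range(n_boot):
            sample = np.concatenate(
                [rng.choice(pos, size=n_pos), rng.choice(neg, size=n_neg)]
            )
            reps[b] = auc(sample, boot_labels)
        alpha = 1.0 - level
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))
    raise ValidationError(f"unknown CI method {method!r}")


def accuracy_band(auc_value: float) -> str:
    """Discrimination band for an AUC: outstanding / excellent / acceptable / poor."""
    if not (0.0 <= auc_value <= 1.0):
        raise ValidationError(f"AUC {auc_value} outside [0, 1]")
    if auc_value >= 0.90:
        return "outstanding"
    if auc_value >= 0.80:
        return "excellent"
    if auc_value >= 0.70:
        return "acceptable"
    return "poor"


def calibrate_channel(
    labeled: pd.DataFrame,
    device: Device,
    position: Position,
    ci_method: str = "delong",
    seed: int | None = None,
) -> CutoffTable:
    """Run the four OvR calibrations for one device/position channel.

    Returns the per-scheme cut-offs (original count scale; MOA with "<"
    direction), sensitivities, specificities, Youden J, AUC with 95% CI
    and accuracy band, plus the derived sedentary range
    ``(moa_cut, lmvpa_cut)``.
    """
    channel = labeled[(labeled["device"] == device) & (labeled["position"] == position)]
    present = set(channel["behaviour"].unique())
    missing = set(Behaviour) - present
    if missing:
        names = ", ".join(sorted(b.value for b in missing))
        raise ValidationError(
            f"channel {Device(device).value}/{Position(position).value} is missing "
            f"behaviours: {names}"
        )
    results: dict[str, RocResult] = {}
    for scheme in OVR_SCHEMES:
        scores, labels = binarize_ovr(channel, scheme)
        roc = roc_curve(scores, labels)
        yr = youden_cutoff(roc)
        cutoff = -yr.cutoff if scheme.direction == BELOW else yr.cutoff
        auc_value = auc(scores, labels)
        ci = auc_ci(scores, labels, method=ci_method, seed=seed)
        results[scheme.name] = RocResult(
            scheme=scheme,
            cutoff=float(cutoff),
            sensitivity=yr.sensitivity,
            specificity=yr.specificity,
            youden_j=yr.youden_j,
            auc=auc_value,
            auc_ci=ci,
            n_pos=int(labels.sum()),
            n_neg=int(len(labels) - labels.sum()),
            accuracy_band=accuracy_band(auc_value),
            ci_method=ci_method,
        )
    return CutoffTable(
        device=Device(device),
        position=Position(position),
        vpa_cut=results["VPA"].cutoff,
        mvpa_cut=results["MVPA"].cutoff,
        lmvpa_cut=results["LMVPA"].cutoff,
        moa_cut=results["MOA"].cutoff,
        results=results,
    )


def gaussian_mixture_auc(
    params: Iterable[ChannelBehaviourParams], scheme: ClassScheme
) -> float:
    """Closed-form OvR AUC when every behaviour's counts are normal.

    For a normal positive behaviour p and negative behaviour q the pairwise
    AUC is Phi((mu_p - mu_q)/sqrt(sd_p^2 + sd_q^2)); the scheme AUC is the
    equal-weight mean over all (positive, negative) behaviour pairs, with
    the difference sign flipped for a below-threshold scheme.  A pair with
    zero variance and equal means contributes 0.5.
    """
    by_behaviour = {p.behaviour: p for p in params}
    missing = set(Behaviour) - set(by_behaviour)
    if missing:
        names = ", ".join(sorted(b.value for b in missing))
        raise ValidationError(f"params missing behaviours: {names}")
    sign = -1.0 if scheme.direction == BELOW else 1.0
    vals = []
    for bp in scheme.positive_set:
        for bq in scheme.negative_set:
            p, q = by_behaviour[bp], by_behaviour[bq]
            denom = np.hypot(p.sd, q.sd)
            delta = sign * (p.mean - q.mean)
            if denom == 0:
                vals.append(0.5 if delta == 0 else (1.0 if delta > 0 else 0.0))
            else:
                vals.append(float(stats.norm.cdf(delta / denom)))
    return float(np.mean(vals))
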