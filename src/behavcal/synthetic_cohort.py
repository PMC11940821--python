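"""Synthetic cohorts of behaviour-labelled epoch counts.

The generator emulates the structure of a directed-activity calibration
session: each of ``n_children`` children performs the six behaviours in
turn, each bout lasting 8-10 minutes, while four channels (MW8/GT3X at
wrist and hip) record counts per 30-s epoch.  Per-epoch counts are drawn
from a configurable marginal family whose mean and SD per
(device, position, behaviour) cell default to the published calibration
moments in :mod:`behavcal.reference`.

Channels worn at the same position observe the same movement, so their
epochs are coupled through a Gaussian copula on a shared latent per-epoch
intensity; the copula is parameterised by the target Spearman rank
correlation between paired devices (0.9 by default).

Marginal families
-----------------
normal
    ``mean + sd * z``.  Counts can go slightly negative for near-zero
    cells; rank-based analyses are unaffected, and closed-form AUC
    oracles exist for this family, which makes it the default.
truncated_normal
    Normal left-truncated at zero (moments shift upward for cells whose
    mean is within ~2 SD of zero).
lognormal
    Moment-matched log-normal; strictly positive, right-skewed.
zero_inflated_gamma
    With probability ``zero_inflation`` the epoch count is exactly 0,
    otherwise a moment-matched gamma draw whose mean is rescaled so the
    cell mean is preserved.  Closest to real stationary-behaviour data,
    where whole motionless epochs are common.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .behaviours import Behaviour, Device, Position, coerce_behaviour
from .epoch_data import (
    BehaviourProtocol,
    EpochSeries,
    LABELED_COLUMNS,
    ProtocolRecord,
    empty_labeled,
)
from .errors import ConfigurationError, ValidationError
from .reference import REFERENCE_MOMENTS

FAMILIES = ("normal", "truncated_normal", "lognormal", "zero_inflated_gamma")


@dataclasses.dataclass(frozen=True)
class ChannelBehaviourParams:
    """Mean and SD of counts/30 s for one (device, position, behaviour) cell."""

    device: Device
    position: Position
    behaviour: Behaviour
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ConfigurationError("mean and sd must be non-negative")


def reference_params() -> list[ChannelBehaviourParams]:
    """The default parameter set: the published calibration moments."""
    return [
        ChannelBehaviourParams(device=d, position=p, behaviour=b, mean=m, sd=s)
        for (d, p, b), (m, s) in REFERENCE_MOMENTS.items()
    ]


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the calibration study's design: 30 children,
    8-10 minute bouts at 30-s epochs, all four channels with the published
    per-cell moments, and a cross-device rank correlation of 0.9.
    """

    n_children: int = 30
    duration_minutes_range: tuple[float, float] = (8.0, 10.0)
    epoch_seconds: float = 30.0
    family: str = "normal"
    params: list[ChannelBehaviourParams] = dataclasses.field(default_factory=reference_params)
    cross_device_rank_correlation: float = 0.9
    zero_inflation: float | Mapping[Behaviour, float] = 0.0
    child_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duration_minutes_range
        if not (0 < lo <= hi):
            raise ConfigurationError("duration_minutes_range must satisfy 0 < lo <= hi")
        if not (0.0 <= self.cross_device_rank_correlation <= 1.0):
            raise ConfigurationError("cross_device_rank_correlation must be in [0, 1]")
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.n_children < 0:
            raise ConfigurationError("n_children must be non-negative")
        if self.epoch_seconds <= 0:
            raise ConfigurationError("epoch_seconds must be positive")
        for prm in self.params:
            if self.family in ("lognormal", "zero_inflated_gamma") and prm.mean == 0:
                raise ConfigurationError(
                    f"family {self.family!r} requires a positive mean; "
                    f"{prm.device.value}/{prm.position.value}/{prm.behaviour.value} has mean 0"
                )
        behaviours_by_channel: dict[tuple[Device, Position], set[Behaviour]] = {}
        for prm in self.params:
            behaviours_by_channel.setdefault((prm.device, prm.position), set()).add(prm.behaviour)
        for (dev, pos), got in behaviours_by_channel.items():
            missing = set(Behaviour) - got
            if missing:
                names = ", ".join(sorted(b.value for b in missing))
                raise ConfigurationError(
                    f"channel {dev.value}/{pos.value} is missing behaviours: {names}"
                )

    def zero_inflation_for(self, behaviour: Behaviour) -> float:
        if isinstance(self.zero_inflation, Mapping):
            return float(self.zero_inflation.get(behaviour, 0.0))
        return float(self.zero_inflation)

    def channels(self) -> list[tuple[Device, Position]]:
        """Requested channels in canonical (position, device) order."""
        seen = {(p.device, p.position) for p in self.params}
        order = {
            (d, p): i
            for i, (p, d) in enumerate(
                (p, d) for p in Position for d in Device
            )
        }
        return sorted(seen, key=lambda ch: order[ch])

    def param_lookup(self) -> dict[tuple[Device, Position, Behaviour], ChannelBehaviourParams]:
        return {(p.device, p.position, p.behaviour): p for p in self.params}

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        """Build a config from a plain mapping (parsed YAML/JSON)."""
        kwargs = dict(raw)
        if "params" in kwargs and kwargs["params"] is not None:
            kwargs["params"] = [
                ChannelBehaviourParams(
                    device=Device(p["device"]),
                    position=Position(p["position"]),
                    behaviour=coerce_behaviour(p["behaviour"]),
                    mean=float(p["mean"]),
                    sd=float(p["sd"]),
                )
                for p in kwargs["params"]
            ]
        if "duration_minutes_range" in kwargs and kwargs["duration_minutes_range"] is not None:
            kwargs["duration_minutes_range"] = tuple(kwargs["duration_minutes_range"])
        if "zero_inflation" in kwargs and isinstance(kwargs["zero_inflation"], Mapping):
            kwargs["zero_inflation"] = {
                coerce_behaviour(k): float(v) for k, v in kwargs["zero_inflation"].items()
            }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        """Plain-data mirror of the config, suitable for YAML/JSON."""
        zi = self.zero_inflation
        if isinstance(zi, Mapping):
            zi = {b.value: float(v) for b, v in zi.items()}
        return {
            "n_children": self.n_children,
            "duration_minutes_range": list(self.duration_minutes_range),
            "epoch_seconds": self.epoch_seconds,
            "family": self.family,
            "params": [
                {
                    "device": p.device.value,
                    "position": p.position.value,
                    "behaviour": p.behaviour.value,
                    "mean": p.mean,
                    "sd": p.sd,
                }
                for p in self.params
            ],
            "cross_device_rank_correlation": self.cross_device_rank_correlation,
            "zero_inflation": zi,
            "child_effect_sd": self.child_effect_sd,
            "seed": self.seed,
        }


def _marginal_from_latent(
    z: np.ndarray, mean: float, sd: float, family: str, zero_p: float
) -> np.ndarray:
    """Map standard-normal latents to the configured marginal via its quantile."""
    if family == "normal":
        return mean + sd * z
    u = stats.norm.cdf(z)
    if sd == 0:
        base = np.full_like(z, mean)
        if family == "zero_inflated_gamma" and zero_p > 0:
            base = np.where(u < zero_p, 0.0, mean / (1.0 - zero_p))
        return base
    if family == "truncated_normal":
        a = (0.0 - mean) / sd
        return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return stats.lognorm.ppf(u, s=np.sqrt(sigma2), scale=np.exp(mu))
    if family == "zero_inflated_gamma":
        # continuous-part mean rescaled so the cell mean is preserved
        m_c = mean / (1.0 - zero_p) if zero_p < 1 else mean
        shape = (m_c / sd) ** 2
        scale = sd**2 / m_c
        out = np.zeros_like(z)
        cont = u >= zero_p
        out[cont] = stats.gamma.ppf((u[cont] - zero_p) / (1.0 - zero_p), a=shape, scale=scale)
        return out
    raise ConfigurationError(f"unknown family {family!r}")  # pragma: no cover


def _copula_loading(rank_correlation: float) -> float:
    """Latent loading a such that corr(a*z+e1, a*z+e2) yields the target
    Spearman correlation under a Gaussian copula."""
    rho_gauss = 2.0 * np.sin(np.pi * rank_correlation / 6.0)
    return float(np.sqrt(rho_gauss))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a behaviour-labelled cohort as a tidy counts frame.

    For every child and behaviour one bout length is drawn uniformly from
    the duration range and floored to whole epochs; every channel emits
    that many epochs, so paired channels align one-to-one in time.
    Channels at the same position share a per-epoch latent intensity
    through the Gaussian copula.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lookup = config.param_lookup()
    channels = config.channels()
    loading = _copula_loading(config.cross_device_rank_correlation)
    lo, hi = config.duration_minutes_range

    frames: list[pd.DataFrame] = []
    for i in range(config.n_children):
        child_id = f"child{i + 1:02d}"
        child_shift = (
            rng.normal(0.0, config.child_effect_sd) if config.child_effect_sd > 0 else 0.0
        )
        for behaviour in Behaviour:
            minutes = rng.uniform(lo, hi)
            n_epochs = int(np.floor(minutes * 60.0 / config.epoch_seconds))
            if n_epochs == 0:
                continue
            zero_p = config.zero_inflation_for(behaviour)
            for position in Position:
                devices = [d for (d, p) in channels if p == position]
                if not devices:
                    continue
                shared = rng.standard_normal(n_epochs)
                for device in devices:
                    eps = rng.standard_normal(n_epochs)
                    z = loading * shared + np.sqrt(1.0 - loading**2) * eps
                    prm = lookup[(device, position, behaviour)]
                    counts = _marginal_from_latent(
                        z + child_shift, prm.mean, prm.sd, config.family, zero_p
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "child_id": child_id,
                                "device": device,
                                "position": position,
                                "behaviour": behaviour,
                                "epoch_index": np.arange(n_epochs),
                                "count": counts,
                            }
                        )
                    )
    if not frames:
        return empty_labeled()
    out = pd.concat(frames, ignore_index=True)
    return out[list(LABELED_COLUMNS)]


def cohort_to_series(
    labeled: pd.DataFrame,
    epoch_seconds: float = 30.0,
    session_start: str | pd.Timestamp = "2021-01-01T09:00:00",
) -> tuple[list[EpochSeries], BehaviourProtocol]:
    """Lay a labelled cohort out as epoch time series plus a protocol.

    Bouts are placed back-to-back in ascending intensity order from a
    common session start, so that extracting segments with the returned
    protocol reproduces the labelled counts.  Counts are clipped at zero
    when writing series (a physical device never reports negative counts).
    """
    session_start = pd.Timestamp(session_start)
    series: list[EpochSeries] = []
    records: list[ProtocolRecord] = []
    if labeled.empty:
        return series, BehaviourProtocol(records=[])

    for child, child_grp in labeled.groupby("child_id", sort=True):
        # bout lengths shared across channels: take the max per behaviour
        bout_epochs = {
            b: int(g.groupby(["device", "position"], observed=True).size().max())
            for b, g in child_grp.groupby("behaviour", sort=False, observed=True)
        }
        offsets: dict[Behaviour, float] = {}
        t = 0.0
        for b in Behaviour:
            if b not in bout_epochs:
                continue
            offsets[b] = t
            dur = bout_epochs[b] * epoch_seconds
            records.append(
                ProtocolRecord(
                    child_id=str(child),
                    behaviour=b,
                    start=session_start + pd.Timedelta(seconds=t),
                    stop=session_start + pd.Timedelta(seconds=t + dur),
                )
            )
            t += dur
        for (device, position), ch_grp in child_grp.groupby(
            ["device", "position"], sort=True, observed=True
        ):
            chunks = []
            for b in Behaviour:
                sub = ch_grp[ch_grp["behaviour"] == b].sort_values("epoch_index")
                if not sub.empty:
                    chunks.append(sub["count"].to_numpy())
            series.append(
                EpochSeries(
                    child_id=str(child),
                    device=device,
                    position=position,
                    start_time=session_start,
                    counts=np.clip(np.concatenate(chunks), 0.0, None),
                    epoch_seconds=epoch_seconds,
                )
            )
    return series, BehaviourProtocol(records=records)


@dataclasses.dataclass
class RawSampleBlock:
    """A block of raw per-sample accelerometer output at a fixed rate."""

    samples: np.ndarray
    sampling_hz: int = 50
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_hz <= 0:
            raise ValidationError("sampling_hz must be positive")
        if np.any(self.samples < 0):
            raise ValidationError("raw samples must be non-negative")
        if self.samples.size % self.sampling_hz != 0:
            raise ValidationError(
                f"sample vector length {self.samples.size} is not a whole number "
                f"of seconds at {self.sampling_hz} Hz"
            )


def counts_from_raw(block: RawSampleBlock) -> np.ndarray:
    """Accumulate raw samples into per-epoch activity counts.

    Implements the MW8 counting rule: within every second keep the highest
    of the per-second samples, then sum those per-second maxima over the
    epoch.  The block must contain a whole number of epochs.
    """
    per_second = block.samples.reshape(-1, block.sampling_hz).max(axis=1)
    sec_per_epoch = block.epoch_seconds
    if sec_per_epoch != int(sec_per_epoch):
        raise ValidationError("epoch_seconds must be a whole number of seconds")
    sec_per_epoch = int(sec_per_epoch)
    if per_second.size % sec_per_epoch != 0:
        raise ValidationError(
            f"{per_second.size} s of samples is not a whole number of "
            f"{sec_per_epoch}-s epochs"
        )
    return per_second.reshape(-1, sec_per_epoch).sum(axis=1)


def empirical_moments(labeled: pd.DataFrame, epoch_seconds: float = 30.0) -> pd.DataFrame:
    """Per-cell sample mean/SD of counts and mean labelled minutes per child.

    SD uses the sample (n-1) convention; a cell with a single epoch
    reports SD 0 and is flagged in the ``single_epoch`` column.
    """
    if labeled.empty:
        raise ValidationError("labelled counts are empty")
    grouped = labeled.groupby(["device", "position", "behaviour"], sort=True, observed=True)
    rows = []
    for (device, position, behaviour), grp in grouped:
        n = len(grp)
        per_child_minutes = (
            grp.groupby("child_id", observed=True).size() * epoch_seconds / 60.0
        )
        rows.append(
            {
                "device": device,
                "position": position,
                "behaviour": behaviour,
                "n_children": grp["child_id"].nunique(),
                "n_epochs": n,
                "mean": float(grp["count"].mean()),
                "sd": float(grp["count"].std(ddof=1)) if n > 1 else 0.0,
                "minutes": float(per_child_minutes.mean()),
                "single_epoch": n == 1,
            }
        )
    return pd.DataFrame(rows)
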