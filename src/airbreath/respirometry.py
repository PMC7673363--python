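"""Intermittent-flow respirometry: from raw O2 traces to standard metabolic rate.

The measurement principle: a fish sits in a sealed chamber whose dissolved-oxygen
concentration is logged continuously.  The system alternates *flush* phases
(oxygenated water pumped through, chamber re-equilibrates) with *closed* phases
(chamber sealed, O2 declines at a rate set by the animal's oxygen uptake plus
bacterial background respiration).  Each closed phase yields one slope
(mg O2 L^-1 h^-1); after subtracting a linearly interpolated background slope
measured in empty chambers before and after the trial, the slope times the
effective water volume (chamber + tubing - fish) gives whole-animal oxygen
uptake MO2 (mg O2 h^-1).  Standard metabolic rate (SMR) is then estimated as a
low quantile of the per-cycle MO2 distribution over a long (overnight) trial,
on the premise that the quietest cycles reflect maintenance metabolism while
activity only ever adds to oxygen demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChamberConfig",
    "CyclePlan",
    "O2Trace",
    "CycleWindow",
    "SlopeEstimate",
    "BackgroundModel",
    "MO2Series",
    "SMREstimate",
    "segment_cycles",
    "fit_slope",
    "background_at",
    "background_from_traces",
    "compute_mo2",
    "estimate_smr",
    "convert_saturation",
]


@dataclass(frozen=True)
class ChamberConfig:
    """Geometry of one respirometry channel.

    Volumes in mL, mass in g.  If ``fish_volume`` is not given it is derived
    from mass assuming tissue density 1.0 g mL^-1 (standard respirometry
    practice when only wet mass is available).
    """

    chamber_volume: float
    tubing_volume: float
    fish_mass: float
    fish_volume: float | None = None
    channel_id: str = ""

    def __post_init__(self) -> None:
        if self.chamber_volume <= 0:
            raise ValueError("chamber_volume must be positive")
        if self.tubing_volume < 0:
            raise ValueError("tubing_volume must be non-negative")
        if self.fish_volume is None:
            object.__setattr__(self, "fish_volume", float(self.fish_mass))
        if self.fish_volume < 0:
            raise ValueError("fish_volume must be non-negative")
        if self.fish_volume >= self.chamber_volume + self.tubing_volume:
            raise ValueError("fish_volume must be smaller than the water volume")

    @property
    def effective_volume_l(self) -> float:
        """Water volume actually respired from, in litres."""
        return (self.chamber_volume + self.tubing_volume - self.fish_volume) / 1000.0


@dataclass(frozen=True)
class CyclePlan:
    """Timing of the flush/closed cycle, in seconds.

    Defaults follow a common overnight protocol: 2 min flush every 8 min,
    first minute after closure discarded (mixing transient), 2 s sampling,
    16 h total.
    """

    flush_duration: float = 120.0
    closed_duration: float = 360.0
    discard_initial: float = 60.0
    sampling_interval: float = 2.0
    total_duration: float = 16 * 3600.0

    def __post_init__(self) -> None:
        if self.flush_duration < 0 or self.closed_duration <= 0:
            raise ValueError("flush/closed durations invalid")
        if not 0 <= self.discard_initial < self.closed_duration:
            raise ValueError("discard_initial must lie within the closed phase")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def period(self) -> float:
        return self.flush_duration + self.closed_duration


@dataclass
class O2Trace:
    """Dissolved-oxygen time series for one channel.

    ``timestamps`` s (strictly increasing), ``o2`` mg O2 L^-1.
    """

    timestamps: np.ndarray
    o2: np.ndarray
    temperature: float = 25.0
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.timestamps.shape != self.o2.shape:
            raise ValueError("timestamps and o2 must have equal length")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, counting one sampling interval per point."""
        if len(self) < 2:
            return 0.0
        dt = float(np.median(np.diff(self.timestamps)))
        return float(self.timestamps[-1] - self.timestamps[0] + dt)


@dataclass(frozen=True)
class CycleWindow:
    """Retained measurement window of one closed phase."""

    cycle_index: int
    t_start: float  # closed-phase start + discard
    t_end: float  # end of the cycle (exclusive)
    timestamps: np.ndarray = field(repr=False)
    o2: np.ndarray = field(repr=False)

    @property
    def midpoint_time(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class SlopeEstimate:
    cycle_index: int
    slope: float  # mg O2 L^-1 h^-1, negative when O2 declines
    intercept: float  # mg O2 L^-1 at t = 0 of the window's clock
    r_squared: float
    midpoint_time: float  # s


@dataclass(frozen=True)
class BackgroundModel:
    """Linear-in-time bacterial background respiration for one channel.

    ``pre_slope``/``post_slope`` are the blank-chamber O2 slopes
    (mg O2 L^-1 h^-1, negative = decline) measured before and after the trial;
    between them the background is interpolated linearly in time.
    """

    pre_slope: float
    post_slope: float
    trial_start: float
    trial_end: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        if self.trial_end <= self.trial_start:
            raise ValueError("trial_end must exceed trial_start")

    @classmethod
    def constant(
        cls, slope: float, trial_start: float, trial_end: float, channel_id: str = ""
    ) -> "BackgroundModel":
        """Single-blank fallback: constant background at the one measured slope."""
        logger.warning(
            "only one blank available for channel %r; background treated as constant",
            channel_id,
        )
        return cls(slope, slope, trial_start, trial_end, channel_id)


@dataclass
class MO2Series:
    """Per-cycle whole-animal oxygen uptake for one fish, background-corrected."""

    values: np.ndarray  # mg O2 h^-1
    background_fraction: np.ndarray  # |bg| / |fish slope| per cycle
    cycle_times: np.ndarray  # midpoint s
    channel_id: str = ""
    fish_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.background_fraction = np.asarray(self.background_fraction, dtype=float)
        self.cycle_times = np.asarray(self.cycle_times, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SMREstimate:
    smr: float  # mg O2 h^-1
    method: str
    n_cycles: int
    mean_background_fraction: float  # percent


def segment_cycles(trace: O2Trace, plan: CyclePlan) -> list[CycleWindow]:
    """Cut a trace into the retained measurement window of each closed phase.

    Windows are ``[cycle_start + flush + discard, cycle_end)`` relative to the
    first sample; trailing partial cycles are dropped, never extrapolated.
    """
    if len(trace) >= 2 and not np.all(np.diff(trace.timestamps) > 0):
        raise ValueError("timestamps must be strictly increasing")
    n_cycles = int(np.floor(trace.duration / plan.period + 1e-9))
    if n_cycles < 1:
        raise ValueError(
            f"trace too short: {trace.duration:.0f} s < one {plan.period:.0f} s cycle"
        )
    t0 = float(trace.timestamps[0])
    windows: list[CycleWindow] = []
    for k in range(n_cycles):
        lo = t0 + k * plan.period + plan.flush_duration + plan.discard_initial
        hi = t0 + (k + 1) * plan.period
        mask = (trace.timestamps >= lo) & (trace.timestamps < hi)
        windows.append(
            CycleWindow(
                cycle_index=k,
                t_start=lo,
                t_end=hi,
                timestamps=trace.timestamps[mask],
                o2=trace.o2[mask],
            )
        )
    return windows


def fit_slope(window: CycleWindow) -> SlopeEstimate:
    """OLS line of O2 against time over one retained window.

    The slope is reported per hour.  r^2 of a zero-variance response is
    defined as 0 (a flat trace carries no fit-quality information).
    """
    t, y = window.timestamps, window.o2
    if t.size < 3:
        raise ValueError(f"cycle {window.cycle_index}: need >= 3 samples, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError(f"cycle {window.cycle_index}: constant time values")
    tc = t - t[0]
    if np.ptp(y) == 0:
        # constant response: slope exactly zero, r^2 defined as 0
        return SlopeEstimate(
            cycle_index=window.cycle_index,
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            midpoint_time=window.midpoint_time,
        )
    slope_s, intercept = np.polyfit(tc, y, 1)
    resid = y - (slope_s * tc + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return SlopeEstimate(
        cycle_index=window.cycle_index,
        slope=float(slope_s) * 3600.0,
        intercept=float(intercept),
        r_squared=r2,
        midpoint_time=window.midpoint_time,
    )


def background_at(model: BackgroundModel, t: float) -> float:
    """Background slope (mg O2 L^-1 h^-1) at time ``t``, linear between blanks.

    No extrapolation: ``t`` must lie within [trial_start, trial_end].
    """
    if not (model.trial_start <= t <= model.trial_end):
        raise ValueError(
            f"t={t} outside trial [{model.trial_start}, {model.trial_end}]"
        )
    frac = (t - model.trial_start) / (model.trial_end - model.trial_start)
    return model.pre_slope + frac * (model.post_slope - model.pre_slope)


def background_from_traces(
    pre: O2Trace | None,
    post: O2Trace | None,
    plan: CyclePlan,
    trial_start: float,
    trial_end: float,
    channel_id: str = "",
) -> BackgroundModel:
    """Fit a BackgroundModel from blank (empty-chamber) traces.

    Each blank trace is segmented and slope-fitted like a fish trace; the mean
    slope over its cycles is the blank value.  With only one blank the
    background is constant at that value.
    """

    def _mean_slope(trace: O2Trace) -> float:
        slopes = [fit_slope(w) for w in segment_cycles(trace, plan)]
        return float(np.mean([s.slope for s in slopes]))

    if pre is None and post is None:
        raise ValueError("at least one blank trace is required")
    if pre is None:
        return BackgroundModel.constant(_mean_slope(post), trial_start, trial_end, channel_id)
    if post is None:
        return BackgroundModel.constant(_mean_slope(pre), trial_start, trial_end, channel_id)
    return BackgroundModel(
        _mean_slope(pre), _mean_slope(post), trial_start, trial_end, channel_id
    )


def compute_mo2(
    slope: SlopeEstimate, bg: float, chamber: ChamberConfig
) -> tuple[float, float]:
    """Convert one background-corrected slope to oxygen uptake.

    uptake = (|fish slope| - |background slope|) x effective volume (L),
    in mg O2 h^-1.  Returns ``(uptake, background_share)`` where the share is
    |bg| / |fish slope| (NaN for a zero fish slope).  A background exceeding
    the fish slope yields a negative uptake, which is retained and flagged so
    the downstream quantile estimator sees the raw distribution.
    """
    eff = chamber.effective_volume_l
    if eff <= 0:
        raise ValueError("non-positive effective volume")
    uptake = (abs(slope.slope) - abs(bg)) * eff
    share = abs(bg) / abs(slope.slope) if slope.slope != 0 else float("nan")
    if uptake < 0:
        logger.debug(
            "cycle %d channel %r: background %.4g exceeds fish slope %.4g; "
            "negative uptake retained",
            slope.cycle_index,
            chamber.channel_id,
            bg,
            slope.slope,
        )
    return uptake, share


def estimate_smr(
    series: MO2Series,
    quantile: float = 0.2,
    method: str = "quantile",
    min_cycles: int = 5,
    clamp_zero: bool = False,
) -> SMREstimate:
    """Estimate SMR from the per-cycle uptake distribution.

    ``method='quantile'`` (default): the ``quantile``-quantile of the values
    under sorted-order linear interpolation (plotting position (k-1)/(n-1)),
    the dominant convention for the "lowest 20th percentile" SMR estimator.
    ``method='mean_lowest'``: mean of the lowest ``quantile`` fraction of
    values — the alternative reading, kept behind this switch.
    """
    n = len(series)
    if n < min_cycles:
        raise ValueError(f"need at least {min_cycles} cycles, got {n}")
    vals = series.values
    if method == "quantile":
        smr = float(np.quantile(vals, quantile, method="linear"))
        descriptor = f"quantile[q={quantile:g}]"
    elif method == "mean_lowest":
        k = max(1, int(np.ceil(quantile * n)))
        smr = float(np.mean(np.sort(vals)[:k]))
        descriptor = f"mean_lowest[frac={quantile:g}]"
    else:
        raise ValueError(f"unknown SMR method {method!r}")
    if clamp_zero and smr < 0:
        smr = 0.0
        descriptor += "+clamp0"
    with np.errstate(invalid="ignore"):
        frac = series.background_fraction
        mean_bg = float(np.nanmean(frac) * 100.0) if np.isfinite(frac).any() else float("nan")
    return SMREstimate(smr=smr, method=descriptor, n_cycles=n, mean_background_fraction=mean_bg)


def convert_saturation(sat: float | np.ndarray, solubility: float) -> float | np.ndarray:
    """Percent air saturation -> concentration mg O2 L^-1.

    ``solubility`` is the air-equilibrated concentration (100% saturation) at
    the prevailing temperature/salinity, supplied by the user.
    """
    sat = np.asarray(sat, dtype=float)
    if np.any(sat < 0) or solubility <= 0:
        raise ValueError("saturation must be >= 0 and solubility > 0")
    out = sat / 100.0 * solubility
    return float(out) if out.ndim == 0 else out


def mo2_series_from_trace(
    trace: O2Trace,
    plan: CyclePlan,
    chamber: ChamberConfig,
    background: BackgroundModel | None = None,
    fish_id: str = "",
    r2_threshold: float | None = None,
) -> MO2Series:
    """Full per-channel reduction: segment, fit slopes, correct, convert.

    ``r2_threshold`` optionally drops cycles with poor linear fits; off by
    default (no fit-quality exclusion unless requested).
    """
    windows = segment_cycles(trace, plan)
    slopes = [fit_slope(w) for w in windows]
    if r2_threshold is not None:
        kept = [s for s in slopes if s.r_squared >= r2_threshold]
        if len(kept) < len(slopes):
            logger.info(
                "channel %r: dropped %d/%d cycles below r2 %.2f",
                trace.channel_id,
                len(slopes) - len(kept),
                len(slopes),
                r2_threshold,
            )
        slopes = kept
    values, shares, times = [], [], []
    for s in slopes:
        bg = background_at(background, s.midpoint_time) if background is not None else 0.0
        uptake, share = compute_mo2(s, bg, chamber)
        values.append(uptake)
        shares.append(share)
        times.append(s.midpoint_time)
    n_neg = int(np.sum(np.array(values) < 0))
    if n_neg:
        logger.warning(
            "channel %r: %d/%d cycles with background exceeding the fish slope "
            "(negative uptake retained)",
            trace.channel_id,
            n_neg,
            len(values),
        )
    return MO2Series(
        values=np.array(values),
        background_fraction=np.array(shares),
        cycle_times=np.array(times),
        channel_id=trace.channel_id,
        fish_id=fish_id,
    )


__all__.append("mo2_series_from_trace")
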