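"""Synthetic data with known ground truth for every pipeline stage.

Generates the four input streams the analysis consumes — respirometry O2
traces, air-breath event tables, 2-D trajectories, and metadata — from an
explicit statistical model, so each stage can be verified against the truth
that generated its input.

The generators mirror a factorial repeated-measures study: groups of fish,
each measured at two acclimation temperatures and filmed at three ambient
oxygen saturations, with overnight intermittent-flow respirometry per fish.

Breathing synchrony is modelled as a common-trigger (batch-arrival) process:
besides an independent Poisson stream per fish, group-level triggers occur at
a calibrated rate and each fish joins each trigger independently with
participation probability p, breathing within a short jitter window.  The
trigger rate is calibrated internally so the expected per-fish event rate is
invariant to p: batches change the *timing* structure (and hence the
dispersion coefficient), not the totals.

Trajectories follow a persistent random walk in a circular arena with an
attraction term of strength kappa toward the group centroid and reflection at
the wall; larger kappa gives tighter (more cohesive) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinematics import TrajectorySet
from .respirometry import BackgroundModel, ChamberConfig, CyclePlan, O2Trace

__all__ = [
    "StudyDesign",
    "EffectConfig",
    "simulate_o2_trace",
    "simulate_breath_events",
    "simulate_trajectories",
    "simulate_tidy_dataset",
    "simulate_study",
]


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout and recording parameters of the emulated study."""

    n_groups: int = 6
    group_size: int = 7
    temperatures: tuple = (25, 30)
    o2_levels: tuple = (100, 60, 20)
    trial_duration: float = 720.0  # s of filming per trial
    respirometry_duration_h: float = 16.0
    frame_rate: float = 25.0
    arena_area: float = 3117.0  # cm^2, circular
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.group_size) < 1 or not self.o2_levels:
            raise ValueError("counts must be positive and levels non-empty")

    @property
    def n_fish(self) -> int:
        return self.n_groups * self.group_size

    @property
    def arena_radius(self) -> float:
        return float(np.sqrt(self.arena_area / np.pi))


@dataclass(frozen=True)
class EffectConfig:
    """True effect sizes and noise levels behind the generated data.

    These are free simulation parameters, set to qualitatively mirror the
    directional biology (more breaths in severe hypoxia, higher SMR when
    warm-acclimated, weak individual-level temperature effect); they are
    synthetic defaults, not estimates from any real dataset.
    """

    # metabolic model: SMR = smr_baseline * mass^mass_exponent * temp_factor^(T=30)
    smr_baseline: float = 0.15  # mg O2 h^-1 at 1 g, 25 degC
    mass_exponent: float = 0.89  # teleost allometric slope
    temp_factor: float = 1.5  # multiplicative effect of 30 vs 25 degC
    smr_noise_sd: float = 0.10  # lognormal sd on log SMR
    mass_mean: float = 1.651  # g, wet mass
    mass_cv: float = 0.20
    # air-breathing model
    breath_rate_base: float = 0.5  # events min^-1 fish^-1 at 100%, 25 degC
    o2_rate_multipliers: dict = field(
        default_factory=lambda: {100: 1.0, 60: 1.0, 20: 1.45}
    )
    temp_rate_multiplier: float = 1.2  # 30 vs 25 degC
    synchrony_participation: float = 0.15  # p: probability of joining a trigger
    trigger_rate: float | None = None  # events min^-1; None = calibrated to p
    trigger_jitter: float = 2.0  # s within which joiners surface
    # trajectory model
    cohesion_attraction: float = 0.3  # kappa, cm per frame toward centroid
    speed_scale: float = 0.12  # cm per frame step length
    heading_persistence: float = 0.5
    heading_noise: float = 1.0
    # respirometry trace model
    activity_burst_prob: float = 0.5  # fraction of cycles with extra uptake
    activity_burst_mean: float = 0.5  # burst mean as a fraction of SMR
    trace_noise_sd: float = 0.0  # mg O2 L^-1 measurement noise
    o2_saturation: float = 8.0  # mg O2 L^-1 at 100% air saturation
    background_pre: float = -0.05  # blank slopes, mg O2 L^-1 h^-1
    background_post: float = -0.15


# ---------------------------------------------------------------------------
# respirometry traces
# ---------------------------------------------------------------------------


def simulate_o2_trace(
    chamber: ChamberConfig,
    plan: CyclePlan,
    uptake_per_cycle: np.ndarray,
    background: BackgroundModel | None = None,
    noise_sd: float = 0.0,
    saturation: float = 8.0,
    rng: np.random.Generator | int | None = None,
) -> O2Trace:
    """One intermittent-flow trace with known per-cycle uptake.

    During each closed phase O2 declines linearly at
    (uptake / effective volume + |background|); flush phases relax
    exponentially back toward saturation with a time constant such that a full
    flush reaches >= 99% of saturation.  Gaussian measurement noise is added
    on top.
    """
    rng = np.random.default_rng(rng)
    uptake_per_cycle = np.asarray(uptake_per_cycle, dtype=float)
    n_cycles = uptake_per_cycle.size
    dt = plan.sampling_interval
    eff = chamber.effective_volume_l
    tau = plan.flush_duration / np.log(100.0)  # 99% recovery per flush
    times = np.arange(0.0, n_cycles * plan.period, dt)
    o2 = np.empty_like(times)
    level = saturation
    for k in range(n_cycles):
        in_cycle = (times >= k * plan.period) & (times < (k + 1) * plan.period)
        tc = times[in_cycle] - k * plan.period
        flush = tc < plan.flush_duration
        o2_cyc = np.empty_like(tc)
        o2_cyc[flush] = saturation - (saturation - level) * np.exp(-tc[flush] / tau)
        close_start = saturation - (saturation - level) * np.exp(
            -plan.flush_duration / tau
        )
        # background evaluated at the midpoint of the retained measurement
        # window, matching where the analysis evaluates its linear model
        t_mid = k * plan.period + 0.5 * (
            plan.flush_duration + plan.discard_initial + plan.period
        )
        bg = (
            abs(
                background.pre_slope
                + (background.post_slope - background.pre_slope)
                * min(max(t_mid / (n_cycles * plan.period), 0.0), 1.0)
            )
            if background is not None
            else 0.0
        )
        rate = (uptake_per_cycle[k] / eff + bg) / 3600.0  # mg L^-1 s^-1
        o2_cyc[~flush] = close_start - rate * (tc[~flush] - plan.flush_duration)
        if o2_cyc[~flush].size and o2_cyc[~flush].min() <= 0:
            raise ValueError("hypoxic chamber, shorten closed phase")
        o2[in_cycle] = o2_cyc
        level = close_start - rate * plan.closed_duration
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=o2.size)
    return O2Trace(
        timestamps=times, o2=o2, temperature=25.0, channel_id=chamber.channel_id
    )


def _uptake_profile(
    smr: float, n_cycles: int, effects: EffectConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-cycle uptake: constant baseline plus non-negative activity bursts."""
    bursts = rng.random(n_cycles) < effects.activity_burst_prob
    extra = np.where(
        bursts, rng.exponential(effects.activity_burst_mean * smr, n_cycles), 0.0
    )
    return smr + extra


# ---------------------------------------------------------------------------
# breath events
# ---------------------------------------------------------------------------


def simulate_breath_events(
    n_fish: int,
    duration_s: float,
    rate_per_min: float,
    participation: float,
    rng: np.random.Generator | int | None = None,
    trigger_rate_per_min: float | None = None,
    jitter_s: float = 2.0,
    fish_ids: list | None = None,
    trial_id: str = "",
) -> pd.DataFrame:
    """Common-trigger breath process for one trial.

    Per fish, an independent Poisson stream at rate ``rate_per_min * (1-p)``
    is superposed with group triggers; each fish joins each trigger with
    probability ``p`` and surfaces within ``jitter_s`` of it.  With the
    default calibrated trigger rate (equal to the per-fish base rate) the
    expected per-fish total is ``rate_per_min`` regardless of ``p``.
    """
    if not 0.0 <= participation <= 1.0:
        raise ValueError("participation must be in [0, 1]")
    if rate_per_min < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(rng)
    if fish_ids is None:
        fish_ids = [f"f{i}" for i in range(n_fish)]
    p = participation
    lam_ind = rate_per_min * (1.0 - p) / 60.0  # s^-1 per fish
    lam_trig = (
        (trigger_rate_per_min if trigger_rate_per_min is not None else rate_per_min)
        / 60.0
    )
    rows: list[tuple] = []
    trigger_times = rng.uniform(
        0.0, duration_s, rng.poisson(lam_trig * duration_s)
    ) if p > 0 else np.empty(0)
    for fid in fish_ids:
        n_ind = rng.poisson(lam_ind * duration_s)
        for t in rng.uniform(0.0, duration_s, n_ind):
            rows.append((trial_id, fid, t))
        if p > 0 and trigger_times.size:
            joins = rng.random(trigger_times.size) < p
            for t in trigger_times[joins] + rng.uniform(
                0.0, jitter_s, int(joins.sum())
            ):
                if t <= duration_s:
                    rows.append((trial_id, fid, float(t)))
    df = pd.DataFrame(rows, columns=["trial_id", "fish_id", "time_s"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectories(
    n_fish: int,
    n_frames: int,
    arena_radius: float,
    step_length: float,
    kappa: float = 0.0,
    persistence: float = 0.5,
    heading_noise: float = 1.0,
    rng: np.random.Generator | int | None = None,
    fish_ids: list | None = None,
) -> TrajectorySet:
    """Persistent random walk with centroid attraction in a circular arena.

    Per frame each fish takes a step of length ``step_length`` along the
    normalised blend of its previous heading (weight ``persistence``),
    isotropic Gaussian noise, and an attraction component of weight ``kappa``
    pointing at the current group centroid; positions leaving the arena are
    reflected radially inside the wall.  Attraction steers the heading rather
    than adding displacement, so the step length — and hence the measured
    speed — is exact by construction at every ``kappa``, and the stationary
    group spread shrinks monotonically as ``kappa`` grows.
    """
    if step_length <= 0 or kappa < 0:
        raise ValueError("step_length must be > 0 and kappa >= 0")
    rng = np.random.default_rng(rng)
    if fish_ids is None:
        fish_ids = [f"f{i}" for i in range(n_fish)]
    # uniform start positions in the disc
    r = arena_radius * np.sqrt(rng.random(n_fish))
    phi = rng.uniform(0, 2 * np.pi, n_fish)
    pos = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
    heading = rng.normal(size=(n_fish, 2))
    heading /= np.linalg.norm(heading, axis=1, keepdims=True)
    out = np.empty((n_frames, n_fish, 2))
    out[0] = pos
    for i in range(1, n_frames):
        v = persistence * heading + heading_noise * rng.normal(size=(n_fish, 2))
        if kappa > 0 and n_fish > 1:
            to_c = pos.mean(axis=0) - pos
            d = np.linalg.norm(to_c, axis=1, keepdims=True)
            d[d == 0] = 1.0
            v = v + kappa * to_c / d
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        step = step_length * v / norm
        pos = pos + step
        rad = np.linalg.norm(pos, axis=1)
        outside = rad > arena_radius
        if outside.any():
            pos[outside] *= ((2 * arena_radius - rad[outside]) / rad[outside])[:, None]
        sl = np.linalg.norm(step, axis=1, keepdims=True)
        sl[sl == 0] = 1.0
        heading = step / sl
        out[i] = pos
    return TrajectorySet(
        positions=out, fish_ids=list(fish_ids), frames=np.arange(n_frames)
    )


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------


def _fish_table(
    design: StudyDesign, effects: EffectConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-fish truth: group membership, mass, true SMR at each temperature."""
    sigma = np.sqrt(np.log1p(effects.mass_cv**2))
    mu = np.log(effects.mass_mean) - 0.5 * sigma**2
    rows = []
    for g in range(design.n_groups):
        for j in range(design.group_size):
            fid = f"g{g + 1}f{j + 1}"
            mass = float(rng.lognormal(mu, sigma))
            for temp in design.temperatures:
                smr_true = (
                    effects.smr_baseline
                    * mass**effects.mass_exponent
                    * (effects.temp_factor if temp == max(design.temperatures) else 1.0)
                    * float(np.exp(rng.normal(0.0, effects.smr_noise_sd)))
                )
                rows.append((f"g{g + 1}", fid, mass, temp, smr_true))
    return pd.DataFrame(
        rows, columns=["group", "fish_id", "mass", "temp", "smr_true"]
    )


def simulate_tidy_dataset(
    design: StudyDesign,
    effects: EffectConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Statistical-level study emulation: the tidy tables the models consume.

    Breath counts come from the common-trigger event simulator (so dispersion
    behaves like the signal-level data); SMR, speed and cohesion are drawn
    from their generating distributions directly, skipping signal synthesis.
    Returns ``(per_fish, per_trial, truth)``; ``truth`` records every
    generating parameter.
    """
    rng = np.random.default_rng(rng)
    fish = _fish_table(design, effects, rng)
    t_hot = max(design.temperatures)
    per_fish_rows, per_trial_rows = [], []
    from .synchrony import trial_summary

    group_speed_re = {
        f"g{g + 1}": rng.normal(0.0, 0.3) for g in range(design.n_groups)
    }
    group_coh_re = {
        f"g{g + 1}": rng.normal(0.0, 2.0) for g in range(design.n_groups)
    }
    for g in range(design.n_groups):
        grp = f"g{g + 1}"
        members = fish[fish.group == grp]
        for temp in design.temperatures:
            for o2 in design.o2_levels:
                trial_id = f"{grp}_t{temp}_o{o2}"
                rate = (
                    effects.breath_rate_base
                    * effects.o2_rate_multipliers[o2]
                    * (effects.temp_rate_multiplier if temp == t_hot else 1.0)
                )
                roster = members[members.temp == temp].fish_id.tolist()
                events = simulate_breath_events(
                    n_fish=design.group_size,
                    duration_s=design.trial_duration,
                    rate_per_min=rate,
                    participation=effects.synchrony_participation,
                    rng=rng,
                    jitter_s=effects.trigger_jitter,
                    fish_ids=roster,
                    trial_id=trial_id,
                )
                summ = trial_summary(events, design.trial_duration, roster=roster)
                speed = float(
                    effects.speed_scale * design.frame_rate
                    + group_speed_re[grp]
                    + rng.normal(0.0, 0.2)
                )
                coh = float(
                    0.55 * design.arena_radius
                    / (1.0 + effects.cohesion_attraction)
                    + group_coh_re[grp]
                    + rng.normal(0.0, 1.0)
                )
                per_trial_rows.append(
                    (grp, temp, o2, trial_id, summ["abf_group"], summ["cd"],
                     max(speed, 0.1), max(coh, 0.5))
                )
                counts = events.groupby("fish_id").size().reindex(roster, fill_value=0)
                for fid, abf in counts.items():
                    row = members[(members.fish_id == fid) & (members.temp == temp)]
                    per_fish_rows.append(
                        (grp, fid, float(row.mass.iloc[0]), temp, o2,
                         float(row.smr_true.iloc[0]), int(abf), trial_id)
                    )
    per_trial = pd.DataFrame(
        per_trial_rows,
        columns=["group", "temp", "o2", "trial_id", "abf_group", "cd", "speed",
                 "cohesion"],
    )
    per_fish = pd.DataFrame(
        per_fish_rows,
        columns=["group", "fish_id", "mass", "temp", "o2", "smr", "abf", "trial_id"],
    )
    # per-fish rows carry the trial-level covariates for the individual model
    per_fish = per_fish.merge(
        per_trial[["trial_id", "speed", "cohesion"]], on="trial_id", how="left"
    )
    truth = pd.DataFrame(
        [{"parameter": k, "value": v}
         for k, v in asdict(effects).items() if not isinstance(v, dict)]
        + [{"parameter": f"o2_rate_multiplier_{k}", "value": v}
           for k, v in effects.o2_rate_multipliers.items()]
    )
    return per_fish, per_trial, truth


def simulate_study(
    design: StudyDesign,
    effects: EffectConfig,
    seed: int | None = None,
    n_frames: int | None = None,
) -> dict:
    """Full signal-level study: every raw stream plus tidy truth tables.

    Returns a dict of DataFrames ready to be written as the CSVs the analysis
    CLI reads: ``traces`` (long O2 series), ``blanks`` (background slopes),
    ``chambers``, ``events``, ``roster``, ``trajectories``, plus
    ``per_fish`` / ``per_trial`` / ``truth`` from the statistical layer.
    Identical seeds give bit-identical outputs.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    per_fish, per_trial, truth = simulate_tidy_dataset(design, effects, rng)
    plan = CyclePlan(total_duration=design.respirometry_duration_h * 3600.0)
    n_cycles = int(design.respirometry_duration_h * 3600.0 / plan.period)
    trace_rows, chamber_rows, blank_rows = [], [], []
    fish_meta = per_fish[["group", "fish_id", "mass", "temp", "smr"]].drop_duplicates(
        ["fish_id", "temp"]
    )
    for _, row in fish_meta.iterrows():
        channel = f"{row.fish_id}_t{int(row.temp)}"
        chamber = ChamberConfig(
            chamber_volume=75.0, tubing_volume=5.0, fish_mass=row.mass,
            channel_id=channel,
        )
        bg = BackgroundModel(
            effects.background_pre, effects.background_post,
            0.0, n_cycles * plan.period, channel_id=channel,
        )
        profile = _uptake_profile(row.smr, n_cycles, effects, rng)
        trace = simulate_o2_trace(
            chamber, plan, profile, background=bg,
            noise_sd=effects.trace_noise_sd, saturation=effects.o2_saturation,
            rng=rng,
        )
        trace_rows.append(
            pd.DataFrame(
                {
                    "time_s": trace.timestamps,
                    "channel": channel,
                    "o2_mg_l": trace.o2,
                    "temp_c": row.temp,
                }
            )
        )
        chamber_rows.append(
            (channel, row.fish_id, row.group, row.temp, 75.0, 5.0, row.mass)
        )
        blank_rows.append(
            (channel, effects.background_pre, effects.background_post,
             0.0, n_cycles * plan.period)
        )
    events_all, roster_rows, traj_rows = [], [], []
    frames = (
        n_frames
        if n_frames is not None
        else int(design.trial_duration * design.frame_rate)
    )
    from .kinematics import ArenaConfig, cohesion as _cohesion, mean_speed as _speed
    from .synchrony import trial_summary as _summary

    arena = ArenaConfig(area=design.arena_area, frame_rate=design.frame_rate)
    per_fish = per_fish.set_index(["trial_id", "fish_id"])
    for idx, trial in per_trial.iterrows():
        roster = per_fish.loc[trial.trial_id].index.tolist()
        for fid in roster:
            roster_rows.append((trial.trial_id, fid))
        rate = (
            effects.breath_rate_base
            * effects.o2_rate_multipliers[trial.o2]
            * (effects.temp_rate_multiplier
               if trial.temp == max(design.temperatures) else 1.0)
        )
        ev = simulate_breath_events(
            design.group_size, design.trial_duration, rate,
            effects.synchrony_participation, rng=rng,
            jitter_s=effects.trigger_jitter, fish_ids=roster,
            trial_id=trial.trial_id,
        )
        ev.insert(1, "group", trial.group)
        ev.insert(2, "temp_c", trial.temp)
        ev.insert(3, "o2_pct", trial.o2)
        events_all.append(ev)
        # per-trial true locomotion parameters: the trial's statistical-level
        # speed draw sets the step length, and the attraction strength varies
        # log-normally around its base value so cohesion differs among trials
        step_trial = max(float(trial.speed), 0.5) / design.frame_rate
        kappa_trial = effects.cohesion_attraction * float(
            np.exp(rng.normal(0.0, 0.4))
        )
        traj = simulate_trajectories(
            design.group_size, frames, design.arena_radius,
            step_trial, kappa_trial,
            effects.heading_persistence, effects.heading_noise,
            rng=rng, fish_ids=roster,
        )
        tdf = traj.to_dataframe()
        tdf.insert(0, "trial_id", trial.trial_id)
        traj_rows.append(tdf)
        # keep the tidy tables consistent with the emitted streams: overwrite
        # the statistical-level draws with values recomputed from the streams
        summ = _summary(ev, design.trial_duration)
        per_trial.loc[idx, ["abf_group", "cd"]] = [summ["abf_group"], summ["cd"]]
        per_trial.loc[idx, "speed"] = _speed(traj, arena).mean_speed
        per_trial.loc[idx, "cohesion"] = _cohesion(traj).cohesion
        counts = ev.groupby("fish_id").size().reindex(roster, fill_value=0)
        per_fish.loc[
            [(trial.trial_id, fid) for fid in roster], "abf"
        ] = counts.to_numpy()
    per_fish = per_fish.reset_index()
    per_fish = per_fish.drop(columns=["speed", "cohesion"]).merge(
        per_trial[["trial_id", "speed", "cohesion"]], on="trial_id", how="left"
    )
    return {
        "traces": pd.concat(trace_rows, ignore_index=True),
        "chambers": pd.DataFrame(
            chamber_rows,
            columns=["channel", "fish_id", "group", "temp_c", "chamber_volume_ml",
                     "tubing_volume_ml", "fish_mass_g"],
        ),
        "blanks": pd.DataFrame(
            blank_rows,
            columns=["channel", "pre_slope_mg_l_h", "post_slope_mg_l_h",
                     "trial_start_s", "trial_end_s"],
        ),
        "events": pd.concat(events_all, ignore_index=True),
        "roster": pd.DataFrame(roster_rows, columns=["trial_id", "fish_id"]),
        "trajectories": pd.concat(traj_rows, ignore_index=True),
        "per_fish": per_fish,
        "per_trial": per_trial,
        "truth": truth,
    }
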