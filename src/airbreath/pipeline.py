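"""End-to-end orchestration: raw CSVs in, per-stage tables and model fits out.

Stages run in a fixed order — respirometry -> synchrony -> kinematics ->
join -> inference -> report — each consuming documented CSV schemas and
emitting tidy CSVs, so any stage can also be run (or re-run) in isolation
through the CLI.  A machine-readable manifest records inputs (with
checksums), every effective parameter, package version and seed: the
manifest alone suffices to reproduce a run.

CSV schemas
-----------
traces:        time_s,channel,o2_mg_l,temp_c   (or o2_sat_pct with a solubility)
blanks:        channel,pre_slope_mg_l_h,post_slope_mg_l_h,trial_start_s,trial_end_s
chambers:      channel,fish_id,group,temp_c,chamber_volume_ml,tubing_volume_ml,fish_mass_g
events:        trial_id,group,temp_c,o2_pct,fish_id,time_s
roster:        trial_id,fish_id
trajectories:  trial_id,frame,fish_id,x,y      (pixels or cm; empty = missing)

Lines starting with ``#`` are treated as comments in all inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import MODEL_BATTERY, ModelSpec, nakagawa_r2, select_model
from .kinematics import ArenaConfig, TrajectorySet, calibrate, cohesion, mean_speed
from .respirometry import (
    BackgroundModel,
    ChamberConfig,
    CyclePlan,
    O2Trace,
    convert_saturation,
    estimate_smr,
    mo2_series_from_trace,
)
from .synchrony import abf_individual, trial_summary

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_all",
    "join_tables",
    "read_traces",
    "read_blanks",
    "read_chambers",
    "smr_stage",
    "synchrony_stage",
    "kinematics_stage",
]

_CSV_KW = dict(comment="#")
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML with CLI overrides."""

    out_dir: str
    traces: str | None = None
    blanks: str | None = None
    chambers: str | None = None
    events: str | None = None
    roster: str | None = None
    trajectories: str | None = None
    plan: dict = field(default_factory=dict)  # CyclePlan overrides
    bin_width: float = 5.0
    trial_duration: float = 720.0
    frame_rate: float = 25.0
    px_per_cm: float = 1.0
    solubility: float | None = None  # required if traces use o2_sat_pct
    smr_quantile: float = 0.2
    smr_method: str = "quantile"
    models: list = field(default_factory=lambda: list(MODEL_BATTERY))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_traces(
    path: str | Path, solubility: float | None = None
) -> dict[str, O2Trace]:
    """Long-format trace CSV -> one O2Trace per channel.

    Accepts either an ``o2_mg_l`` column or ``o2_sat_pct`` plus a solubility
    (mg O2 L^-1 at 100% air saturation).
    """
    df = pd.read_csv(path, **_CSV_KW)
    if "o2_mg_l" not in df.columns:
        if "o2_sat_pct" not in df.columns:
            raise ValueError("traces need o2_mg_l or o2_sat_pct")
        if solubility is None:
            raise ValueError("o2_sat_pct traces require a solubility")
        df["o2_mg_l"] = convert_saturation(df["o2_sat_pct"].to_numpy(), solubility)
    out = {}
    for channel, grp in df.groupby("channel", sort=True):
        grp = grp.sort_values("time_s")
        out[str(channel)] = O2Trace(
            timestamps=grp["time_s"].to_numpy(),
            o2=grp["o2_mg_l"].to_numpy(),
            temperature=float(grp["temp_c"].iloc[0]) if "temp_c" in grp else 25.0,
            channel_id=str(channel),
        )
    return out


def read_blanks(path: str | Path) -> dict[str, BackgroundModel]:
    df = pd.read_csv(path, **_CSV_KW)
    out = {}
    for _, r in df.iterrows():
        pre = r.get("pre_slope_mg_l_h")
        post = r.get("post_slope_mg_l_h")
        if pd.isna(pre) and pd.isna(post):
            raise ValueError(f"channel {r['channel']}: no blank slopes")
        if pd.isna(pre) or pd.isna(post):
            out[str(r["channel"])] = BackgroundModel.constant(
                float(post if pd.isna(pre) else pre),
                float(r["trial_start_s"]),
                float(r["trial_end_s"]),
                str(r["channel"]),
            )
        else:
            out[str(r["channel"])] = BackgroundModel(
                float(pre), float(post),
                float(r["trial_start_s"]), float(r["trial_end_s"]),
                str(r["channel"]),
            )
    return out


def read_chambers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, **_CSV_KW)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def smr_stage(
    traces: dict[str, O2Trace],
    blanks: dict[str, BackgroundModel],
    chambers: pd.DataFrame,
    plan: CyclePlan,
    quantile: float = 0.2,
    method: str = "quantile",
    r2_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-fish SMR table from raw traces."""
    rows = []
    meta = chambers.set_index("channel")
    for channel, trace in traces.items():
        if channel not in meta.index:
            raise ValueError(f"channel {channel!r} missing from chambers table")
        m = meta.loc[channel]
        chamber = ChamberConfig(
            chamber_volume=float(m["chamber_volume_ml"]),
            tubing_volume=float(m["tubing_volume_ml"]),
            fish_mass=float(m["fish_mass_g"]),
            channel_id=channel,
        )
        series = mo2_series_from_trace(
            trace, plan, chamber, background=blanks.get(channel),
            fish_id=str(m["fish_id"]), r2_threshold=r2_threshold,
        )
        est = estimate_smr(series, quantile=quantile, method=method)
        rows.append(
            (str(m["fish_id"]), str(m["group"]), float(m["temp_c"]),
             est.smr, est.n_cycles, est.mean_background_fraction, est.method)
        )
    return pd.DataFrame(
        rows,
        columns=["fish_id", "group", "temp_c", "smr_mgO2_h", "n_cycles",
                 "mean_bg_pct", "method"],
    ).sort_values(["fish_id", "temp_c"]).reset_index(drop=True)


def synchrony_stage(
    events: pd.DataFrame,
    roster: pd.DataFrame | None,
    duration: float,
    width: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial (ABF, CD) and per-fish (ABF) tables from the event log."""
    trial_rows, fish_rows = [], []
    meta_cols = [c for c in ("group", "temp_c", "o2_pct") if c in events.columns]
    trial_ids = (
        roster["trial_id"].unique()
        if roster is not None
        else events["trial_id"].unique()
    )
    for trial_id in sorted(map(str, trial_ids)):
        ev = events[events["trial_id"].astype(str) == trial_id]
        fish = (
            roster[roster["trial_id"].astype(str) == trial_id]["fish_id"].tolist()
            if roster is not None
            else sorted(ev["fish_id"].unique())
        )
        meta = {c: ev[c].iloc[0] if len(ev) else np.nan for c in meta_cols}
        summ = trial_summary(ev, duration, width, roster=fish)
        trial_rows.append({"trial_id": trial_id, **meta, **summ})
        for fid, abf in abf_individual(ev, roster=fish).items():
            fish_rows.append({"trial_id": trial_id, **meta, "fish_id": fid, "abf": abf})
    return pd.DataFrame(trial_rows), pd.DataFrame(fish_rows)


def kinematics_stage(
    traj_df: pd.DataFrame,
    frame_rate: float,
    px_per_cm: float = 1.0,
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Per-trial activity and cohesion from long trajectory tables."""
    from .kinematics import smooth as smooth_fn

    arena = ArenaConfig(frame_rate=frame_rate, px_per_cm=px_per_cm)
    rows = []
    for trial_id, grp in traj_df.groupby("trial_id", sort=True):
        traj = TrajectorySet.from_dataframe(grp)
        if px_per_cm != 1.0:
            traj = calibrate(traj, px_per_cm)
        if smooth_window:
            traj = smooth_fn(traj, smooth_window)
        act = mean_speed(traj, arena)
        coh = cohesion(traj)
        rows.append(
            (str(trial_id), act.mean_speed, coh.cohesion, act.frames_used)
        )
    return pd.DataFrame(
        rows, columns=["trial_id", "mean_speed_cm_s", "cohesion_cm", "frames_used"]
    )


def join_tables(
    per_fish_abf: pd.DataFrame,
    per_trial: pd.DataFrame,
    smr_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the tidy per-fish and per-trial modelling tables.

    Inner joins on trial/fish keys; rows dropped by a join are counted and
    logged.  A fish lacking an SMR estimate is absent from the
    individual-level table but still contributes to the trial totals.
    """
    for name, df, keys in (
        ("per_fish_abf", per_fish_abf, ["trial_id", "fish_id"]),
        ("per_trial", per_trial, ["trial_id"]),
    ):
        dup = df.duplicated(keys)
        if dup.any():
            raise ValueError(
                f"duplicate keys in {name}: {df.loc[dup, keys].to_dict('records')}"
            )
    trial = per_trial.copy()
    fish = per_fish_abf.merge(
        trial.drop(columns=[c for c in ("group", "temp_c", "o2_pct") if c in trial],
                   errors="ignore"),
        on="trial_id", how="inner",
    )
    if smr_table is not None:
        n0 = len(fish)
        fish = fish.merge(
            smr_table[["fish_id", "temp_c", "smr_mgO2_h"]].rename(
                columns={"smr_mgO2_h": "smr"}
            ),
            on=["fish_id", "temp_c"], how="inner",
        )
        dropped = n0 - len(fish)
        if dropped:
            logger.warning("join dropped %d per-fish rows lacking SMR", dropped)
    return fish, trial


def _rename_for_models(fish: pd.DataFrame, trial: pd.DataFrame, chambers=None):
    """Map pipeline column names onto the battery's model variables."""
    t = trial.rename(columns={"temp_c": "temp", "o2_pct": "o2",
                              "mean_speed_cm_s": "speed",
                              "cohesion_cm": "cohesion"})
    f = fish.rename(columns={"temp_c": "temp", "o2_pct": "o2",
                             "mean_speed_cm_s": "speed",
                             "cohesion_cm": "cohesion"})
    if chambers is not None:
        f = f.merge(
            chambers.drop_duplicates("fish_id")[["fish_id", "fish_mass_g"]].rename(
                columns={"fish_mass_g": "mass"}
            ),
            on="fish_id", how="left",
        )
    return f, t


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage the inputs allow; returns the manifest dict.

    Any stage error halts the run: partial outputs are kept and a ``FAILED``
    marker naming the stage and error is written to the output directory.
    """
    import matplotlib

    matplotlib.use("Agg")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "plots").mkdir(exist_ok=True)
    manifest: dict = {
        "package": "airbreath",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "inputs": {},
    }
    for key in ("traces", "blanks", "chambers", "events", "roster", "trajectories"):
        p = getattr(config, key)
        if p is not None:
            if not Path(p).exists():
                raise FileNotFoundError(f"input {key} not found: {p}")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    def _write(df: pd.DataFrame, name: str) -> str:
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        return str(path)

    stage = "respirometry"
    try:
        smr_table = None
        if config.traces and config.blanks and config.chambers:
            plan = CyclePlan(**config.plan)
            smr_table = smr_stage(
                read_traces(config.traces, config.solubility),
                read_blanks(config.blanks),
                read_chambers(config.chambers),
                plan,
                quantile=config.smr_quantile,
                method=config.smr_method,
            )
            manifest["stages"][stage] = {
                "status": "ok", "out": _write(smr_table, "smr.csv"),
                "n_fish_trials": len(smr_table),
            }
        else:
            manifest["stages"][stage] = {"status": "skipped", "reason": "no traces"}

        stage = "synchrony"
        trial_tbl = fish_tbl = None
        if config.events:
            events = pd.read_csv(config.events, **_CSV_KW)
            roster = pd.read_csv(config.roster, **_CSV_KW) if config.roster else None
            trial_tbl, fish_tbl = synchrony_stage(
                events, roster, config.trial_duration, config.bin_width
            )
            manifest["stages"][stage] = {
                "status": "ok",
                "out": [_write(trial_tbl, "trials.csv"),
                        _write(fish_tbl, "abf_individual.csv")],
                "n_trials": len(trial_tbl),
            }
        else:
            manifest["stages"][stage] = {"status": "skipped", "reason": "no events"}

        stage = "kinematics"
        kin_tbl = None
        if config.trajectories:
            kin_tbl = kinematics_stage(
                pd.read_csv(config.trajectories, **_CSV_KW),
                config.frame_rate, config.px_per_cm,
            )
            manifest["stages"][stage] = {
                "status": "ok", "out": _write(kin_tbl, "kinematics.csv"),
                "n_trials": len(kin_tbl),
            }
        else:
            manifest["stages"][stage] = {
                "status": "skipped",
                "reason": "no trajectory file; kinematics and activity/cohesion "
                          "models will be skipped",
            }

        stage = "join"
        fish_data = trial_data = None
        if trial_tbl is not None:
            if kin_tbl is not None:
                trial_tbl = trial_tbl.merge(kin_tbl, on="trial_id", how="left")
            fish_data, trial_data = join_tables(fish_tbl, trial_tbl, smr_table)
            chambers = (
                read_chambers(config.chambers) if config.chambers else None
            )
            fish_data, trial_data = _rename_for_models(fish_data, trial_data, chambers)
            manifest["stages"][stage] = {
                "status": "ok",
                "out": [_write(fish_data, "dataset_fish.csv"),
                        _write(trial_data, "dataset_trial.csv")],
            }
        else:
            manifest["stages"][stage] = {"status": "skipped", "reason": "no events"}

        stage = "inference"
        if trial_data is not None:
            fits, traces_log = _run_models(config, fish_data, trial_data, kin_tbl)
            for name, (fit, r2) in fits.items():
                frame = fit.summary_frame().reset_index(names="term")
                frame["r2_marginal"] = r2.r2_marginal
                frame["r2_conditional"] = r2.r2_conditional
                _write(frame, f"model_{name}.csv")
                _plot_diagnostics(fit, out / "plots" / f"{name}_residuals.png")
            _write(pd.DataFrame(traces_log), "selection_trace.csv")
            manifest["stages"][stage] = {
                "status": "ok",
                "models": {k: v[0].spec.formula for k, v in fits.items()},
            }
        else:
            manifest["stages"][stage] = {"status": "skipped", "reason": "no dataset"}

        stage = "report"
        manifest["stages"][stage] = {"status": "ok"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return manifest


def _run_models(config, fish_data, trial_data, kin_tbl):
    fits, trace_log = {}, []
    have_kin = kin_tbl is not None and "speed" in trial_data.columns
    for name in config.models:
        spec = MODEL_BATTERY[name]
        if name in ("activity", "cohesion") and not have_kin:
            logger.warning("model %r skipped: no kinematics", name)
            continue
        if name == "smr" and "smr" not in fish_data.columns:
            logger.warning("model %r skipped: no SMR table", name)
            continue
        if name in ("group_abf", "cd") and not have_kin:
            spec = spec.with_formula(
                spec.formula.replace(" + speed", "").replace(" + cohesion", "")
            )
            logger.warning("model %r: speed/cohesion dropped (no kinematics)", name)
        if name == "smr":
            # one row per fish per acclimation temperature
            data = fish_data.drop_duplicates(["fish_id", "temp"])
        elif name == "indiv_abf":
            data = fish_data
        else:
            data = trial_data
        if name == "cd":
            data = data.dropna(subset=["cd"])
        try:
            fit, trace = select_model(spec, data)
        except Exception as exc:
            logger.warning("model %r failed: %s", name, exc)
            continue
        for t in trace:
            trace_log.append({"model": name, **t})
        fits[name] = (fit, nakagawa_r2(fit))
    return fits, trace_log


def _plot_diagnostics(fit, path: Path) -> None:
    """Fitted-vs-residual and normal QQ panels (Gaussian models only)."""
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    if fit.spec.family != "gaussian":
        resid = None
        try:
            resid = fit.raw.model.endog - fit.raw.fittedvalues
            fitted = fit.raw.fittedvalues
        except AttributeError:
            return
    else:
        fitted = fit.raw.fittedvalues
        resid = fit.raw.resid
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].scatter(fitted, resid, s=12)
    axes[0].axhline(0.0, color="grey", lw=0.8)
    axes[0].set_xlabel("fitted")
    axes[0].set_ylabel("residual")
    sps.probplot(np.asarray(resid), plot=axes[1])
    axes[1].set_title("")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
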