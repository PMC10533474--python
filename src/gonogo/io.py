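"""File formats, run configuration, and the end-to-end pipeline.

Canonical on-disk formats are plain CSV (comma, UTF-8, '.' decimal,
header row), one concern per file:

* ``trials.csv``      session_id, trial_index, stimulus, laser, block_index, onset_s
* ``licks.csv``       session_id, lick_time_s            (session clock)
* ``spikes.csv``      unit_id, spike_time_s
* ``waveforms.csv``   unit_id, sample_index, spont_amp, laser_amp
* ``laser.csv``       onset_s, duration_s
* ``photometry.csv``  time_s, fluorescence

The pipeline (:func:`run_pipeline`) chains simulate -> behavior ->
spiking -> choice -> photometry -> motion as configured, writing tidy
result tables, a machine-readable ``summary.json``, and an exclusion
log.  Identical config and seeds produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, choice, motion, photometry, spiking, synth
from .core import (
    Laser,
    PhotometryTrace,
    Session,
    SpikeUnit,
    Stimulus,
    TaskTiming,
    Trial,
)

__all__ = [
    "RunConfig",
    "load_config",
    "read_session",
    "write_session",
    "read_spikes",
    "write_spikes",
    "read_waveforms",
    "write_waveforms",
    "read_laser",
    "write_laser",
    "read_photometry",
    "write_photometry",
    "run_pipeline",
]

log = logging.getLogger("gonogo")

_STAGES = ("simulate", "behavior", "spiking", "choice", "cohort",
           "tagging", "photometry", "motion")


# ---------------------------------------------------------------- config

_CONFIG_KEYS = {
    "seed", "out_dir", "timing", "session", "cohort", "tagging_criteria",
    "choice", "stages",
}


@dataclass
class RunConfig:
    """Structured pipeline configuration.

    ``session`` holds SimConfig overrides for the single detailed
    session; ``cohort`` (optional) holds ``cr_levels``,
    ``units_per_level`` and ``slope`` for the correlation analysis;
    ``stages`` selects which stages run (default: all configured).
    Every stochastic operation derives its seed from ``seed``.
    """

    seed: int
    out_dir: str = "results"
    timing: dict = field(default_factory=dict)
    session: dict = field(default_factory=dict)
    cohort: dict | None = None
    tagging_criteria: dict = field(default_factory=dict)
    choice: dict = field(default_factory=dict)
    stages: list[str] | None = None

    def __post_init__(self) -> None:
        if self.stages is not None:
            bad = set(self.stages) - set(_STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")

    def task_timing(self) -> TaskTiming:
        return TaskTiming(**self.timing)

    def sim_config(self) -> synth.SimConfig:
        params = dict(self.session)
        params.setdefault("n_trials", 240)
        params.setdefault("seed", self.seed)
        return synth.SimConfig(**params)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    return RunConfig(**raw)


# ---------------------------------------------------------------- session IO

def write_session(session: Session, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = pd.DataFrame(
        {
            "session_id": session.session_id,
            "trial_index": [t.index for t in session.trials],
            "stimulus": [t.stimulus.value for t in session.trials],
            "laser": [t.laser.value for t in session.trials],
            "block_index": [t.block_index for t in session.trials],
            "onset_s": [repr(float(t.onset)) for t in session.trials],
        }
    )
    licks = []
    for t in session.trials:
        for lt in t.lick_times:
            licks.append((session.session_id, repr(float(t.onset + lt))))
    trials_path = out / "trials.csv"
    licks_path = out / "licks.csv"
    trials.to_csv(trials_path, index=False)
    pd.DataFrame(licks, columns=["session_id", "lick_time_s"]).to_csv(
        licks_path, index=False
    )
    return {"trials": trials_path, "licks": licks_path}


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_session(
    trials_path: str | Path,
    licks_path: str | Path | None = None,
    timing: TaskTiming | None = None,
    session_id: str | None = None,
    mouse_id: str = "",
) -> Session:
    """Rebuild a Session from trials.csv (+ licks.csv).

    Trial rows are sorted by onset on read (with a warning if they were
    shuffled); strictly increasing onsets are then enforced.  Licks are
    assigned to the trial whose onset interval contains them and stored
    trial-relative.
    """
    trials_path = Path(trials_path)
    df = pd.read_csv(trials_path, float_precision="round_trip")
    _require_columns(
        df, ["session_id", "trial_index", "stimulus", "laser",
             "block_index", "onset_s"], trials_path,
    )
    if df.empty:
        raise ValueError(f"{trials_path}: no trial rows")
    if session_id is None:
        session_id = str(df["session_id"].iloc[0])
    if not df["onset_s"].is_monotonic_increasing:
        log.warning("%s: trial rows not sorted by onset; sorting", trials_path)
        df = df.sort_values("onset_s").reset_index(drop=True)
    onsets = df["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{trials_path}: non-monotone trial onsets")

    lick_abs = np.empty(0)
    if licks_path is not None:
        ldf = pd.read_csv(licks_path, float_precision="round_trip")
        _require_columns(ldf, ["session_id", "lick_time_s"], Path(licks_path))
        lick_abs = np.sort(ldf["lick_time_s"].to_numpy(dtype=float))

    trials = []
    for pos, row in enumerate(df.itertuples(index=False)):
        t0 = onsets[pos]
        t1 = onsets[pos + 1] if pos + 1 < len(onsets) else np.inf
        mine = lick_abs[(lick_abs >= t0) & (lick_abs < t1)]
        trials.append(
            Trial(
                index=int(row.trial_index),
                stimulus=Stimulus(row.stimulus),
                laser=Laser(row.laser),
                block_index=int(row.block_index),
                onset=float(t0),
                lick_times=mine - t0,
            )
        )
    return Session(
        session_id=session_id,
        mouse_id=mouse_id,
        timing=timing or TaskTiming(),
        trials=trials,
    )


# ------------------------------------------------------------- other files

def write_spikes(unit: SpikeUnit, path: str | Path) -> None:
    pd.DataFrame(
        {"unit_id": unit.unit_id,
         "spike_time_s": [repr(float(t)) for t in unit.spike_times]}
    ).to_csv(path, index=False)


def read_spikes(path: str | Path, unit_id: str | None = None) -> SpikeUnit:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["unit_id", "spike_time_s"], Path(path))
    if unit_id is not None:
        df = df[df["unit_id"] == unit_id]
    uid = unit_id or (str(df["unit_id"].iloc[0]) if len(df) else "unit")
    return SpikeUnit(
        unit_id=uid,
        spike_times=np.sort(df["spike_time_s"].to_numpy(dtype=float)),
    )


def write_waveforms(unit: SpikeUnit, path: str | Path) -> None:
    spont = unit.mean_waveform_spont
    laser = unit.mean_waveform_laser
    n = len(spont) if spont is not None else 0
    pd.DataFrame(
        {
            "unit_id": unit.unit_id,
            "sample_index": np.arange(n),
            "spont_amp": spont if spont is not None else [],
            "laser_amp": laser if laser is not None else [np.nan] * n,
        }
    ).to_csv(path, index=False)


def read_waveforms(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path, float_precision="round_trip").sort_values("sample_index")
    _require_columns(df, ["unit_id", "sample_index", "spont_amp", "laser_amp"],
                     Path(path))
    spont = df["spont_amp"].to_numpy(dtype=float)
    laser = df["laser_amp"].to_numpy(dtype=float)
    if np.all(np.isnan(laser)):
        return spont, None
    return spont, laser


def write_laser(onsets: np.ndarray, path: str | Path, duration: float = 0.1) -> None:
    pd.DataFrame(
        {"onset_s": [repr(float(t)) for t in onsets], "duration_s": duration}
    ).to_csv(path, index=False)


def read_laser(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["onset_s", "duration_s"], Path(path))
    return df["onset_s"].to_numpy(dtype=float)


def write_photometry(trace: PhotometryTrace, path: str | Path) -> None:
    t = trace.time_axis()
    pd.DataFrame(
        {"time_s": [repr(float(v)) for v in t],
         "fluorescence": [repr(float(v)) for v in trace.values]}
    ).to_csv(path, index=False)


def read_photometry(path: str | Path) -> PhotometryTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "fluorescence"], Path(path))
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        raise ValueError(f"{path}: non-uniform sampling")
    return PhotometryTrace(
        t0=float(t[0]), rate=1.0 / float(dt[0]),
        values=df["fluorescence"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------- pipeline

def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the configured analysis stages and write the report bundle.

    Returns the summary dictionary that is also written to
    ``summary.json``.  Any stage failure aborts with a stage-tagged
    error; excluded sessions/units are recorded (once each) under
    ``exclusions`` with a machine-readable reason.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or config.stages or list(_STAGES)
    timing = config.task_timing()
    sim = config.sim_config()
    min_fa = int(config.choice.get("min_fa", 10))
    window = config.choice.get("window", choice.WINDOW_FULL)

    summary: dict = {"seed": int(config.seed), "stages": stages,
                     "exclusions": []}
    t_start = time.perf_counter()

    session: Session | None = None
    unit: SpikeUnit | None = None

    def stage(name: str) -> bool:
        return name in stages

    try:
        if stage("simulate"):
            t0 = time.perf_counter()
            session = synth.generate_session(sim, timing)
            behavior.classify_outcomes(session)
            unit = synth.generate_spikes(session, sim)
            write_session(session, out / "session")
            write_spikes(unit, out / "session" / "spikes.csv")
            log.info("simulate: %d trials in %.2fs", session.n_trials,
                     time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if stage("behavior"):
        if session is None:
            raise RuntimeError("stage 'behavior' failed: no session available")
        try:
            rows = []
            for label, pred in (
                ("ALL", None),
                ("LASER_OFF", lambda t: t.laser is Laser.OFF),
                ("LASER_ON", lambda t: t.laser is Laser.ON),
            ):
                s = behavior.compute_rates(session, pred, subset_label=label)
                rows.append(dataclasses.asdict(s))
            pd.DataFrame(rows).to_csv(out / "behavior.csv", index=False)
            delta = behavior.delta_metrics(session)
            lat = behavior.lick_latency(session)
            summary["behavior"] = {
                "hit_rate": rows[0]["hit_rate"],
                "fa_rate": rows[0]["fa_rate"],
                "dprime": rows[0]["dprime"],
                "d_hit": delta.d_hit,
                "d_fa": delta.d_fa,
                "d_dprime": delta.d_dprime,
                "median_lick_latency": lat.median_latency,
                "no_lick_waiting_fraction":
                    behavior.no_lick_waiting_fraction(session),
            }
            log.info("behavior: d_fa=%.3f", delta.d_fa)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'behavior' failed: {exc}") from exc

    if stage("spiking") and session is not None and unit is not None:
        try:
            p_resp, responsive = spiking.responsiveness_test(unit, session)
            rc = spiking.rate_change_test(unit, session)
            pd.DataFrame(
                [{"unit_id": unit.unit_id, "p_responsive": p_resp,
                  "responsive": responsive, "p_cr": rc.p_cr, "p_fa": rc.p_fa,
                  "p_hit": rc.p_hit, "rate_change_significant": rc.significant}]
            ).to_csv(out / "responsiveness.csv", index=False)
            summary["spiking"] = {"p_responsive": p_resp,
                                  "responsive": responsive,
                                  "rate_change_significant": rc.significant}
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'spiking' failed: {exc}") from exc

    if stage("choice") and session is not None and unit is not None:
        try:
            values = choice.spike_window_values(unit, session, window)
            try:
                res = choice.unit_choice_result(values, session, window,
                                                min_fa=min_fa)
                pd.DataFrame([dataclasses.asdict(res)]).to_csv(
                    out / "choice_units.csv", index=False)
                summary["choice"] = dataclasses.asdict(res)
            except choice.SessionIneligibleError as exc:
                summary["exclusions"].append(
                    {"stage": "choice", "id": session.session_id,
                     "reason": "too_few_eligible_fa_trials",
                     "n_eligible_fa": exc.eligibility.n_eligible_fa})
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'choice' failed: {exc}") from exc

    if stage("cohort") and config.cohort is not None:
        try:
            c = config.cohort
            spec = synth.make_cohort_spec(
                cr_levels=list(c.get("cr_levels", [0.25, 0.35, 0.45, 0.55, 0.65])),
                units_per_level=int(c.get("units_per_level", 15)),
                slope=float(c.get("slope", 1.0)),
                base=sim,
                seed=int(config.seed) + 1,
            )
            triples = synth.generate_cohort(spec, timing)
            results = []
            for s, u, _ in triples:
                cr = behavior.compute_rates(s).cr_rate
                vals = choice.spike_window_values(u, s, window)
                try:
                    res = choice.unit_choice_result(vals, s, window,
                                                    min_fa=min_fa)
                    results.append((res, cr))
                except choice.SessionIneligibleError as exc:
                    summary["exclusions"].append(
                        {"stage": "cohort", "id": s.session_id,
                         "reason": "too_few_eligible_fa_trials",
                         "n_eligible_fa": exc.eligibility.n_eligible_fa})
            corr = choice.binned_correlation(results)
            pd.DataFrame(
                {"bin_center_pct": corr.bin_centers,
                 "mean_choice_pref": corr.bin_means,
                 "n_units": corr.bin_ns}
            ).to_csv(out / "choice_bins.csv", index=False)
            summary["cohort"] = {"r": corr.r, "p_value": corr.p_value,
                                 "n_units": int(sum(corr.bin_ns)),
                                 "n_bins": int(corr.bin_ns.size)}
            log.info("cohort: r=%.3f over %d bins", corr.r, corr.bin_ns.size)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    if stage("tagging"):
        try:
            crit = spiking.TaggingCriteria(**config.tagging_criteria)
            rows = []
            for label, tagged in (("tagged", True), ("untagged", False)):
                cfg = dataclasses.replace(sim, seed=int(config.seed) + 2)
                u, onsets = synth.generate_tagging_data(cfg, tagged=tagged)
                res = spiking.optotag_classify(u, onsets, crit)
                rows.append({"condition": label, **dataclasses.asdict(res)})
            pd.DataFrame(rows).to_csv(out / "tagging.csv", index=False)
            summary["tagging"] = {r["condition"]: bool(r["tagged"]) for r in rows}
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'tagging' failed: {exc}") from exc

    if stage("photometry") and session is not None:
        try:
            trace = synth.generate_photometry(session, sim)
            dff = photometry.extract_dff(trace, session)
            lat = photometry.response_latency(
                dff, session, predicate=lambda t: t.stimulus is Stimulus.NOGO)
            vals = photometry.waiting_mean_response(dff)
            phot_choice = None
            try:
                res = choice.unit_choice_result(vals, session, min_fa=min_fa)
                phot_choice = res.choice_pref
            except choice.SessionIneligibleError as exc:
                summary["exclusions"].append(
                    {"stage": "photometry", "id": session.session_id,
                     "reason": "too_few_eligible_fa_trials",
                     "n_eligible_fa": exc.eligibility.n_eligible_fa})
            pd.DataFrame(
                [{"session_id": session.session_id, "latency_s": lat.latency,
                  "threshold": lat.threshold, "choice_pref": phot_choice}]
            ).to_csv(out / "photometry_latency.csv", index=False)
            summary["photometry"] = {
                "latency_s": lat.latency, "choice_pref": phot_choice,
                "n_bad_trials": len(dff.bad_trials)}
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'photometry' failed: {exc}") from exc

    if stage("motion") and session is not None:
        try:
            frames, times = synth.generate_face_video(session, sim)
            energy = motion.motion_energy(frames)
            pcs = motion.motion_pcs(energy, t0=float(times[0]))
            try:
                rocs = motion.motion_choice_roc(pcs, session, min_fa=min_fa)
                pd.DataFrame(
                    [{"pc": i + 1, "choice_pref": r.choice_pref,
                      "roc_area": r.roc_area} for i, r in enumerate(rocs)]
                ).to_csv(out / "motion_choice.csv", index=False)
                summary["motion"] = {
                    "choice_pref_pc1": rocs[0].choice_pref,
                    "explained_variance_pc1": float(pcs.explained_variance[0])}
            except choice.SessionIneligibleError as exc:
                summary["exclusions"].append(
                    {"stage": "motion", "id": session.session_id,
                     "reason": "too_few_eligible_fa_trials",
                     "n_eligible_fa": exc.eligibility.n_eligible_fa})
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'motion' failed: {exc}") from exc

    log.info("pipeline finished in %.2fs", time.perf_counter() - t_start)
    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return summary
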