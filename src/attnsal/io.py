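"""Session bundle format: plain-text CSV/JSON round-trip of simulated sessions.

A bundle directory holds ``session.json`` (paradigm, config echo, format
version), ``trials.csv``, ``events.csv``, ``spikes.csv`` and, for synthetic
sessions, ``ground_truth.json``.  All times are seconds relative to trial
start; CSVs are UTF-8, comma-separated, ``NA`` for nulls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .neurons import Kernel, NeuronRecording, NeuronTuning, SyntheticSession
from .task import LatencySpec, TaskConfig, TaskTrial

FORMAT_VERSION = "1.0"

TRIAL_COLUMNS = ["trial_id", "is_single_stimulus", "cue_side", "trial_type",
                 "left_value", "right_value", "change_side", "change_latency_s",
                 "distractor_latency_s", "outcome", "rt_s", "delivered_reward_level"]
EVENT_NAMES = ["fixation_on", "sacc_target_on", "cue_on", "stim_on", "cue_off",
               "change_on", "distractor_change_on", "response", "trial_end"]
SPIKE_COLUMNS = ["neuron_id", "area", "trial_id", "spike_time_s"]


class BundleError(ValueError):
    """Malformed or inconsistent session bundle."""


def _config_to_json(config: TaskConfig) -> dict:
    d = dataclasses.asdict(config)
    d["reward_volumes_ml"] = {str(k): v for k, v in config.reward_volumes_ml.items()}
    return d


def _config_from_json(d: dict) -> TaskConfig:
    d = dict(d)
    d["reward_volumes_ml"] = {int(k): v for k, v in d["reward_volumes_ml"].items()}
    d["value_levels"] = tuple(d["value_levels"])
    d["response_window"] = tuple(d["response_window"])
    for key in ("latency_d", "latency_g_target", "latency_g_distractor"):
        d[key] = LatencySpec(**d[key])
    return TaskConfig(**d)


def write_bundle(session: SyntheticSession, path, subject_tag: str = "synthetic") -> Path:
    """Write a session to a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "paradigm": session.config.paradigm,
        "subject_tag": subject_tag,
        "n_trials": len(session.trials),
        "n_neurons": len(session.recordings),
        "config": _config_to_json(session.config),
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    trial_rows, event_rows = [], []
    for t in session.trials:
        trial_rows.append({c: getattr(t, c) for c in TRIAL_COLUMNS})
        events = {"fixation_on": 0.0, "sacc_target_on": 0.5, "cue_on": t.t_cue_on,
                  "stim_on": t.t_stim_on, "cue_off": t.t_cue_off, "change_on": t.t_change_on,
                  "distractor_change_on": t.t_distractor_change_on,
                  "response": t.t_response, "trial_end": t.t_end}
        for name, time in events.items():
            if time is not None:
                event_rows.append({"trial_id": t.trial_id, "event": name, "time_s": time})
    pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS).to_csv(
        path / "trials.csv", index=False, na_rep="NA", float_format="%.17g")
    pd.DataFrame(event_rows, columns=["trial_id", "event", "time_s"]).to_csv(
        path / "events.csv", index=False, na_rep="NA", float_format="%.17g")

    spike_rows = []
    for rec in session.recordings:
        for trial_id in sorted(rec.spikes):
            for s in rec.spikes[trial_id]:
                spike_rows.append((rec.neuron_id, rec.area, trial_id, s))
    pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS).to_csv(
        path / "spikes.csv", index=False, na_rep="NA", float_format="%.17g")

    if session.ground_truth:
        gt = {}
        for nid, tun in session.ground_truth.items():
            gt[nid] = {
                "area": tun.area,
                "baseline_rate_hz": tun.baseline_rate_hz,
                "coefficients": tun.coefficients,
                "kernels": {k: dataclasses.asdict(v) for k, v in tun.kernels.items()},
            }
        (path / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True))
    return path


@dataclass
class Bundle:
    """In-memory view of a session bundle with inclusion flags."""

    config: TaskConfig
    trials: List[TaskTrial]
    recordings: List[NeuronRecording]
    ground_truth: Dict[str, NeuronTuning]
    excluded_neurons: Dict[str, str]  # neuron_id -> reason (flagged, not dropped)
    meta: dict

    def included_recordings(self) -> List[NeuronRecording]:
        return [r for r in self.recordings if r.neuron_id not in self.excluded_neurons]


def _opt(v):
    return None if pd.isna(v) else v


def read_bundle(path, min_valid_trials: int = 100, min_rate_hz: float = 1.0) -> Bundle:
    """Read and validate a bundle; flag neurons failing the inclusion rules.

    Flagged (not dropped): units with fewer than ``min_valid_trials``
    valid-cue (paradigm D) or target (paradigm G) trials, or a mean rate
    below ``min_rate_hz``.
    """
    path = Path(path)
    for fname in ("session.json", "trials.csv", "events.csv", "spikes.csv"):
        if not (path / fname).exists():
            raise BundleError(f"missing bundle file {fname}")
    meta = json.loads((path / "session.json").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise BundleError(f"unrecognized format version {meta.get('format_version')!r}")
    config = _config_from_json(meta["config"])

    trials_df = pd.read_csv(path / "trials.csv", na_values="NA", keep_default_na=False,
                            float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(trials_df.columns)
    if missing:
        raise BundleError(f"trials.csv missing columns {sorted(missing)}")
    events_df = pd.read_csv(path / "events.csv", na_values="NA", keep_default_na=False,
                            float_precision="round_trip")
    spikes_df = pd.read_csv(path / "spikes.csv", na_values="NA", keep_default_na=False,
                            float_precision="round_trip")
    missing = set(SPIKE_COLUMNS) - set(spikes_df.columns)
    if missing:
        raise BundleError(f"spikes.csv missing columns {sorted(missing)}")

    known_ids = set(trials_df.trial_id.astype(int))
    ev = events_df.pivot(index="trial_id", columns="event", values="time_s")
    trials = []
    for row_num, row in enumerate(trials_df.itertuples(index=False), start=2):
        tid = int(row.trial_id)
        e = ev.loc[tid]
        trial = TaskTrial(
            trial_id=tid, paradigm=meta["paradigm"],
            is_single_stimulus=bool(row.is_single_stimulus),
            cue_side=row.cue_side, trial_type=row.trial_type,
            left_value=None if pd.isna(row.left_value) else int(row.left_value),
            right_value=None if pd.isna(row.right_value) else int(row.right_value),
            change_side=_opt(row.change_side),
            change_latency_s=_opt(row.change_latency_s),
            distractor_latency_s=_opt(row.distractor_latency_s),
            outcome=_opt(row.outcome), rt_s=_opt(row.rt_s),
            responded_to=(None if pd.isna(row.rt_s)
                          else ("distractor" if row.outcome == "false_alarm" else "target")),
            delivered_reward_level=(None if pd.isna(row.delivered_reward_level)
                                    else int(row.delivered_reward_level)),
            t_cue_on=float(e["cue_on"]), t_stim_on=float(e["stim_on"]),
            t_cue_off=float(e["cue_off"]),
            t_change_on=_opt(e.get("change_on")),
            t_distractor_change_on=_opt(e.get("distractor_change_on")),
            t_response=_opt(e.get("response")), t_end=_opt(e.get("trial_end")),
        )
        trials.append(trial)

    if (spikes_df.spike_time_s < 0).any():
        bad = int(spikes_df.index[spikes_df.spike_time_s < 0][0]) + 2
        raise BundleError(f"negative spike time at spikes.csv row {bad}")
    recordings: Dict[str, NeuronRecording] = {}
    for (nid, area), grp in spikes_df.groupby(["neuron_id", "area"], sort=True):
        rec = NeuronRecording(neuron_id=str(nid), area=str(area))
        for tid, g in grp.groupby("trial_id", sort=True):
            if int(tid) not in known_ids:
                bad = int(g.index[0]) + 2
                raise BundleError(
                    f"spikes.csv row {bad}: unknown trial_id {tid} for neuron {nid}")
            times = g.spike_time_s.to_numpy()
            if np.any(np.diff(times) < 0):
                bad = int(g.index[np.flatnonzero(np.diff(times) < 0)[0] + 1]) + 2
                raise BundleError(f"non-monotone spike times at spikes.csv row {bad}")
            rec.spikes[int(tid)] = times
        recordings[rec.neuron_id] = rec

    # inclusion rules: flagged, never silently dropped
    valid_type = "valid" if meta["paradigm"] == "D" else "target"
    n_valid = sum(1 for t in trials if t.trial_type == valid_type and not t.is_single_stimulus)
    excluded = {}
    for rec in recordings.values():
        if n_valid < min_valid_trials:
            excluded[rec.neuron_id] = f"only {n_valid} {valid_type} trials (<{min_valid_trials})"
            continue
        rate = rec.mean_rate(trials)
        if rate < min_rate_hz:
            excluded[rec.neuron_id] = f"mean rate {rate:.2f} hz < {min_rate_hz} hz"

    ground_truth = {}
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        for nid, d in json.loads(gt_path.read_text()).items():
            ground_truth[nid] = NeuronTuning(
                neuron_id=nid, area=d["area"], baseline_rate_hz=d["baseline_rate_hz"],
                coefficients=d["coefficients"],
                kernels={k: Kernel(**v) for k, v in d["kernels"].items()})

    return Bundle(config=config, trials=trials, recordings=list(recordings.values()),
                  ground_truth=ground_truth, excluded_neurons=excluded, meta=meta)


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, stage: str, seed, params: dict, inputs: Optional[dict] = None):
    """Record the provenance of one pipeline stage for exact re-runs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": params,
        "input_hashes": inputs or {},
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
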