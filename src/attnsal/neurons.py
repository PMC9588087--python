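"""Inhomogeneous-Poisson spike-train synthesis with configurable task encoding.

Each neuron's instantaneous rate is a rectified linear combination of
event-anchored temporal kernels weighted by trial regressors:

    lambda(t) = max(0, baseline + sum_c  coeff_c * kernel_c(t) * x_c(trial))

where ``x_c`` is the signed cue location (-1/+1) for spatial components and a
z-scored reward level for value components.  Spike counts per (small) time bin
are Poisson; spike times are placed uniformly within their bin.

Two area profiles ship with the package: an OFC-like profile whose value
coding loads on the salient value (SV) with mixed tuning signs and whose cue
coding is only a brief frame-onset transient, and a DLPFC-like profile with
strong, sustained cue-location coding that flips sign after stimulus onset
(the covert attention shift away from the frame) plus moderate SV coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .task import TaskConfig, TaskTrial, side_sign

#: mean/sd used to standardize reward levels {0,1,2,4,8} inside the generator
VALUE_LEVELS = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
VALUE_MEAN = float(VALUE_LEVELS.mean())
VALUE_SD = float(VALUE_LEVELS.std())


def zscore_level(v) -> float:
    """Standardize a reward level against the uniform distribution over levels."""
    return (v - VALUE_MEAN) / VALUE_SD


@dataclass(frozen=True)
class Kernel:
    """Difference-of-exponentials temporal kernel, normalized to unit peak.

    Anchored to a trial event; zero before ``latency_s`` after the event.
    """

    event: str  # "cue_on" | "stim_on" | "change_on"
    latency_s: float = 0.05
    rise_s: float = 0.02
    decay_s: float = 0.2

    def __post_init__(self):
        if self.rise_s <= 0 or self.decay_s <= 0 or self.decay_s <= self.rise_s:
            raise ValueError("require 0 < rise_s < decay_s")

    def _peak(self) -> float:
        r, d = self.rise_s, self.decay_s
        t_star = (r * d) / (d - r) * math.log(d / r)
        return math.exp(-t_star / d) - math.exp(-t_star / r)

    def evaluate(self, t: np.ndarray, event_time: float) -> np.ndarray:
        """Kernel value at absolute times ``t`` given the anchor event time."""
        s = np.asarray(t, dtype=float) - event_time - self.latency_s
        out = np.zeros_like(s)
        pos = s > 0
        out[pos] = (np.exp(-s[pos] / self.decay_s) - np.exp(-s[pos] / self.rise_s)) / self._peak()
        return out


def default_kernels() -> Dict[str, Kernel]:
    return {
        # sustained while the frame directs bottom-up attention, decays after
        "cue_side_pre": Kernel("cue_on", latency_s=0.04, rise_s=0.02, decay_s=0.15),
        # brief visual transient to the frame onset
        "frame_transient": Kernel("cue_on", latency_s=0.04, rise_s=0.01, decay_s=0.06),
        # top-down attention side after the shift, opposite-signed coefficients
        # relative to cue_side_pre reproduce the flip geometry
        "cue_side_post": Kernel("stim_on", latency_s=0.15, rise_s=0.05, decay_s=8.0),
        "sv": Kernel("stim_on", latency_s=0.10, rise_s=0.05, decay_s=8.0),
        "nsv": Kernel("stim_on", latency_s=0.10, rise_s=0.05, decay_s=8.0),
    }


#: regressor extractor per component; spatial components are cue-side signed
def _component_value(name: str, trial: TaskTrial) -> float:
    if name in ("cue_side_pre", "cue_side_post", "frame_transient"):
        return float(trial.cue_loc)
    if name == "sv":
        return zscore_level(trial.sv) if trial.sv is not None else 0.0
    if name == "nsv":
        return zscore_level(trial.nsv) if trial.nsv is not None else 0.0
    raise KeyError(f"unknown tuning component {name!r}")


@dataclass
class NeuronTuning:
    """Ground-truth encoding parameters of one synthetic unit."""

    neuron_id: str
    area: str  # "OFC" | "DLPFC"
    baseline_rate_hz: float
    coefficients: Dict[str, float] = field(default_factory=dict)  # hz per unit regressor
    kernels: Dict[str, Kernel] = field(default_factory=default_kernels)

    def rate(self, trial: TaskTrial, t: np.ndarray) -> np.ndarray:
        """Rectified instantaneous rate lambda(t) for one trial."""
        lam = np.full(np.shape(t), self.baseline_rate_hz, dtype=float)
        events = {"cue_on": trial.t_cue_on, "stim_on": trial.t_stim_on,
                  "change_on": trial.t_change_on}
        for name, coeff in self.coefficients.items():
            if coeff == 0.0:
                continue
            k = self.kernels[name]
            ev = events[k.event]
            if ev is None:
                continue
            lam += coeff * _component_value(name, trial) * k.evaluate(t, ev)
        return np.maximum(lam, 0.0)


@dataclass
class NeuronRecording:
    """Spike timestamps of one unit, per trial, relative to trial start."""

    neuron_id: str
    area: str
    spikes: Dict[int, np.ndarray] = field(default_factory=dict)  # trial_id -> times

    def spike_count(self, trial_id: int, t0: float, t1: float) -> int:
        s = self.spikes.get(trial_id)
        if s is None:
            return 0
        return int(np.count_nonzero((s >= t0) & (s < t1)))

    def mean_rate(self, trials: Sequence[TaskTrial]) -> float:
        total_spikes = sum(len(self.spikes.get(t.trial_id, ())) for t in trials)
        total_time = sum(t.t_end for t in trials if t.t_end is not None)
        return total_spikes / total_time if total_time > 0 else 0.0


def simulate_neuron(tuning: NeuronTuning, trials: Sequence[TaskTrial], rng,
                    bin_ms: float = 2.0) -> NeuronRecording:
    """Draw a Poisson spike train per trial from the neuron's rate function."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dt = bin_ms / 1000.0
    rec = NeuronRecording(tuning.neuron_id, tuning.area)
    for trial in trials:
        t_end = trial.t_end if trial.t_end is not None else trial.t_stim_on + 3.0
        edges = np.arange(0.0, t_end + dt, dt)
        centers = edges[:-1] + dt / 2
        lam = tuning.rate(trial, centers)
        counts = rng.poisson(lam * dt)
        n = int(counts.sum())
        if n == 0:
            rec.spikes[trial.trial_id] = np.empty(0)
            continue
        lefts = np.repeat(edges[:-1], counts)
        times = np.sort(lefts + rng.random(n) * dt)
        rec.spikes[trial.trial_id] = times
    return rec


def expected_rate_table(tuning: NeuronTuning, trials: Sequence[TaskTrial],
                        window_fn, grid_ms: float = 2.0) -> np.ndarray:
    """Noise-free mean rate of each trial over a per-trial window.

    ``window_fn(trial) -> (t0, t1)``.  Used directly for exact-Gaussian unit
    tests (the rate-table bypass of the Poisson spiking front end).
    """
    out = np.full(len(trials), np.nan)
    dt = grid_ms / 1000.0
    for i, trial in enumerate(trials):
        w = window_fn(trial)
        if w is None:
            continue
        t0, t1 = w
        grid = np.arange(t0 + dt / 2, t1, dt)
        out[i] = float(tuning.rate(trial, grid).mean())
    return out


def gaussian_rate_table(tuning: NeuronTuning, trials, window_fn, noise_sd: float,
                        rng, grid_ms: float = 2.0) -> np.ndarray:
    """Rate table with additive i.i.d. Gaussian noise (exact linear-model data)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = expected_rate_table(tuning, trials, window_fn, grid_ms)
    return mu + noise_sd * rng.standard_normal(mu.shape)


# ---------------------------------------------------------------------------
# population profiles


@dataclass(frozen=True)
class PopulationProfile:
    """Coefficient distributions for sampling a population of tunings.

    ``p_*_tuned`` are mixture weights for carrying a non-zero coefficient;
    magnitudes are gamma-distributed (hz per z-unit / per cue sign unit).
    """

    name: str
    area: str
    baseline_log_mean: float = math.log(8.0)
    baseline_log_sd: float = 0.4
    p_sv_tuned: float = 0.7
    p_sv_positive: float = 0.58  # sign mixture among value-tuned units
    sv_gamma_shape: float = 2.0
    sv_gamma_scale: float = 1.5
    p_nsv_tuned: float = 0.15
    nsv_gamma_shape: float = 2.0
    nsv_gamma_scale: float = 0.4
    p_cue_tuned: float = 0.1
    cue_gamma_shape: float = 2.0
    cue_gamma_scale: float = 0.5
    post_flip_gain: tuple = (0.6, 1.4)  # cue_side_post = -gain * cue_side_pre
    p_frame_transient: float = 0.5
    frame_gamma_shape: float = 2.0
    frame_gamma_scale: float = 1.0


def ofc_like_profile(**overrides) -> PopulationProfile:
    """Value coding dominated by SV, negligible sustained cue coding."""
    return PopulationProfile(name="OFC-like", area="OFC", **overrides)


def dlpfc_like_profile(**overrides) -> PopulationProfile:
    """Strong cue-side coding with a pre/post sign flip, moderate SV coding."""
    params = dict(
        name="DLPFC-like", area="DLPFC",
        p_sv_tuned=0.4, sv_gamma_scale=0.8,
        p_nsv_tuned=0.1, nsv_gamma_scale=0.3,
        p_cue_tuned=0.9, cue_gamma_shape=3.0, cue_gamma_scale=1.2,
        p_frame_transient=0.3, frame_gamma_scale=0.5,
    )
    params.update(overrides)
    return PopulationProfile(**params)


PROFILES = {"OFC-like": ofc_like_profile, "DLPFC-like": dlpfc_like_profile}


def sample_tuning(profile: PopulationProfile, neuron_id: str, rng) -> NeuronTuning:
    baseline = float(np.exp(rng.normal(profile.baseline_log_mean, profile.baseline_log_sd)))
    coeffs = {}
    if rng.random() < profile.p_sv_tuned:
        mag = rng.gamma(profile.sv_gamma_shape, profile.sv_gamma_scale)
        sign = 1.0 if rng.random() < profile.p_sv_positive else -1.0
        coeffs["sv"] = sign * mag
    if rng.random() < profile.p_nsv_tuned:
        mag = rng.gamma(profile.nsv_gamma_shape, profile.nsv_gamma_scale)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        coeffs["nsv"] = sign * mag
    if rng.random() < profile.p_cue_tuned:
        mag = rng.gamma(profile.cue_gamma_shape, profile.cue_gamma_scale)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pre = sign * mag
        gain = rng.uniform(*profile.post_flip_gain)
        coeffs["cue_side_pre"] = pre
        coeffs["cue_side_post"] = -gain * pre
    if rng.random() < profile.p_frame_transient:
        mag = rng.gamma(profile.frame_gamma_shape, profile.frame_gamma_scale)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        coeffs["frame_transient"] = sign * mag
    return NeuronTuning(neuron_id=neuron_id, area=profile.area,
                        baseline_rate_hz=baseline, coefficients=coeffs)


@dataclass
class SyntheticSession:
    """A fully simulated session: trials, recordings, and their ground truth."""

    config: TaskConfig
    trials: List[TaskTrial]
    recordings: List[NeuronRecording]
    ground_truth: Dict[str, NeuronTuning] = field(default_factory=dict)
    behavior_params: Optional[object] = None


def generate_population(area_profile, n_neurons: int, trials: Sequence[TaskTrial],
                        seed, config: Optional[TaskConfig] = None,
                        bin_ms: float = 2.0) -> SyntheticSession:
    """Sample tunings from a profile and simulate every neuron's spike trains.

    ``area_profile`` may be a profile name ("OFC-like" / "DLPFC-like") or a
    :class:`PopulationProfile`.  Deterministic given the seed.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    if isinstance(area_profile, str):
        if area_profile not in PROFILES:
            raise ValueError(f"unknown profile {area_profile!r}")
        profile = PROFILES[area_profile]()
    else:
        profile = area_profile
    rng = np.random.default_rng(seed)
    recordings, truth = [], {}
    for i in range(n_neurons):
        nid = f"{profile.area.lower()}_{i:04d}"
        tuning = sample_tuning(profile, nid, rng)
        truth[nid] = tuning
        recordings.append(simulate_neuron(tuning, trials, rng, bin_ms=bin_ms))
    return SyntheticSession(config=config or TaskConfig(), trials=list(trials),
                            recordings=recordings, ground_truth=truth)
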