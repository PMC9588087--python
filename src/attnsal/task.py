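"""Posner-cueing luminance-detection task: schedules, latencies, behavioral outcomes.

Two paradigms are supported.  In paradigm ``D`` a frame cue indicates, with 90%
validity, the side *opposite* to the upcoming luminance change; the subject
responds to any change.  In paradigm ``G`` the subject must respond only to
changes at the cued location (target trials, 80%) and ignore changes at the
un-cued location (distractor-only 10%, distractor+target 10%).

Each trial presents a pair of over-trained stimuli associated with one of five
juice-reward levels.  The reward for a correct response is drawn at random
between the two stimuli, so neither the cue nor reward salience predicts the
outcome.  Value regressors (CV/UCV, SV/NSV, TV, ...) are derived properties of
a trial, never stored separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

LEFT = "left"
RIGHT = "right"
SIDES = (LEFT, RIGHT)

#: trial types per paradigm
D_TYPES = ("valid", "invalid")
G_TYPES = ("target", "distractor_only", "distractor_target")

OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")


def opposite(side: str) -> str:
    return RIGHT if side == LEFT else LEFT


def side_sign(side: str) -> int:
    """Attention-cue location code: left = -1, right = +1."""
    return 1 if side == RIGHT else -1


@dataclass(frozen=True)
class LatencySpec:
    """Truncated-exponential change latency: offset + Exp(tau) truncated at cutoff."""

    tau_s: float
    cutoff_s: float
    offset_s: float = 0.4

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be positive, got {self.tau_s}")
        if self.cutoff_s <= 0:
            raise ValueError(f"cutoff_s must be positive, got {self.cutoff_s}")

    @property
    def mean(self) -> float:
        """Closed-form mean of the truncated-exponential latency."""
        tau, c = self.tau_s, self.cutoff_s
        z = 1.0 - math.exp(-c / tau)
        return self.offset_s + tau - c * math.exp(-c / tau) / z


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the detection task.

    Event timing (seconds from trial start): fixation at 0; after 0.5 s the
    saccade target appears; after another 0.5 s the frame cue; stimuli 0.2 s
    later; the cue disappears 0.2 s after stimulus onset.  The luminance
    change follows stimulus onset at a truncated-exponential latency.
    """

    paradigm: str = "D"
    value_levels: tuple = (0, 1, 2, 4, 8)
    reward_volumes_ml: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.033, 1: 0.10, 2: 0.16, 4: 0.29, 8: 0.55}
    )
    p_valid: float = 0.90
    p_target: float = 0.80
    p_distractor_only: float = 0.10
    p_distractor_target: float = 0.10
    p_single: Optional[float] = None  # default depends on paradigm
    # latency distributions per change type
    latency_d: LatencySpec = LatencySpec(2.5, 1.4)
    latency_g_target: LatencySpec = LatencySpec(2.5, 1.9)
    latency_g_distractor: LatencySpec = LatencySpec(1.25, 1.9)
    # event times relative to trial start
    t_fixation_on: float = 0.0
    t_sacc_target_on: float = 0.5
    t_cue_on: float = 1.0
    t_stim_on: float = 1.2
    t_cue_off: float = 1.4
    response_window: tuple = (0.1, 0.4)
    # stimulus geometry, metadata only (never used in computation)
    eccentricity_deg: float = 7.0
    rotation_deg: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.paradigm not in ("D", "G"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.paradigm == "D":
            if not math.isclose(self.p_valid + (1 - self.p_valid), 1.0):
                raise ValueError("p_valid must lie in [0, 1]")
            if not 0 <= self.p_valid <= 1:
                raise ValueError("p_valid must lie in [0, 1]")
        else:
            tot = self.p_target + self.p_distractor_only + self.p_distractor_target
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                raise ValueError(f"paradigm G trial-type fractions sum to {tot}, not 1")
        if list(self.value_levels) != sorted(set(self.value_levels)):
            raise ValueError("value_levels must be strictly increasing")
        for t in (self.t_sacc_target_on, self.t_cue_on, self.t_stim_on, self.t_cue_off):
            if t <= self.t_fixation_on:
                raise ValueError("event times must be strictly increasing from fixation")
        if not self.response_window[1] > self.response_window[0] >= 0:
            raise ValueError("response window must be a non-empty interval")

    @property
    def single_fraction(self) -> float:
        if self.p_single is not None:
            return self.p_single
        return 0.071 if self.paradigm == "D" else 0.101

    def latency_spec(self, change: str = "target") -> LatencySpec:
        if self.paradigm == "D":
            return self.latency_d
        return self.latency_g_target if change == "target" else self.latency_g_distractor

    def trial_types(self) -> tuple:
        return D_TYPES if self.paradigm == "D" else G_TYPES

    def type_probs(self) -> np.ndarray:
        if self.paradigm == "D":
            return np.array([self.p_valid, 1.0 - self.p_valid])
        return np.array([self.p_target, self.p_distractor_only, self.p_distractor_target])


@dataclass
class TaskTrial:
    """One trial's design variables, timing, and (once simulated) its outcome.

    ``cue_side`` is the side of the frame cue; the *cued stimulus* — the one
    whose luminance change must be detected — sits on the opposite side.
    """

    trial_id: int
    paradigm: str
    is_single_stimulus: bool
    cue_side: str
    trial_type: str
    left_value: Optional[int]
    right_value: Optional[int]
    change_side: Optional[str]
    change_latency_s: Optional[float]  # target change, from stimulus onset
    distractor_latency_s: Optional[float] = None
    delivered_reward_level: Optional[int] = None
    outcome: Optional[str] = None
    rt_s: Optional[float] = None  # from the change the response followed
    responded_to: Optional[str] = None  # "target" | "distractor" | None
    # event times (seconds from trial start); filled by schedule/behavior
    t_cue_on: float = 1.0
    t_stim_on: float = 1.2
    t_cue_off: float = 1.4
    t_change_on: Optional[float] = None
    t_distractor_change_on: Optional[float] = None
    t_response: Optional[float] = None
    t_end: Optional[float] = None

    # ---- derived value regressors (pure functions of stored fields) ----

    @property
    def cued_side(self) -> str:
        """Side of the cued stimulus (opposite the frame)."""
        return opposite(self.cue_side)

    @property
    def cue_loc(self) -> int:
        """Attention cue location coded -1 (left) / +1 (right)."""
        return side_sign(self.cue_side)

    def _value(self, side: str) -> Optional[int]:
        return self.left_value if side == LEFT else self.right_value

    @property
    def cv(self) -> Optional[int]:
        """Cued value: value of the stimulus opposite the frame."""
        if self.is_single_stimulus:
            return self.v_sin
        return self._value(self.cued_side)

    @property
    def ucv(self) -> Optional[int]:
        if self.is_single_stimulus:
            return None
        return self._value(self.cue_side)

    @property
    def sv(self) -> Optional[int]:
        if self.is_single_stimulus:
            return self.v_sin
        return max(self.left_value, self.right_value)

    @property
    def nsv(self) -> Optional[int]:
        if self.is_single_stimulus:
            return None
        return min(self.left_value, self.right_value)

    @property
    def tv(self) -> Optional[int]:
        if self.is_single_stimulus:
            return None
        return self.left_value + self.right_value

    @property
    def v_sin(self) -> Optional[int]:
        if not self.is_single_stimulus:
            return None
        return self.left_value if self.left_value is not None else self.right_value

    @property
    def salient_side(self) -> Optional[str]:
        """Side of the higher-valued stimulus; None for ties or single-stimulus."""
        if self.is_single_stimulus or self.left_value == self.right_value:
            return None
        return LEFT if self.left_value > self.right_value else RIGHT

    @property
    def change_at_salient(self) -> Optional[bool]:
        """Whether the (first) luminance change is at the salient stimulus."""
        first = self.first_change_side
        if self.salient_side is None or first is None:
            return None
        return first == self.salient_side

    @property
    def first_change_side(self) -> Optional[str]:
        if self.trial_type in ("distractor_only", "distractor_target"):
            return self.cue_side  # distractor is at the un-cued (frame) side
        return self.change_side

    def regressor(self, name: str):
        """Look up a named task variable (LV, RV, CV, UCV, SV, NSV, diffs, TV, cue_loc)."""
        table = {
            "LV": self.left_value,
            "RV": self.right_value,
            "LV_RV": None if self.is_single_stimulus else self.left_value - self.right_value,
            "CV": self.cv,
            "UCV": self.ucv,
            "CV_UCV": None if self.is_single_stimulus else self.cv - self.ucv,
            "SV": self.sv,
            "NSV": self.nsv,
            "SV_NSV": None if self.is_single_stimulus else self.sv - self.nsv,
            "TV": self.tv,
            "V_sin": self.v_sin,
            "cue_loc": self.cue_loc,
        }
        if name not in table:
            raise KeyError(f"unknown task variable {name!r}")
        return table[name]


def sample_change_latency(tau_s, cutoff_s, offset_s, rng, size=None):
    """Draw latencies offset + X, X ~ Exponential(tau) truncated to [0, cutoff].

    Inverse-CDF sampling; support is exactly [offset, offset + cutoff].
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if cutoff_s < 0:
        raise ValueError("cutoff_s must be non-negative")
    if cutoff_s == 0:
        return offset_s if size is None else np.full(size, offset_s)
    u = rng.random(size)
    z = 1.0 - np.exp(-cutoff_s / tau_s)
    x = -tau_s * np.log1p(-u * z)
    return offset_s + x


def generate_trial_schedule(config: TaskConfig, n_trials: int, seed) -> list:
    """Generate a counterbalanced trial list for one session.

    Cue sides are exactly counterbalanced (|#left - #right| <= 1), stimulus
    pairs are drawn uniformly over the value grid, trial types follow the
    paradigm's fractions, and change latencies follow the paradigm's
    truncated-exponential distributions.  Deterministic given the seed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    levels = np.asarray(config.value_levels)

    # exact counterbalancing of the frame side
    n_left = n_trials // 2
    sides = np.array([LEFT] * n_left + [RIGHT] * (n_trials - n_left), dtype=object)
    if n_trials % 2 == 1 and rng.random() < 0.5:
        sides[n_left] = LEFT
        sides[0] = RIGHT
    rng.shuffle(sides)

    types = config.trial_types()
    type_idx = rng.choice(len(types), size=n_trials, p=config.type_probs())
    single = rng.random(n_trials) < config.single_fraction
    lv = levels[rng.integers(0, len(levels), size=n_trials)]
    rv = levels[rng.integers(0, len(levels), size=n_trials)]
    pick_left = rng.random(n_trials) < 0.5

    trials = []
    for i in range(n_trials):
        cue_side = sides[i]
        cued = opposite(cue_side)
        if single[i]:
            # single-stimulus trials: cued side only, cue always valid / target
            ttype = "valid" if config.paradigm == "D" else "target"
            left_value = int(lv[i]) if cued == LEFT else None
            right_value = int(rv[i]) if cued == RIGHT else None
            delivered = left_value if left_value is not None else right_value
        else:
            ttype = types[type_idx[i]]
            left_value, right_value = int(lv[i]), int(rv[i])
            delivered = left_value if pick_left[i] else right_value

        # change sides and latencies
        distractor_latency = None
        if config.paradigm == "D":
            change_side = cued if ttype == "valid" else cue_side
            latency = float(
                sample_change_latency(
                    config.latency_d.tau_s, config.latency_d.cutoff_s,
                    config.latency_d.offset_s, rng,
                )
            )
        else:
            spec_t = config.latency_g_target
            spec_d = config.latency_g_distractor
            if ttype == "target":
                change_side = cued
                latency = float(sample_change_latency(spec_t.tau_s, spec_t.cutoff_s, spec_t.offset_s, rng))
            elif ttype == "distractor_only":
                change_side = None
                latency = None
                distractor_latency = float(
                    sample_change_latency(spec_d.tau_s, spec_d.cutoff_s, spec_d.offset_s, rng)
                )
            else:  # distractor_target: distractor change first, then target
                change_side = cued
                distractor_latency = float(
                    sample_change_latency(spec_d.tau_s, spec_d.cutoff_s, spec_d.offset_s, rng)
                )
                latency = float(sample_change_latency(spec_t.tau_s, spec_t.cutoff_s, spec_t.offset_s, rng))
                while latency <= distractor_latency:
                    latency = float(
                        sample_change_latency(spec_t.tau_s, spec_t.cutoff_s, spec_t.offset_s, rng)
                    )

        trial = TaskTrial(
            trial_id=i,
            paradigm=config.paradigm,
            is_single_stimulus=bool(single[i]),
            cue_side=cue_side,
            trial_type=ttype,
            left_value=left_value,
            right_value=right_value,
            change_side=change_side,
            change_latency_s=latency,
            distractor_latency_s=distractor_latency,
            delivered_reward_level=delivered,
            t_cue_on=config.t_cue_on,
            t_stim_on=config.t_stim_on,
            t_cue_off=config.t_cue_off,
            t_change_on=None if latency is None else config.t_stim_on + latency,
            t_distractor_change_on=(
                None if distractor_latency is None else config.t_stim_on + distractor_latency
            ),
        )
        trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# behavioral simulation


@dataclass(frozen=True)
class BehaviorCell:
    """Response parameters for one (trial type x change-salience) condition."""

    p_respond: float  # hit probability (target change) or FA probability (distractor)
    rt_mean_s: float
    rt_sd_s: float

    def __post_init__(self):
        if not 0 <= self.p_respond <= 1:
            raise ValueError("response probability must lie in [0, 1]")


def _default_cells_d():
    # hit rates / RTs chosen to mimic a well-trained subject on paradigm D
    return {
        ("valid", "salient"): BehaviorCell(0.948, 0.2236, 0.040),
        ("valid", "non_salient"): BehaviorCell(0.939, 0.2254, 0.040),
        ("invalid", "salient"): BehaviorCell(0.907, 0.2363, 0.040),
        ("invalid", "non_salient"): BehaviorCell(0.899, 0.2319, 0.040),
    }


def _default_cells_g():
    return {
        ("target", "salient"): BehaviorCell(0.940, 0.2738, 0.040),
        ("target", "non_salient"): BehaviorCell(0.912, 0.2822, 0.040),
        # FA probability on the distractor change (CR rate = 1 - p)
        ("distractor", "salient"): BehaviorCell(0.196, 0.2944, 0.040),
        ("distractor", "non_salient"): BehaviorCell(0.176, 0.2990, 0.040),
        # target response after a correctly ignored distractor
        ("post_distractor_target", "salient"): BehaviorCell(0.905, 0.2712, 0.040),
        ("post_distractor_target", "non_salient"): BehaviorCell(0.895, 0.2712, 0.040),
    }


@dataclass
class BehaviorParams:
    """Per-condition Bernoulli outcome and truncated-normal RT parameters."""

    paradigm: str = "D"
    cells: Mapping = None
    response_window: tuple = (0.1, 0.4)

    def __post_init__(self):
        if self.cells is None:
            self.cells = _default_cells_d() if self.paradigm == "D" else _default_cells_g()
        lo, hi = self.response_window
        if hi <= lo:
            raise ValueError("RT window empty")
        for key, cell in self.cells.items():
            if not lo <= cell.rt_mean_s <= hi:
                raise ValueError(
                    f"RT mean {cell.rt_mean_s} for cell {key} outside response window"
                )

    def cell(self, trial_type: str, salient: Optional[bool]) -> BehaviorCell:
        sal = "salient" if (salient or salient is None) else "non_salient"
        return self.cells[(trial_type, sal)]


def _draw_rt(cell: BehaviorCell, window, rng) -> float:
    """RT from a normal truncated to the legal response window."""
    from scipy import stats

    a = (window[0] - cell.rt_mean_s) / cell.rt_sd_s
    b = (window[1] - cell.rt_mean_s) / cell.rt_sd_s
    return float(stats.truncnorm.rvs(a, b, loc=cell.rt_mean_s, scale=cell.rt_sd_s, random_state=rng))


def simulate_behavior(trial: TaskTrial, behav_params: BehaviorParams, rng) -> TaskTrial:
    """Fill in the outcome, RT, and response/end event times of one trial.

    Outcomes are Bernoulli draws per condition cell; RTs are truncated-normal
    within the response window.  On distractor+target trials the distractor
    response is resolved first: a false alarm ends the trial before the
    target change is ever scored.
    """
    t = replace(trial)
    window = behav_params.response_window
    sal = t.change_at_salient

    def finish(outcome, rt, responded_to, change_time):
        t.outcome = outcome
        t.rt_s = rt
        t.responded_to = responded_to
        t.t_response = None if rt is None else change_time + rt
        last_change = max(x for x in (t.t_change_on, t.t_distractor_change_on) if x is not None)
        t.t_end = last_change + 0.6
        if t.t_response is not None:
            t.t_end = max(t.t_end, t.t_response + 0.2)
        return t

    if t.paradigm == "D":
        cell = behav_params.cell(t.trial_type, sal)
        if rng.random() < cell.p_respond:
            return finish("hit", _draw_rt(cell, window, rng), "target", t.t_change_on)
        return finish("miss", None, None, t.t_change_on)

    # paradigm G
    if t.trial_type == "target":
        cell = behav_params.cell("target", sal)
        if rng.random() < cell.p_respond:
            return finish("hit", _draw_rt(cell, window, rng), "target", t.t_change_on)
        return finish("miss", None, None, t.t_change_on)

    # distractor change occurs first; salience judged from the distractor side
    d_sal = t.change_at_salient
    d_cell = behav_params.cell("distractor", d_sal)
    if rng.random() < d_cell.p_respond:
        rt = _draw_rt(d_cell, window, rng)
        if (t.trial_type == "distractor_target"
                and t.t_change_on is not None
                and t.t_change_on > t.t_distractor_change_on + rt):
            # the false alarm ends the trial before the target change is shown
            t.t_change_on = None
            t.change_latency_s = None
        return finish("false_alarm", rt, "distractor", t.t_distractor_change_on)
    if t.trial_type == "distractor_only":
        return finish("correct_rejection", None, None, t.t_distractor_change_on)
    # distractor+target: distractor ignored, target change scored
    tgt_side = t.change_side
    tgt_sal = None if t.salient_side is None else (tgt_side == t.salient_side)
    cell = behav_params.cell("post_distractor_target", tgt_sal)
    if rng.random() < cell.p_respond:
        rt = _draw_rt(cell, window, rng)
        t_resp = t.t_change_on + rt
        if t_resp < t.t_distractor_change_on + window[1]:
            # a saccade inside the distractor's response window counts as a
            # false alarm even when the target change had already occurred
            return finish("false_alarm", t_resp - t.t_distractor_change_on,
                          "distractor", t.t_distractor_change_on)
        return finish("hit", rt, "target", t.t_change_on)
    return finish("miss", None, None, t.t_change_on)


def simulate_session_behavior(trials: Sequence[TaskTrial], behav_params: BehaviorParams,
                              seed) -> list:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [simulate_behavior(t, behav_params, rng) for t in trials]
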