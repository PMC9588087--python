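"""Single-neuron value and attention coding: selectivity, CPD, grouped responses.

Selectivity is screened with simple per-variable linear regressions of epoch
firing rates (two-sided t on the slope, p < 0.005), and value-selective
neurons are classed positive / negative / contradictory by the signs of
their significant value slopes across epochs.

Value-vs-attention coding is quantified with two three-regressor linear
models of the trial firing rate — cue location with either the salient and
non-salient values (SV, NSV) or the cued and un-cued values (CV, UCV), all
predictors z-scored — and the coefficient of partial determination

    CPD_i = (SSE_without_i - SSE_full) / SSE_without_i,

the fraction of residual variance uniquely explained by regressor i.  CPD
time courses are tested per bin against a pre-cue baseline (the CPD in the
200 ms before cue onset, averaged over regressors) with paired t-tests and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import bh_fdr, bin_rates
from .task import TaskTrial

log = logging.getLogger(__name__)

SELECTIVITY_P = 0.005

#: per-trial epoch windows (absolute trial time); None excludes the trial
EPOCHS: Dict[str, Callable] = {
    "precue": lambda tr: (tr.t_cue_on - 0.2, tr.t_cue_on),
    "cue_stimulus": lambda tr: (tr.t_stim_on, tr.t_stim_on + 0.2),
    "early_stimulus": lambda tr: (tr.t_stim_on + 0.2, tr.t_stim_on + 0.6),
    "late_stimulus": lambda tr: (
        None if tr.t_change_on is None or tr.t_change_on - 0.4 < tr.t_stim_on
        else (tr.t_change_on - 0.4, tr.t_change_on)),
    "stimulus_period": lambda tr: (
        None if tr.t_change_on is None else (tr.t_stim_on, tr.t_change_on)),
    "postcue_period": lambda tr: (
        None if tr.t_change_on is None else (tr.t_cue_off, tr.t_change_on)),
}

SCREEN_EPOCHS = ("cue_stimulus", "early_stimulus", "late_stimulus")
VALUE_VARIABLES = ("LV", "RV", "LV_RV", "CV", "UCV", "CV_UCV", "SV", "NSV", "SV_NSV", "TV")


def analysis_trials(trials: Sequence[TaskTrial], single: bool = False) -> List[TaskTrial]:
    """Correct (hit) trials entering the neural analyses."""
    return [t for t in trials
            if t.outcome == "hit" and t.is_single_stimulus == single]


def epoch_rates(recording, trials: Sequence[TaskTrial],
                epochs: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mean firing rate per trial per named epoch (spike count / duration)."""
    epochs = list(EPOCHS) if epochs is None else list(epochs)
    out = {}
    for name in epochs:
        fn = EPOCHS[name]
        col = np.full(len(trials), np.nan)
        for i, tr in enumerate(trials):
            w = fn(tr)
            if w is None:
                continue
            t0, t1 = w
            if t1 <= t0:
                raise ValueError(f"epoch {name!r} has non-positive length on trial {tr.trial_id}")
            col[i] = recording.spike_count(tr.trial_id, t0, t1) / (t1 - t0)
        out[name] = col
    return pd.DataFrame(out, index=[t.trial_id for t in trials])


# ---------------------------------------------------------------------------
# simple-regression selectivity screen


def _simple_regression(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    """OLS y = b0 + b1 x; returns (b0, b1, t, two-sided p)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise ValueError("constant regressor: rank-deficient design")
    resid = y - X @ beta
    dof = n - 2
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[0]), float(beta[1]), float(t), float(p)


@dataclass
class SelectivityResult:
    """Per-variable, per-epoch tuning of one neuron."""

    neuron_id: str
    table: pd.DataFrame  # variable, epoch, beta0, beta1, t, p, selective
    tuning_class: str  # positive | negative | contradictory | none
    value_selective: bool


def selectivity_screen(rates: pd.DataFrame, trials: Sequence[TaskTrial],
                       neuron_id: str = "", p_threshold: float = SELECTIVITY_P,
                       single_rates: Optional[pd.DataFrame] = None,
                       single_trials: Optional[Sequence[TaskTrial]] = None) -> SelectivityResult:
    """Screen one neuron's epoch rates against every task variable.

    ``rates`` holds double-stimulus correct trials; single-stimulus value
    tuning (V_sin) is screened from ``single_rates`` when provided.  A neuron
    is value-selective if any value variable reaches p < 0.005 in any epoch;
    signs of the significant value slopes define the tuning class (mixed
    signs across variables or epochs are contradictory).
    """
    rows = []

    def screen(df, trs, variables):
        for var in variables:
            x_all = np.array([np.nan if t.regressor(var) is None else t.regressor(var)
                              for t in trs], dtype=float)
            for epoch in SCREEN_EPOCHS:
                y_all = df[epoch].to_numpy()
                keep = ~(np.isnan(x_all) | np.isnan(y_all))
                if keep.sum() < 3 or np.ptp(x_all[keep]) == 0:
                    continue
                b0, b1, t, p = _simple_regression(x_all[keep], y_all[keep])
                rows.append(dict(variable=var, epoch=epoch, beta0=b0, beta1=b1,
                                 t=t, p=p, selective=p < p_threshold))

    screen(rates, trials, VALUE_VARIABLES + ("cue_loc",))
    if single_rates is not None and single_trials:
        screen(single_rates, single_trials, ("V_sin",))
    table = pd.DataFrame(rows)

    value_vars = set(VALUE_VARIABLES) | {"V_sin"}
    sig = table[(table.selective) & (table.variable.isin(value_vars))]
    if len(sig) == 0:
        cls, value_sel = "none", False
    else:
        value_sel = True
        signs = np.sign(sig.beta1.to_numpy())
        if np.all(signs > 0):
            cls = "positive"
        elif np.all(signs < 0):
            cls = "negative"
        else:
            cls = "contradictory"
    return SelectivityResult(neuron_id=neuron_id, table=table,
                             tuning_class=cls, value_selective=value_sel)


def screen_population(recordings, trials: Sequence[TaskTrial],
                      p_threshold: float = SELECTIVITY_P) -> Dict[str, SelectivityResult]:
    """Run the selectivity screen for every recorded unit."""
    double = analysis_trials(trials, single=False)
    single = analysis_trials(trials, single=True)
    out = {}
    for rec in recordings:
        rates = epoch_rates(rec, double, SCREEN_EPOCHS)
        srates = epoch_rates(rec, single, SCREEN_EPOCHS) if single else None
        out[rec.neuron_id] = selectivity_screen(rates, double, rec.neuron_id,
                                                p_threshold, srates, single)
    return out


# ---------------------------------------------------------------------------
# CPD regression


@dataclass(frozen=True)
class CpdModelSpec:
    """Regressor set of one three-predictor linear rate model."""

    name: str
    regressors: Tuple[str, ...]


SV_NSV_MODEL = CpdModelSpec("sv_nsv", ("cue_loc", "SV", "NSV"))
CV_UCV_MODEL = CpdModelSpec("cv_ucv", ("cue_loc", "CV", "UCV"))
MODELS = {m.name: m for m in (SV_NSV_MODEL, CV_UCV_MODEL)}


def design_matrix(trials: Sequence[TaskTrial], spec: CpdModelSpec) -> np.ndarray:
    """Z-scored predictor matrix (no intercept column) for the trial subset."""
    cols = []
    for name in spec.regressors:
        x = np.array([t.regressor(name) for t in trials], dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"predictor {name!r} is constant on this trial subset")
        cols.append((x - x.mean()) / sd)
    return np.column_stack(cols)


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits of each column of Y on X (with intercept)."""
    n = X.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(Xd)
    proj = Q.T @ Y
    return np.maximum((Y * Y).sum(axis=0) - (proj * proj).sum(axis=0), 0.0)


@dataclass
class CpdFit:
    """Full-model coefficients and per-regressor CPDs for one response vector."""

    regressors: Tuple[str, ...]
    beta: np.ndarray  # (k+1,), intercept first
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sse_full: float
    sse_reduced: Dict[str, float]
    cpd: Dict[str, float]
    condition_warning: bool = False


def fit_cpd(y: np.ndarray, X: np.ndarray, names: Sequence[str],
            min_trials: int = 10) -> CpdFit:
    """OLS full and leave-one-regressor-out models; CPD per regressor.

    ``X`` holds the already z-scored predictors (one column per name).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")
    Xd = np.column_stack([np.ones(n), X])
    cond_warn = np.linalg.cond(Xd) > 1e8
    if cond_warn:
        log.warning("collinear predictors (condition number > 1e8); CPDs unstable")
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    sse_full = float(resid @ resid)
    dof = n - (k + 1)
    sigma2 = sse_full / dof
    cov = sigma2 * np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sse_red, cpd = {}, {}
    yy = y[:, None]
    for i, name in enumerate(names):
        Xr = np.delete(X, i, axis=1)
        s = float(_sse(Xr, yy)[0])
        sse_red[name] = s
        cpd[name] = (s - sse_full) / s if s > 0 else 0.0
        cpd[name] = max(cpd[name], 0.0)
    return CpdFit(regressors=tuple(names), beta=beta, se=se, t=tvals, p=pvals,
                  sse_full=sse_full, sse_reduced=sse_red, cpd=cpd,
                  condition_warning=cond_warn)


def _cpd_per_bin(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """CPDs of every regressor for every response column; (n_bins, k)."""
    sse_full = _sse(X, Y)
    k = X.shape[1]
    out = np.empty((Y.shape[1], k))
    for i in range(k):
        sse_red = _sse(np.delete(X, i, axis=1), Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (sse_red - sse_full) / sse_red
        out[:, i] = np.clip(np.nan_to_num(c), 0.0, None)
    return out


@dataclass
class CpdResult:
    """Population CPD time courses with baseline-referenced significance."""

    spec: CpdModelSpec
    neuron_ids: List[str]
    alignments: List[str]
    bin_centers: Dict[str, np.ndarray]
    cpd: Dict[str, np.ndarray]  # alignment -> (N, B, k)
    baseline: np.ndarray  # (N,) mean CPD over regressors in the pre-cue window
    table: pd.DataFrame  # per alignment/bin/regressor population stats
    contrast: pd.DataFrame  # regressor-2 vs regressor-3 paired test per bin


def cpd_timecourse(recordings, trials: Sequence[TaskTrial], spec: CpdModelSpec,
                   bin_ms: float = 25.0,
                   alignments: Sequence[str] = ("stim_on", "change_on"),
                   windows: Optional[Mapping[str, Tuple[float, float]]] = None,
                   baseline_window: Tuple[float, float] = (-0.2, 0.0),
                   alpha: float = 0.005) -> CpdResult:
    """CPD time courses per neuron, population t-tests against the baseline.

    Firing rates are computed in ``bin_ms`` windows aligned to stimulus onset
    and to the luminance change; the per-neuron baseline is the regressor-
    averaged CPD of the rate in the 200 ms before cue onset.  Per-bin paired
    t-tests (neuron-wise) against baseline and between the two value
    regressors are Benjamini-Hochberg corrected across bins.
    """
    windows = dict(windows or {"stim_on": (-0.6, 0.6), "change_on": (-0.4, 0.4)})
    use = analysis_trials(trials)
    if not use:
        raise ValueError("no correct double-stimulus trials")
    X = design_matrix(use, spec)
    k = X.shape[1]

    # baseline: one 200 ms pre-cue window
    lo, hi = baseline_window
    if hi <= lo:
        raise ValueError("empty baseline window")
    base_tensor = bin_rates(recordings, use, "cue_on", window=(lo, hi),
                            bin_ms=(hi - lo) * 1000.0)
    N = len(recordings)
    baseline = np.empty(N)
    for j in range(N):
        baseline[j] = _cpd_per_bin(base_tensor.values[:, :, j], X).mean()

    cpd, centers = {}, {}
    for al in alignments:
        tensor = bin_rates(recordings, use, al, window=windows[al], bin_ms=bin_ms)
        B = len(tensor.bin_centers)
        arr = np.empty((N, B, k))
        for j in range(N):
            arr[j] = _cpd_per_bin(tensor.values[:, :, j], X)
        cpd[al] = arr
        centers[al] = tensor.bin_centers

    # population tests, FDR across all bins of both alignments per regressor
    rows, contrast_rows = [], []
    for i, name in enumerate(spec.regressors):
        pvals, keys = [], []
        for al in alignments:
            for b, c in enumerate(centers[al]):
                vals = cpd[al][:, b, i]
                t, p = stats.ttest_rel(vals, baseline)
                pvals.append(p)
                keys.append((al, c, vals.mean(), vals.std(ddof=1) / np.sqrt(N), t))
        rej, padj = bh_fdr(pvals, alpha=alpha)
        for (al, c, m, sem, t), p, r, pa in zip(keys, pvals, rej, padj):
            rows.append(dict(alignment=al, bin_center=c, regressor=name, mean_cpd=m,
                             sem=sem, t=t, p=p, p_fdr=pa, significant=bool(r)))
    # value-regressor contrast (regressors 2 vs 3)
    pvals, keys = [], []
    for al in alignments:
        for b, c in enumerate(centers[al]):
            d1, d2 = cpd[al][:, b, 1], cpd[al][:, b, 2]
            t, p = stats.ttest_rel(d1, d2)
            pvals.append(p)
            keys.append((al, c, (d1 - d2).mean(), t))
    rej, padj = bh_fdr(pvals, alpha=alpha)
    for (al, c, md, t), p, r, pa in zip(keys, pvals, rej, padj):
        contrast_rows.append(dict(alignment=al, bin_center=c, mean_diff=md, t=t,
                                  p=p, p_fdr=pa, significant=bool(r)))
    return CpdResult(spec=spec, neuron_ids=[r.neuron_id for r in recordings],
                     alignments=list(alignments), bin_centers=centers, cpd=cpd,
                     baseline=baseline, table=pd.DataFrame(rows),
                     contrast=pd.DataFrame(contrast_rows))


@dataclass
class EpochCpdResult:
    """Per-neuron epoch CPDs plus population comparisons."""

    spec: CpdModelSpec
    window: str
    table: pd.DataFrame  # neuron_id x regressor: cpd, beta, p, significant
    value_paired_t: Tuple[float, float]  # regressor 2 vs 3 CPDs across neurons
    delta_cpd: pd.DataFrame  # per neuron: cpd(cue_loc) - cpd(second regressor)
    delta_t: Tuple[float, float, float]  # mean, t, p (one-sample)


def epoch_cpd_summary(recordings, trials: Sequence[TaskTrial], spec: CpdModelSpec,
                      window: str = "stimulus_period",
                      p_coef: float = 0.05) -> EpochCpdResult:
    """Epoch-level CPDs per neuron with per-coefficient significance.

    The response is the mean rate over the (per-trial, variable-length)
    window.  Coefficient significance is the regression t-test at ``p_coef``
    uncorrected.  Population comparisons: paired t between the two value
    regressors' CPDs, and the per-neuron difference CPD(cue) - CPD(value)
    against zero.
    """
    if len(recordings) < 2:
        raise ValueError("need at least two neurons for population tests")
    use = analysis_trials(trials)
    X = design_matrix(use, spec)
    rows = []
    for rec in recordings:
        y = epoch_rates(rec, use, [window])[window].to_numpy()
        keep = ~np.isnan(y)
        fit = fit_cpd(y[keep], X[keep], spec.regressors)
        for i, name in enumerate(spec.regressors):
            rows.append(dict(neuron_id=rec.neuron_id, regressor=name,
                             cpd=fit.cpd[name], beta=fit.beta[i + 1],
                             p=fit.p[i + 1], significant=fit.p[i + 1] < p_coef))
    table = pd.DataFrame(rows)
    wide = table.pivot(index="neuron_id", columns="regressor", values="cpd")
    r_cue, r_v1, r_v2 = spec.regressors
    if np.allclose(wide[r_v1], wide[r_v2]):
        t_val, p_val = np.nan, np.nan
        log.warning("degenerate paired t: identical CPDs for %s and %s", r_v1, r_v2)
    else:
        t_val, p_val = stats.ttest_rel(wide[r_v1], wide[r_v2])
    delta = (wide[r_cue] - wide[r_v1]).rename("delta_cpd").reset_index()
    if np.allclose(delta.delta_cpd, delta.delta_cpd.iloc[0]):
        dt, dp = np.nan, np.nan
    else:
        dt, dp = stats.ttest_1samp(delta.delta_cpd, 0.0)
    return EpochCpdResult(spec=spec, window=window, table=table,
                          value_paired_t=(float(t_val), float(p_val)),
                          delta_cpd=delta,
                          delta_t=(float(delta.delta_cpd.mean()), float(dt), float(dp)))


# ---------------------------------------------------------------------------
# grouped population responses and ANOVA


GROUPINGS = ("identical_pairs", "sv", "cv", "ucv", "sv8_toward_away")


def _group_of(trial: TaskTrial, grouping: str):
    """(group label, value level) of a trial under a named grouping, or None."""
    if grouping == "identical_pairs":
        if trial.left_value == trial.right_value:
            return "identical", trial.left_value
        return None
    if grouping == "sv":
        return ("sv", trial.sv) if trial.left_value != trial.right_value else None
    if grouping == "cv":
        return "cv", trial.cv
    if grouping == "ucv":
        return "ucv", trial.ucv
    if grouping == "sv8_toward_away":
        if trial.sv != 8:
            return None
        if trial.cv == 8:
            return "toward", trial.nsv  # attention on the 8-drop stimulus
        return "away", trial.nsv
    raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class GroupedResponse:
    """Population mean epoch responses for a trial grouping."""

    groupings: Tuple[str, ...]
    tuning_class: Optional[str]
    cells: pd.DataFrame  # neuron_id, group, value, rate (epoch mean)
    population: pd.DataFrame  # group, value, mean, sem, n_neurons


def grouped_population_response(recordings, trials: Sequence[TaskTrial],
                                groupings: Sequence[str],
                                tuning: Optional[Mapping[str, str]] = None,
                                tuning_class: Optional[str] = None,
                                epoch: str = "stimulus_period") -> GroupedResponse:
    """Per-neuron group means then across-neuron mean +/- SEM per (group, value).

    ``tuning`` maps neuron_id to its tuning class; when ``tuning_class`` is
    given only those neurons enter.  Neurons with an empty cell are omitted
    from that group with a log entry.
    """
    use = analysis_trials(trials)
    recs = [r for r in recordings
            if tuning_class is None or (tuning or {}).get(r.neuron_id) == tuning_class]
    rows = []
    for rec in recs:
        rates = epoch_rates(rec, use, [epoch])[epoch].to_numpy()
        for grouping in groupings:
            cells: Dict[tuple, list] = {}
            for r, tr in zip(rates, use):
                g = _group_of(tr, grouping)
                if g is None or np.isnan(r):
                    continue
                cells.setdefault(g, []).append(r)
            if not cells:
                log.info("neuron %s has no trials under grouping %s", rec.neuron_id, grouping)
                continue
            for (group, value), vals in cells.items():
                rows.append(dict(neuron_id=rec.neuron_id, grouping=grouping,
                                 group=group, value=value, rate=float(np.mean(vals)),
                                 n_trials=len(vals)))
    cells_df = pd.DataFrame(rows)
    pop = (cells_df.groupby(["group", "value"])["rate"]
           .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n_neurons="count")
           .reset_index())
    return GroupedResponse(groupings=tuple(groupings), tuning_class=tuning_class,
                           cells=cells_df, population=pop)


def two_way_anova(cells: pd.DataFrame, response: str = "rate",
                  factors: Tuple[str, str] = ("group", "value")) -> pd.DataFrame:
    """Additive two-way ANOVA (no interaction), type-II sums of squares.

    Returns one row per factor with F, p, and degrees of freedom.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    f1, f2 = factors
    for f in factors:
        if cells[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    model = smf.ols(f"{response} ~ C({f1}) + C({f2})", data=cells).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.rename(index={f"C({f1})": f1, f"C({f2})": f2})
    out = out.loc[[f1, f2], ["sum_sq", "df", "F", "PR(>F)"]]
    return out.rename(columns={"PR(>F)": "p"})
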