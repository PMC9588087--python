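"""Pseudo-population decoding of covert attention (cue) location.

The pipeline mirrors standard population-decoding practice for serially
recorded units: event-aligned spike-count rates are z-scored per neuron over
all trials and time points of both alignment windows, Gaussian-smoothed,
assembled into a class-balanced pseudo-ensemble (M trials x T bins x N
neurons), reduced by PCA to the components capturing a fixed fraction of
variance, and classified with a two-class linear discriminant (pooled
covariance, equal priors).  Performance is the posterior probability assigned
to the true cue side, estimated by leave-one-out cross-validation repeated
over independently resampled pseudo-ensembles; chance is 0.5 by construction.

Cross-temporal generalization trains the discriminant at one time (or on a
pre-stimulus window) and tests at all times in a shared (joint-PCA) subspace;
posteriors below the shuffle level indicate a sign-reversed representation —
attention on the side opposite to where it was during training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from scipy.special import expit

log = logging.getLogger(__name__)

#: event-aligned analysis windows (seconds relative to the event)
ALIGNMENTS = {"stim_on": (-0.4, 0.6), "change_on": (-0.4, 0.4)}

CHANCE = 0.5


# ---------------------------------------------------------------------------
# binning, z-scoring, smoothing


@dataclass
class AlignedRateTensor:
    """trials x time-bins x neurons firing-rate array around one event."""

    values: np.ndarray
    bin_centers: np.ndarray  # seconds relative to the alignment event
    alignment: str
    trial_ids: np.ndarray
    neuron_ids: List[str]
    bin_ms: float
    zscored: bool = False
    smoothed: bool = False

    @property
    def n_trials(self):
        return self.values.shape[0]


def bin_rates(recordings, trials, alignment: str, window: Optional[Tuple[float, float]] = None,
              bin_ms: float = 10.0) -> AlignedRateTensor:
    """Bin spike counts into half-open bins around an alignment event.

    Trials lacking the event (e.g. correct rejections for the
    luminance-change alignment) are excluded.  Rates are counts / bin width.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if window is None:
        if alignment not in ALIGNMENTS:
            raise ValueError(f"unknown alignment {alignment!r}")
        window = ALIGNMENTS[alignment]
    event_attr = {"stim_on": "t_stim_on", "change_on": "t_change_on",
                  "cue_on": "t_cue_on"}.get(alignment)
    if event_attr is None:
        raise ValueError(f"unknown alignment {alignment!r}")

    kept = [t for t in trials if getattr(t, event_attr) is not None]
    if not kept:
        raise ValueError(f"no trial has the event {alignment!r}")
    dt = bin_ms / 1000.0
    edges = np.arange(window[0], window[1] + dt / 2, dt)
    centers = edges[:-1] + dt / 2
    values = np.zeros((len(kept), len(centers), len(recordings)))
    for j, rec in enumerate(recordings):
        for i, trial in enumerate(kept):
            ev = getattr(trial, event_attr)
            s = rec.spikes.get(trial.trial_id)
            if s is None:
                values[i, :, j] = np.nan
                continue
            counts, _ = np.histogram(s - ev, bins=edges)
            values[i, :, j] = counts / dt
    return AlignedRateTensor(values=values, bin_centers=centers, alignment=alignment,
                             trial_ids=np.array([t.trial_id for t in kept]),
                             neuron_ids=[r.neuron_id for r in recordings], bin_ms=bin_ms)


def _gaussian_taps(sigma_ms: float, window_ms: float, bin_ms: float) -> np.ndarray:
    half = int(round(window_ms / 2 / bin_ms))
    x = np.arange(-half, half + 1) * bin_ms
    w = np.exp(-0.5 * (x / sigma_ms) ** 2)
    return w / w.sum()


def zscore_and_smooth(tensors: Sequence[AlignedRateTensor], sigma_ms: float = 50.0,
                      window_ms: float = 100.0) -> List[AlignedRateTensor]:
    """Z-score each neuron jointly over all tensors, then Gaussian-smooth.

    The z-scoring pools all trials and all time points of every provided
    alignment window, so a neuron has global mean 0 / sd 1 across the set.
    Zero-variance neurons are excluded (with a logged warning) from every
    returned tensor.  Smoothing uses a Gaussian kernel (sigma ``sigma_ms``)
    truncated to ``window_ms`` and renormalized at the edges.
    """
    pooled = [np.concatenate([t.values[:, :, j].ravel() for t in tensors])
              for j in range(len(tensors[0].neuron_ids))]
    means = np.array([np.nanmean(p) for p in pooled])
    sds = np.array([np.nanstd(p) for p in pooled])
    keep = sds > 0
    if not np.all(keep):
        dropped = [tensors[0].neuron_ids[j] for j in np.flatnonzero(~keep)]
        log.warning("excluding %d zero-variance neurons: %s", len(dropped), dropped)

    out = []
    for t in tensors:
        v = (t.values[:, :, keep] - means[keep]) / sds[keep]
        taps = _gaussian_taps(sigma_ms, window_ms, t.bin_ms)
        num = ndimage.convolve1d(v, taps, axis=1, mode="constant", cval=0.0)
        den = ndimage.convolve1d(np.ones(v.shape[1]), taps, mode="constant", cval=0.0)
        v = num / den[None, :, None]
        out.append(AlignedRateTensor(values=v, bin_centers=t.bin_centers,
                                     alignment=t.alignment, trial_ids=t.trial_ids,
                                     neuron_ids=[n for n, k in zip(t.neuron_ids, keep) if k],
                                     bin_ms=t.bin_ms, zscored=True, smoothed=True))
    return out


# ---------------------------------------------------------------------------
# pseudo-ensemble assembly and PCA


@dataclass
class PseudoEnsemble:
    """Class-balanced pseudo-trial tensor and (optionally) its PCA subspaces."""

    values: np.ndarray  # (M, T, N)
    labels: np.ndarray  # (M,), -1 / +1 cue side
    bin_centers: np.ndarray
    neuron_ids: List[str]
    pca_mode: Optional[str] = None  # "per_bin" | "joint"
    var_threshold: Optional[float] = None
    reduced: Optional[object] = None  # list of (M,P_t) arrays, or (M,T,Q) array
    dims: Optional[List[int]] = None


def build_pseudo_population(tensor: AlignedRateTensor, labels: np.ndarray,
                            n_per_class: int = 100, min_trials: Optional[int] = None,
                            seed=None) -> PseudoEnsemble:
    """Assemble a balanced pseudo-ensemble by independent per-neuron sampling.

    For each neuron, ``n_per_class`` trials per cue side are drawn without
    replacement; pseudo-trial m pairs the m-th sampled trial of every neuron
    within each class.  Neurons with fewer than ``min_trials`` trials in
    either class raise an error (filter upstream).  Deterministic given seed.
    """
    min_trials = n_per_class if min_trials is None else min_trials
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two label classes")
    M = 2 * n_per_class
    T = len(tensor.bin_centers)
    N = len(tensor.neuron_ids)
    values = np.empty((M, T, N))
    for j in range(N):
        valid = ~np.isnan(tensor.values[:, 0, j])
        for c_i, c in enumerate(classes):
            idx = np.flatnonzero(valid & (labels == c))
            if len(idx) < max(min_trials, n_per_class):
                raise ValueError(
                    f"neuron {tensor.neuron_ids[j]} has {len(idx)} trials in class {c}, "
                    f"needs {max(min_trials, n_per_class)}")
            pick = rng.choice(idx, size=n_per_class, replace=False)
            values[c_i * n_per_class:(c_i + 1) * n_per_class, :, j] = tensor.values[pick, :, j]
    ens_labels = np.repeat(classes, n_per_class)
    return PseudoEnsemble(values=values, labels=ens_labels,
                          bin_centers=tensor.bin_centers, neuron_ids=list(tensor.neuron_ids))


def _pca_scores(X: np.ndarray, var_threshold: float) -> Tuple[np.ndarray, int]:
    """Scores on the smallest leading subspace capturing >= threshold variance."""
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    ratio = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(ratio, var_threshold - 1e-12) + 1)
    return U[:, :k] * S[:k], k


def pca_reduce(ensemble: PseudoEnsemble, mode: str = "per_bin",
               var_threshold: float = 0.70) -> PseudoEnsemble:
    """Attach PCA-reduced views of the ensemble.

    ``per_bin``: an independent subspace per time bin.  ``joint``: one
    subspace fit on the (M*T, N) unfolding, so every bin shares the same
    subspace (required for cross-temporal decoding).
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must lie in (0, 1]")
    M, T, N = ensemble.values.shape
    if mode == "per_bin":
        reduced, dims = [], []
        for t in range(T):
            scores, k = _pca_scores(ensemble.values[:, t, :], var_threshold)
            reduced.append(scores)
            dims.append(k)
    elif mode == "joint":
        flat = ensemble.values.transpose(0, 1, 2).reshape(M * T, N)
        scores, k = _pca_scores(flat, var_threshold)
        reduced = scores.reshape(M, T, k)
        dims = [k]
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")
    ensemble.pca_mode = mode
    ensemble.var_threshold = var_threshold
    ensemble.reduced = reduced
    ensemble.dims = dims
    return ensemble


# ---------------------------------------------------------------------------
# linear discriminant with pooled covariance


def _pooled_scatter(X, y01, m0, m1):
    D = X - np.where(y01[:, None] == 1, m1, m0)
    return D.T @ D, D


def _ridge_if_needed(S, p):
    if np.linalg.cond(S) > 1e8:
        return 1e-6 * np.trace(S) / p
    return 0.0


@dataclass
class LinearDiscriminant:
    """Two-class Gaussian discriminant with pooled covariance."""

    classes: np.ndarray
    means: np.ndarray  # (2, P)
    cov: np.ndarray
    w: np.ndarray
    b: float
    prior: float = 0.5

    def posterior(self, X) -> np.ndarray:
        """P(class = classes[1] | x) via Bayes with the stated prior."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None] if len(self.w) == 1 else X[None, :]
        s = X @ self.w + self.b
        return expit(s)

    def predict(self, X) -> np.ndarray:
        return self.classes[(self.posterior(X) > 0.5).astype(int)]


def lda_fit(X, y, prior: float = 0.5) -> LinearDiscriminant:
    """Fit class means and pooled covariance; posterior through Bayes' rule."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("lda_fit requires exactly two classes")
    n = len(y)
    if n < 4:
        raise ValueError("too few trials")
    y01 = (y == classes[1]).astype(int)
    m0 = X[y01 == 0].mean(axis=0)
    m1 = X[y01 == 1].mean(axis=0)
    S, _ = _pooled_scatter(X, y01, m0, m1)
    p = X.shape[1]
    S = S + _ridge_if_needed(S, p) * np.eye(p)
    cov = S / (n - 2)
    w = np.linalg.solve(cov, m1 - m0)
    b = float(-0.5 * (m0 + m1) @ w + np.log(prior / (1 - prior)))
    return LinearDiscriminant(classes=classes, means=np.stack([m0, m1]),
                              cov=cov, w=w, b=b, prior=prior)


def loo_lda_models(F: np.ndarray, y01: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Leave-one-out LDA: discriminant (w_i, b_i) fit without sample i, for all i.

    Exact rank-one downdate of the pooled scatter (Sherman-Morrison), so the
    result equals refitting from scratch per fold at O(M P^2) total cost.
    """
    F = np.asarray(F, dtype=float)
    y01 = np.asarray(y01)
    M, P = F.shape
    n1 = int(y01.sum())
    n0 = M - n1
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least two samples")
    m0 = F[y01 == 0].mean(axis=0)
    m1 = F[y01 == 1].mean(axis=0)
    S, D = _pooled_scatter(F, y01, m0, m1)
    lam = _ridge_if_needed(S, P)
    S = S + lam * np.eye(P)
    A = np.linalg.inv(S)
    delta = m1 - m0

    nk = np.where(y01 == 1, n1, n0)
    c = nk / (nk - 1.0)
    s_sign = np.where(y01 == 1, 1.0, -1.0)
    AD = D @ A  # (M, P); A symmetric
    dAd = np.einsum("ij,ij->i", D, AD)
    denom = 1.0 - c * dAd
    # delta_i = delta - s_i d_i/(nk-1);  A delta_i:
    Adelta = A @ delta
    Adelta_i = Adelta[None, :] - (s_sign / (nk - 1.0))[:, None] * AD
    dot = np.einsum("ij,j->i", D, Adelta) - (s_sign / (nk - 1.0)) * dAd
    Aprime_delta = Adelta_i + (c * dot / denom)[:, None] * AD
    W = (M - 3.0) * Aprime_delta  # cov_fold = S_fold/(M-3)
    # mean-sum after removal: (m0+m1) - d_i/(nk-1)
    msum = (m0 + m1)[None, :] - D / (nk - 1.0)[:, None]
    b = -0.5 * np.einsum("ij,ij->i", msum, W)
    return W, b


def _loo_lda_models_naive(F, y01):
    """Per-fold refit from scratch; oracle for the downdate implementation."""
    F = np.asarray(F, dtype=float)
    M, P = F.shape
    m0 = F[y01 == 0].mean(axis=0)
    m1 = F[y01 == 1].mean(axis=0)
    S_full, _ = _pooled_scatter(F, y01, m0, m1)
    lam = _ridge_if_needed(S_full, P)
    W = np.empty((M, P))
    b = np.empty(M)
    for i in range(M):
        keep = np.ones(M, bool)
        keep[i] = False
        Xf, yf = F[keep], y01[keep]
        mm0 = Xf[yf == 0].mean(axis=0)
        mm1 = Xf[yf == 1].mean(axis=0)
        S, _ = _pooled_scatter(Xf, yf, mm0, mm1)
        cov = (S + lam * np.eye(P)) / (M - 3.0)
        W[i] = np.linalg.solve(cov, mm1 - mm0)
        b[i] = -0.5 * (mm0 + mm1) @ W[i]
    return W, b


def loo_true_label_posterior(F, y01, models=loo_lda_models) -> np.ndarray:
    """Posterior assigned to each held-out sample's true class under LOOCV."""
    W, b = models(F, y01)
    s = np.einsum("ij,ij->i", F, W) + b
    p1 = expit(s)
    return np.where(y01 == 1, p1, 1.0 - p1)


# ---------------------------------------------------------------------------
# sliding-window decoding


def _window_operator(bin_centers: np.ndarray, bin_ms: float, decode_bin_ms: float,
                     step_ms: float) -> Tuple[np.ndarray, np.ndarray]:
    """Averaging operator (T x W) from raw bins to sliding decode windows.

    Windows extending outside the binned range are dropped.
    """
    half = decode_bin_ms / 2000.0
    step = step_ms / 1000.0
    lo = bin_centers[0] - bin_ms / 2000.0
    hi = bin_centers[-1] + bin_ms / 2000.0
    centers = np.arange(np.ceil((lo + half) / step) * step, hi - half + 1e-9, step)
    ops = np.zeros((len(bin_centers), len(centers)))
    for wi, c in enumerate(centers):
        inside = (bin_centers >= c - half - 1e-9) & (bin_centers < c + half - 1e-9)
        ops[inside, wi] = 1.0 / inside.sum()
    return ops, centers


@dataclass
class DecodingResult:
    """Posterior-probability decoding output (diagonal or cross-temporal)."""

    kind: str
    bin_centers: np.ndarray  # test-bin centers
    posteriors: np.ndarray  # diagonal: (R, M, W); cross: (R, M, W_train, W_test)
    labels: np.ndarray  # (M,) per pseudo-trial (class order is fixed)
    train_bin_centers: Optional[np.ndarray] = None
    train_window: Optional[Tuple[float, float]] = None
    meta: Dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def mean_posterior(self) -> np.ndarray:
        return self.posteriors.mean(axis=(0, 1))

    @property
    def sem(self) -> np.ndarray:
        """SEM across pseudo-trials of the resample-averaged posterior."""
        per_trial = self.posteriors.mean(axis=0)
        return per_trial.std(axis=0, ddof=1) / np.sqrt(per_trial.shape[0])


def _prepare_ensemble(tensor, labels, n_per_class, rng, shuffle, pca_mode, var_threshold,
                      decode_bin_ms, step_ms):
    ens = build_pseudo_population(tensor, labels, n_per_class=n_per_class, seed=rng)
    y = ens.values
    ops, centers = _window_operator(tensor.bin_centers, tensor.bin_ms,
                                    decode_bin_ms, step_ms)
    win = np.einsum("mtn,tw->mwn", y, ops)
    ens_w = PseudoEnsemble(values=win, labels=ens.labels.copy(), bin_centers=centers,
                           neuron_ids=ens.neuron_ids)
    if shuffle:
        rng.shuffle(ens_w.labels)
    pca_reduce(ens_w, mode=pca_mode, var_threshold=var_threshold)
    return ens_w


def decode_diagonal(tensor: AlignedRateTensor, labels, n_per_class: int = 100,
                    decode_bin_ms: float = 25.0, step_ms: float = 10.0,
                    n_resample: int = 200, var_threshold: float = 0.70,
                    pca_mode: str = "per_bin", shuffle_labels: bool = False,
                    seed=None) -> DecodingResult:
    """Train and test the discriminant at the same time bin (sliding window).

    Repeats leave-one-out cross-validation over ``n_resample`` independently
    sampled pseudo-ensembles; reports the mean posterior assigned to the true
    cue side per decode bin.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    all_post = []
    ens_labels = None
    for _ in range(n_resample):
        ens = _prepare_ensemble(tensor, labels, n_per_class, rng, shuffle_labels,
                                pca_mode, var_threshold, decode_bin_ms, step_ms)
        y01 = (ens.labels == np.unique(ens.labels)[1]).astype(int)
        Wn = len(ens.bin_centers)
        post = np.empty((len(y01), Wn))
        for t in range(Wn):
            F = ens.reduced[t] if ens.pca_mode == "per_bin" else ens.reduced[:, t, :]
            post[:, t] = loo_true_label_posterior(F, y01)
        all_post.append(post)
        ens_labels = ens.labels
    posteriors = np.stack(all_post)
    return DecodingResult(kind="diagonal", bin_centers=ens.bin_centers,
                          posteriors=posteriors, labels=ens_labels,
                          meta=dict(n_per_class=n_per_class, n_resample=n_resample,
                                    decode_bin_ms=decode_bin_ms, step_ms=step_ms,
                                    var_threshold=var_threshold, pca_mode=pca_mode,
                                    shuffle=shuffle_labels, alignment=tensor.alignment))


def decode_cross_temporal(tensor: AlignedRateTensor, labels, train_spec="all",
                          n_per_class: int = 100, decode_bin_ms: float = 25.0,
                          step_ms: float = 10.0, n_resample: int = 20,
                          var_threshold: float = 0.70, shuffle_labels: bool = False,
                          seed=None) -> DecodingResult:
    """Train at one time (bin or pre-stimulus window), test at all times.

    All bins share one joint-PCA subspace.  ``train_spec`` is "all" (full
    train x test matrix), or ``("window", (lo, hi))`` to train on features
    averaged over a window, e.g. 50-200 ms before stimulus onset.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    window_mode = isinstance(train_spec, tuple)
    all_post = []
    ens_labels = None
    for _ in range(n_resample):
        ens = _prepare_ensemble(tensor, labels, n_per_class, rng, shuffle_labels,
                                "joint", var_threshold, decode_bin_ms, step_ms)
        y01 = (ens.labels == np.unique(ens.labels)[1]).astype(int)
        R = ens.reduced  # (M, W, Q)
        Wn = R.shape[1]
        if window_mode:
            lo, hi = train_spec[1]
            mask = (ens.bin_centers >= lo) & (ens.bin_centers < hi)
            if not mask.any():
                raise ValueError("train window contains no decode bins")
            train_feats = [R[:, mask, :].mean(axis=1)]
        else:
            train_feats = [R[:, t, :] for t in range(Wn)]
        post = np.empty((len(y01), len(train_feats), Wn))
        sign = np.where(y01 == 1, 1.0, -1.0)
        for ti, F in enumerate(train_feats):
            Wmat, b = loo_lda_models(F, y01)
            scores = np.einsum("mp,mwp->mw", Wmat, R) + b[:, None]
            p1 = expit(scores)
            post[:, ti, :] = np.where(y01[:, None] == 1, p1, 1.0 - p1)
        all_post.append(post)
        ens_labels = ens.labels
    posteriors = np.stack(all_post)
    meta = dict(n_per_class=n_per_class, n_resample=n_resample, decode_bin_ms=decode_bin_ms,
                step_ms=step_ms, var_threshold=var_threshold, pca_mode="joint",
                shuffle=shuffle_labels, alignment=tensor.alignment, train_spec=str(train_spec))
    if window_mode:
        return DecodingResult(kind="cross", bin_centers=ens.bin_centers,
                              posteriors=posteriors[:, :, 0, :], labels=ens_labels,
                              train_window=train_spec[1], meta=meta)
    return DecodingResult(kind="cross", bin_centers=ens.bin_centers, posteriors=posteriors,
                          labels=ens_labels, train_bin_centers=ens.bin_centers, meta=meta)


# ---------------------------------------------------------------------------
# significance


def bh_fdr(pvals, alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    reject = np.zeros(p.shape, bool)
    adj = np.full(p.shape, np.nan)
    if ok.any():
        rej, padj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        reject[ok] = rej
        adj[ok] = padj
    return reject, adj


@dataclass
class SignificanceMask:
    bin_centers: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    above: np.ndarray  # significantly above the null
    below: np.ndarray  # significantly below (sign-reversed representation)
    alpha: float


def shuffle_significance(result: DecodingResult, null_result: DecodingResult,
                         alpha: float = 0.01) -> SignificanceMask:
    """Per-bin two-tailed paired t-test of true vs label-shuffled posteriors.

    Pairs are (resample, pseudo-trial) posterior pairs; Benjamini-Hochberg
    FDR across bins; above- and below-null bins are flagged separately.
    """
    a = result.posteriors.reshape(-1, result.posteriors.shape[-1])
    b = null_result.posteriors.reshape(-1, null_result.posteriors.shape[-1])
    if a.shape != b.shape:
        raise ValueError("result and null must share geometry")
    diff = a - b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance bins yield NaN p
        tstat, p = stats.ttest_rel(a, b, axis=0)
    p = np.where(np.all(diff == 0, axis=0), 1.0, p)
    reject, padj = bh_fdr(p, alpha=alpha)
    mean_diff = diff.mean(axis=0)
    return SignificanceMask(bin_centers=result.bin_centers, p=p, p_fdr=padj,
                            above=reject & (mean_diff > 0), below=reject & (mean_diff < 0),
                            alpha=alpha)


# ---------------------------------------------------------------------------
# reaction-time split


@dataclass
class RtSplitResult:
    fast: DecodingResult
    slow: DecodingResult
    comparison: SignificanceMask
    degenerate: bool = False


def rt_split_decoding(tensor: AlignedRateTensor, labels, rts, n_per_class: int,
                      decode_bin_ms: float = 25.0, step_ms: float = 10.0,
                      n_resample: int = 20, var_threshold: float = 0.70,
                      alpha: float = 0.01, seed=None) -> RtSplitResult:
    """Decode fast- and slow-RT halves separately (per-neuron median split).

    Trials at the median RT go to the slow half.  Trials lacking an RT are
    excluded.  A degenerate split (all RTs identical) is flagged.
    """
    rng = np.random.default_rng(seed)
    rts = np.asarray(rts, dtype=float)
    has_rt = np.isfinite(rts)
    med = np.median(rts[has_rt])
    fast_mask = has_rt & (rts < med)
    slow_mask = has_rt & (rts >= med)
    degenerate = fast_mask.sum() == 0 or slow_mask.sum() == 0

    def subset(mask):
        return AlignedRateTensor(values=tensor.values[mask], bin_centers=tensor.bin_centers,
                                 alignment=tensor.alignment, trial_ids=tensor.trial_ids[mask],
                                 neuron_ids=tensor.neuron_ids, bin_ms=tensor.bin_ms,
                                 zscored=tensor.zscored, smoothed=tensor.smoothed), \
               np.asarray(labels)[mask]

    if degenerate:
        raise ValueError("degenerate RT split: all reaction times identical")
    t_fast, l_fast = subset(fast_mask)
    t_slow, l_slow = subset(slow_mask)
    kwargs = dict(n_per_class=n_per_class, decode_bin_ms=decode_bin_ms, step_ms=step_ms,
                  n_resample=n_resample, var_threshold=var_threshold)
    res_fast = decode_diagonal(t_fast, l_fast, seed=rng, **kwargs)
    res_slow = decode_diagonal(t_slow, l_slow, seed=rng, **kwargs)
    comp = shuffle_significance(res_fast, res_slow, alpha=alpha)
    return RtSplitResult(fast=res_fast, slow=res_slow, comparison=comp)
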