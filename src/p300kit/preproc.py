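"""Continuous-EEG preprocessing: filtering, ICA ocular cleanup, epoching,
artifact rejection and condition balancing.

The chain mirrors the standard ERP workflow: 0.1 Hz zero-phase Butterworth
high-pass and 50 Hz notch on the continuous data, extended-Infomax ICA with
automatic EOG-correlation flagging of ocular components, 0.5-30 Hz
band-pass, segmentation into 1000 ms stimulus-locked epochs (200 ms
pre-stimulus baseline), fully automatic epoch rejection on four amplitude
criteria, and random equalization of target/non-target epoch counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import ContinuousRecording

logger = logging.getLogger("p300kit")

__all__ = [
    "EpochSet",
    "RejectionCriteria",
    "UnmixingModel",
    "PreprocSettings",
    "butterworth_zero_phase",
    "notch_filter",
    "fit_extended_infomax",
    "identify_ocular_components",
    "remove_components",
    "epoch_data",
    "baseline_correct",
    "reject_artifacts",
    "equalize_epoch_counts",
    "check_min_epochs",
    "preprocess_subject",
]


@dataclass
class EpochSet:
    """Stimulus-locked epochs: tensor epochs x channels x time, in µV."""

    data: np.ndarray
    time_ms: np.ndarray  # relative to stimulus onset
    condition: np.ndarray  # per-epoch label ("target"/"nontarget")
    retained: np.ndarray  # per-epoch bool mask
    channel_labels: list[str]
    sampling_rate: float
    subject_id: str = ""

    def __post_init__(self):
        n_ep, n_ch, n_t = self.data.shape
        if len(self.time_ms) != n_t:
            raise ValueError("time axis length mismatch")
        if len(self.condition) != n_ep or len(self.retained) != n_ep:
            raise ValueError("per-epoch arrays must match epoch count")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel label count mismatch")

    def retained_count(self, condition: str | None = None) -> int:
        mask = self.retained
        if condition is not None:
            mask = mask & (self.condition == condition)
        return int(mask.sum())

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            condition=self.condition.copy(),
            retained=self.retained.copy(),
        )


@dataclass
class RejectionCriteria:
    """Automatic epoch-rejection thresholds.

    max_abs: largest allowed absolute amplitude anywhere in the epoch (µV).
    max_step: largest allowed adjacent-sample voltage step (µV/ms).
    max_range: largest allowed max-min difference in any 200 ms window (µV).
    min_activity: smallest allowed max-min difference in any 100 ms window
    (µV); flatlined channels fail this.
    """

    max_abs: float = 70.0
    max_step: float = 50.0
    max_range: float = 50.0
    min_activity: float = 0.5
    range_window_ms: float = 200.0
    activity_window_ms: float = 100.0

    def __post_init__(self):
        for name in ("max_abs", "max_step", "max_range", "min_activity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class UnmixingModel:
    """Linear decomposition from extended-Infomax ICA.

    ``unmixing @ (x - mean)`` gives component activations; ``mixing`` maps
    activations back to channels.  ``component_scores`` holds per-component
    EOG correlations once :func:`identify_ocular_components` has run.
    """

    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    mean: np.ndarray  # per-channel mean removed before fitting
    channel_labels: list[str]
    converged: bool
    n_iter: int
    component_scores: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def activations(self, data: np.ndarray) -> np.ndarray:
        dt = data.dtype if np.issubdtype(data.dtype, np.floating) else np.float64
        return self.unmixing.astype(dt) @ (data - self.mean[:, None].astype(dt))


# ---------------------------------------------------------------------------
# Filters


def _as_recording(rec, data):
    if isinstance(rec, ContinuousRecording):
        return rec.copy_with(data)
    return data


def _rec_data(rec) -> tuple[np.ndarray, float]:
    if isinstance(rec, ContinuousRecording):
        return rec.data, rec.sampling_rate
    raise TypeError("expected a ContinuousRecording")


def butterworth_zero_phase(
    rec: ContinuousRecording,
    kind: str,
    edges: float | tuple[float, float],
    order: int = 4,
) -> ContinuousRecording:
    """Forward-backward (zero-phase) Butterworth filter on all channels.

    *kind* is ``"highpass"`` or ``"bandpass"``; *edges* is the cutoff in Hz
    (a pair for band-pass).  The effective magnitude order is 2x *order*
    because of the two passes; phase is identically zero, so waveform peaks
    do not shift.  Events are untouched.
    """
    data, fs = _rec_data(rec)
    nyq = fs / 2.0
    if order < 1:
        raise ValueError("order must be >= 1")
    if kind == "highpass":
        edges_list = [float(np.atleast_1d(edges)[0])]
        btype = "highpass"
    elif kind == "bandpass":
        edges_list = list(np.atleast_1d(edges))
        if len(edges_list) != 2:
            raise ValueError("bandpass needs two edges")
        btype = "bandpass"
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    if any(e >= nyq for e in edges_list) or any(e <= 0 for e in edges_list):
        raise ValueError(f"filter edges {edges_list} must lie in (0, {nyq}) Hz")
    wn = edges_list[0] if btype == "highpass" else edges_list
    sos = signal.butter(order, wn, btype=btype, fs=fs, output="sos")
    # default sosfiltfilt padding; fail clearly on too-short signals
    padlen = 3 * (2 * sos.shape[0] + 1)
    if data.shape[1] <= padlen * 3:
        raise ValueError(
            f"signal of {data.shape[1]} samples too short for zero-phase "
            f"filtering (needs > {padlen * 3})"
        )
    out = signal.sosfiltfilt(sos, data, axis=1)
    return _as_recording(rec, out)


def notch_filter(
    rec: ContinuousRecording, freq: float = 50.0, quality: float = 30.0
) -> ContinuousRecording:
    """Zero-phase second-order IIR notch (power-line removal)."""
    data, fs = _rec_data(rec)
    if freq >= fs / 2:
        raise ValueError(f"notch frequency {freq} must be below Nyquist {fs / 2}")
    b, a = signal.iirnotch(freq, quality, fs=fs)
    out = signal.filtfilt(b, a, data, axis=1)
    return _as_recording(rec, out)


# ---------------------------------------------------------------------------
# Extended-Infomax ICA


def fit_extended_infomax(
    data: np.ndarray,
    seed: int = 0,
    channel_labels: list[str] | None = None,
    l_rate: float | None = None,
    block: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    anneal: float = 0.98,
) -> UnmixingModel:
    """Fit extended-Infomax ICA on *data* (channels x samples).

    Natural-gradient learning on symmetric-whitened data, with per-component
    sub-/super-Gaussian switching by the sign of the activation kurtosis.
    Weight updates run over seeded-shuffled sample blocks; the learning rate
    anneals each pass and halves on divergence.  Deterministic given *seed*.
    Non-convergence sets ``converged=False`` on the model (no exception);
    rank-deficient data raises.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("data must be channels x samples with >= 2 channels")
    n_ch, n = X.shape
    if n < 20 * n_ch * n_ch:
        raise ValueError("too few samples for a stable ICA fit")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]

    cov = (Xc @ Xc.T) / n
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-10 * evals.max():
        raise ValueError(
            "rank-deficient data (duplicated or linearly dependent channel); "
            "remove the offending channel before ICA"
        )
    sphere = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    Xw = sphere @ Xc

    rng = np.random.default_rng(seed)
    W = np.eye(n_ch)
    I = np.eye(n_ch)
    block = block or min(n, 512)
    lrate = l_rate if l_rate is not None else 0.01 / math.log(n_ch + 2.0)
    signs = np.ones(n_ch)  # +1 super-Gaussian, -1 sub-Gaussian
    kurt_sel = slice(0, min(n, 10_000))

    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        order = rng.permutation(n)
        W_old = W.copy()
        blew_up = False
        # refresh source-type signs from current activations
        u_all = W @ Xw[:, kurt_sel]
        m2 = np.mean(u_all**2, axis=1)
        m4 = np.mean(u_all**4, axis=1)
        kurt = m4 / np.maximum(m2**2, 1e-30) - 3.0
        signs = np.where(kurt >= 0, 1.0, -1.0)
        K = signs[:, None]

        for start in range(0, n - block + 1, block):
            xb = Xw[:, order[start : start + block]]
            u = W @ xb
            y = np.tanh(u)
            grad = I - (K * y) @ u.T / block - (u @ u.T) / block
            W = W + lrate * grad @ W
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                blew_up = True
                break
        if blew_up:
            lrate *= 0.5
            W = np.eye(n_ch)
            logger.debug("infomax blow-up; restarting with lrate=%g", lrate)
            continue
        wchange = float(np.sum((W - W_old) ** 2))
        lrate *= anneal
        if wchange < tol:
            converged = True
            break
    if not converged:
        logger.warning("extended infomax did not converge in %d iterations", n_iter)

    unmixing = W @ sphere
    mixing = np.linalg.pinv(unmixing)
    labels = channel_labels or [f"ch{i}" for i in range(n_ch)]
    return UnmixingModel(unmixing, mixing, mean, list(labels), converged, n_iter)


def identify_ocular_components(
    model: UnmixingModel,
    data: np.ndarray,
    eog_trace: np.ndarray,
    threshold: float = 0.7,
) -> list[int]:
    """Flag components whose activation correlates with the EOG trace.

    Returns indices of components with ``|corr| >= threshold``; fills
    ``model.component_scores``.  A zero-variance EOG trace flags nothing.
    """
    acts = model.activations(np.asarray(data, dtype=float))
    eog = np.asarray(eog_trace, dtype=float)
    if eog.shape[0] != acts.shape[1]:
        raise ValueError("EOG trace not aligned with the data used for fitting")
    scores = np.zeros(model.n_components)
    if eog.std() > 0:
        eog_z = (eog - eog.mean()) / eog.std()
        for k in range(model.n_components):
            a = acts[k]
            sd = a.std()
            if sd > 0:
                scores[k] = float(np.mean((a - a.mean()) / sd * eog_z))
    model.component_scores = scores
    return [k for k in range(model.n_components) if abs(scores[k]) >= threshold]


def remove_components(
    rec: ContinuousRecording,
    model: UnmixingModel,
    flagged: list[int],
) -> ContinuousRecording:
    """Reconstruct the recording with the flagged components zeroed.

    Only the channels the model was fitted on are modified; any others
    (e.g. EOG) pass through unchanged.  With no flags the reconstruction
    equals the input to numerical precision.
    """
    out = rec.data.copy()
    rows = [rec.channel_labels.index(lab) for lab in model.channel_labels]
    sub = out[rows]
    acts = model.activations(sub)
    keep = [k for k in range(model.n_components) if k not in set(flagged)]
    dt = acts.dtype
    clean = model.mixing[:, keep].astype(dt) @ acts[keep] + model.mean[
        :, None
    ].astype(dt)
    out[rows] = clean
    return rec.copy_with(out)


# ---------------------------------------------------------------------------
# Epoching


def epoch_data(
    rec: ContinuousRecording,
    window_ms: tuple[float, float] = (-200.0, 800.0),
    subject_id: str = "",
) -> EpochSet:
    """Cut one epoch per stimulus event, half-open window [pre, post) ms.

    At 500 Hz and the default window this yields 500 samples spanning the
    1000 ms epoch including the 200 ms pre-stimulus period.  Events too
    close to the recording edge are dropped with a logged warning.
    """
    fs = rec.sampling_rate
    pre = int(round(-window_ms[0] / 1000.0 * fs))
    post = int(round(window_ms[1] / 1000.0 * fs))
    n_t = pre + post
    time_ms = (np.arange(n_t) - pre) * 1000.0 / fs

    epochs, conds = [], []
    n_dropped = 0
    for ev in rec.events:
        lo, hi = ev.sample_index - pre, ev.sample_index + post
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(rec.data[:, lo:hi])
        conds.append(ev.condition)
    if n_dropped:
        logger.warning(
            "dropped %d event(s) without full epoch support near recording edges",
            n_dropped,
        )
    data = (
        np.stack(epochs) if epochs else np.empty((0, len(rec.channel_labels), n_t))
    )
    return EpochSet(
        data=data,
        time_ms=time_ms,
        condition=np.array(conds, dtype=object),
        retained=np.ones(len(conds), dtype=bool),
        channel_labels=list(rec.channel_labels),
        sampling_rate=fs,
        subject_id=subject_id,
    )


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract each epoch/channel's mean over the pre-stimulus interval."""
    mask = (epochs.time_ms >= baseline_ms[0]) & (epochs.time_ms < baseline_ms[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def _window_ranges(x: np.ndarray, width: int) -> np.ndarray:
    """Max-min over every full sliding window of *width* samples.

    x: ... x time -> ... x (time - width + 1).  Uses O(n) running
    max/min filters; only fully supported windows are returned.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    n = x.shape[-1]
    if width > n:
        raise ValueError("window wider than the epoch")
    hi = maximum_filter1d(x, size=width, axis=-1, mode="nearest")
    lo = minimum_filter1d(x, size=width, axis=-1, mode="nearest")
    # centered filter at index i covers [i - width//2, i + width-1 - width//2];
    # slice the positions whose window lies fully inside the epoch
    start = width // 2
    return (hi - lo)[..., start : n - width + 1 + start]


def reject_artifacts(
    epochs: EpochSet,
    criteria: RejectionCriteria | None = None,
    eeg_channels: tuple[str, ...] = ("Fz", "Cz", "Pz"),
) -> tuple[EpochSet, dict[str, int]]:
    """Apply the four automatic rejection criteria; update the mask.

    An epoch is rejected if ANY tested channel violates ANY criterion:
    (a) absolute amplitude above ``max_abs``; (b) adjacent-sample step above
    ``max_step`` µV/ms; (c) any sliding 200 ms window with range above
    ``max_range``; (d) any sliding 100 ms window with range below
    ``min_activity`` (near-flat signal).  Channels outside *eeg_channels*
    (the EOG) are not tested.  Returns the updated set and per-criterion
    violation counts among previously retained epochs.
    """
    criteria = criteria or RejectionCriteria()
    rows = [
        epochs.channel_labels.index(ch)
        for ch in eeg_channels
        if ch in epochs.channel_labels
    ]
    if not rows:
        raise ValueError("no EEG channels to test")
    X = epochs.data[:, rows, :]  # epochs x eeg_ch x time
    dt_ms = 1000.0 / epochs.sampling_rate
    n_range = int(round(criteria.range_window_ms / dt_ms))
    n_act = int(round(criteria.activity_window_ms / dt_ms))

    viol_a = (np.abs(X) > criteria.max_abs).any(axis=(1, 2))
    steps = np.abs(np.diff(X, axis=2)) / dt_ms
    viol_b = (steps > criteria.max_step).any(axis=(1, 2))
    viol_c = (_window_ranges(X, n_range) > criteria.max_range).any(axis=(1, 2))
    viol_d = (_window_ranges(X, n_act) < criteria.min_activity).any(axis=(1, 2))

    prev = epochs.retained
    counts = {
        "max_abs": int((viol_a & prev).sum()),
        "max_step": int((viol_b & prev).sum()),
        "max_range": int((viol_c & prev).sum()),
        "min_activity": int((viol_d & prev).sum()),
    }
    out = epochs.copy()
    out.retained = prev & ~(viol_a | viol_b | viol_c | viol_d)
    return out, counts


def equalize_epoch_counts(
    epochs: EpochSet, seed: int | np.random.Generator = 0
) -> EpochSet:
    """Randomly subsample the richer condition to match the poorer one.

    Seeded, without replacement; never enlarges a condition.  Raises if a
    condition has no retained epochs.
    """
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    conds = sorted(set(epochs.condition.tolist()))
    idx_by_cond = {
        c: np.flatnonzero(epochs.retained & (epochs.condition == c)) for c in conds
    }
    for c, idx in idx_by_cond.items():
        if idx.size == 0:
            raise ValueError(f"condition {c!r} has no retained epochs")
    n_min = min(idx.size for idx in idx_by_cond.values())
    for c, idx in idx_by_cond.items():
        if idx.size > n_min:
            drop = rng.choice(idx, size=idx.size - n_min, replace=False)
            out.retained[drop] = False
    return out


def check_min_epochs(epochs: EpochSet, minimum: int = 20) -> dict[str, bool]:
    """Per-condition flag: does the retained count reach the minimum?"""
    conds = sorted(set(epochs.condition.tolist()))
    return {c: epochs.retained_count(c) >= minimum for c in conds}


# ---------------------------------------------------------------------------
# Subject-level chain


@dataclass
class PreprocSettings:
    """Tunable knobs of the subject-level preprocessing chain."""

    hp_cutoff: float = 0.1
    hp_order: int = 2
    band: tuple[float, float] = (0.5, 30.0)
    band_order: int = 4
    notch_freq: float = 50.0
    notch_quality: float = 30.0
    run_ica: bool = True
    ica_threshold: float = 0.7
    ica_max_samples: int = 10_000
    ica_tol: float = 1e-6
    # larger blocks / faster annealing than the library defaults: ocular
    # flagging needs far less precision than full source recovery
    ica_block: int = 1024
    ica_lrate: float = 0.02
    ica_anneal: float = 0.95
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    eeg_channels: tuple[str, ...] = ("Fz", "Cz", "Pz")
    eog_channel: str = "EOG"
    min_epochs: int = 20


def preprocess_subject(
    rec: ContinuousRecording,
    settings: PreprocSettings | None = None,
    seed: int = 0,
    subject_id: str = "",
) -> tuple[EpochSet, dict]:
    """Run the full continuous-to-epochs chain on one recording.

    Order: 0.1 Hz high-pass -> 50 Hz notch -> ICA ocular cleanup (fitted on
    a 0.5-30 Hz filtered, subsampled copy of the EEG channels; components
    flagged by |EOG correlation| >= threshold) -> 0.5-30 Hz band-pass ->
    epoch -> baseline-correct -> automatic rejection -> equalize counts.
    Returns the epoch set and a report dict (rejection counts, retained
    counts, ICA details, min-epoch flags).
    """
    settings = settings or PreprocSettings()
    report: dict = {}
    x = butterworth_zero_phase(rec, "highpass", settings.hp_cutoff, settings.hp_order)
    x = notch_filter(x, settings.notch_freq, settings.notch_quality)

    if settings.run_ica:
        xf = butterworth_zero_phase(x, "bandpass", settings.band, settings.band_order)
        # EOG is included in the decomposition: with a sparse montage the
        # blink needs its dominant direction in the fit to separate cleanly.
        fit_channels = [*settings.eeg_channels, settings.eog_channel]
        fit_rows = [xf.channel_labels.index(ch) for ch in fit_channels]
        step = max(1, xf.n_samples // settings.ica_max_samples)
        fit_data = xf.data[fit_rows, ::step]
        model = fit_extended_infomax(
            fit_data,
            seed=seed,
            channel_labels=fit_channels,
            tol=settings.ica_tol,
            block=settings.ica_block,
            l_rate=settings.ica_lrate,
            anneal=settings.ica_anneal,
        )
        eog = xf.channel(settings.eog_channel)[::step]
        flagged = identify_ocular_components(
            model, fit_data, eog, settings.ica_threshold
        )
        x = remove_components(x, model, flagged)
        report["ica"] = {
            "flagged_components": flagged,
            "component_eog_corr": model.component_scores.tolist(),
            "converged": model.converged,
            "n_iter": model.n_iter,
        }

    x = butterworth_zero_phase(x, "bandpass", settings.band, settings.band_order)
    epochs = epoch_data(x, settings.epoch_window_ms, subject_id=subject_id)
    epochs = baseline_correct(epochs, settings.baseline_ms)
    epochs, counts = reject_artifacts(epochs, settings.rejection, settings.eeg_channels)
    report["rejection_counts"] = counts
    report["retained_before_equalization"] = {
        c: epochs.retained_count(c) for c in ("target", "nontarget")
    }
    epochs = equalize_epoch_counts(epochs, seed=seed)
    report["retained"] = {c: epochs.retained_count(c) for c in ("target", "nontarget")}
    report["min_epochs_ok"] = check_min_epochs(epochs, settings.min_epochs)
    return epochs, report
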