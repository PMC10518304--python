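"""Synthetic visual-oddball EEG cohorts with known ground truth.

The generator stands in for unavailable clinical recordings.  A session is
120 stimuli (target probability 0.33) with 3-7 s uniform inter-stimulus
intervals at 500 Hz on midline channels Fz/Cz/Pz plus an EOG channel.  Each
subject carries latent P300 latency/amplitude factors drawn from
group-level normal distributions whose default means/sds are the published
group summary cells for HC and MCI cohorts (per channel and condition), and
neuropsychological scores drawn jointly with those factors through a
Gaussian-copula one-factor model so that score/ERP couplings are
configurable.  Rendering adds 1/f background noise, a 10 Hz alpha
component, and stereotyped blink transients propagated from EOG to the EEG
channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortTable, ContinuousRecording, DEFAULT_CODE_MAP, EventMarker

__all__ = [
    "SessionConfig",
    "SubjectERPParams",
    "GroupModel",
    "TABLE_PEAKS",
    "TABLE_NEUROPSYCH",
    "generate_event_sequence",
    "render_subject_recording",
    "simulate_cohort",
    "simulate_cohort_params",
    "check_count_accuracy",
]

GROUPS = ("HC", "MCI")
CONDITIONS = ("target", "nontarget")
EEG_CHANNELS = ("Fz", "Cz", "Pz")

#: Group-level P300 peak calibration: group -> (condition, channel) ->
#: (latency mean ms, latency sd, amplitude mean uV, amplitude sd).
TABLE_PEAKS: dict[str, dict[tuple[str, str], tuple[float, float, float, float]]] = {
    "HC": {
        ("target", "Fz"): (413.789, 29.081, 5.854, 2.121),
        ("target", "Cz"): (419.053, 30.312, 5.757, 1.919),
        ("target", "Pz"): (419.053, 43.703, 5.438, 1.906),
        ("nontarget", "Fz"): (443.474, 57.418, 4.503, 1.722),
        ("nontarget", "Cz"): (449.053, 72.631, 4.811, 1.600),
        ("nontarget", "Pz"): (437.684, 63.394, 4.020, 1.478),
    },
    "MCI": {
        ("target", "Fz"): (443.619, 56.465, 6.092, 3.005),
        ("target", "Cz"): (455.048, 64.005, 5.386, 2.804),
        ("target", "Pz"): (452.381, 60.417, 4.745, 2.486),
        ("nontarget", "Fz"): (434.381, 59.979, 4.581, 2.339),
        ("nontarget", "Cz"): (422.762, 68.210, 4.086, 1.882),
        ("nontarget", "Pz"): (410.762, 77.801, 3.602, 1.776),
    },
}

#: Neuropsychological marginals: test -> group -> (mean, sd).
TABLE_NEUROPSYCH: dict[str, dict[str, tuple[float, float]]] = {
    "MMSE": {"HC": (29.31, 0.82), "MCI": (25.85, 3.30)},
    "GDS": {"HC": (6.00, 3.71), "MCI": (8.20, 5.31)},
    "OVMPT-T": {"HC": (109.25, 13.92), "MCI": (68.65, 18.75)},
    "OVMPT-IR": {"HC": (4.50, 1.43), "MCI": (3.65, 1.66)},
    "OVMPT-FR": {"HC": (12.65, 1.35), "MCI": (5.50, 3.62)},
    "OVMPT-TR": {"HC": (15.00, 0.00), "MCI": (13.35, 1.46)},
    "DS-Forward": {"HC": (5.10, 0.91), "MCI": (4.95, 0.97)},
    "DS-Backward": {"HC": (3.90, 0.97), "MCI": (3.37, 0.68)},
    "Stroop-Int": {"HC": (47.75, 21.43), "MCI": (68.06, 38.71)},
    "Animal": {"HC": (22.55, 4.03), "MCI": (16.55, 2.35)},
    "BNT-15": {"HC": (14.92, 0.28), "MCI": (13.94, 1.70)},
}

#: Demographic marginals (same joint machinery, no ERP coupling by default).
TABLE_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"HC": (71.00, 5.96), "MCI": (70.65, 7.08)},
    "education": {"HC": (10.30, 4.11), "MCI": (10.20, 4.99)},
}

# Score post-processing: test -> (decimals, lower cap, upper cap).
_SCORE_ROUNDING: dict[str, tuple[int, float, float | None]] = {
    "MMSE": (0, 0, 30),
    "GDS": (0, 0, 30),
    "OVMPT-T": (0, 0, 150),
    "OVMPT-IR": (0, 0, 15),
    "OVMPT-FR": (0, 0, 15),
    "OVMPT-TR": (0, 0, 15),
    "DS-Forward": (0, 0, 9),
    "DS-Backward": (0, 0, 8),
    "Stroop-Int": (1, 0, None),
    "Animal": (0, 0, None),
    "BNT-15": (0, 0, 15),
}


@dataclass
class SessionConfig:
    """Stimulation-session layout of one oddball recording."""

    n_stimuli: int = 120
    p_target: float = 0.33
    isi_range: tuple[float, float] = (3.0, 7.0)
    stim_duration_ms: float = 1000.0
    sampling_rate: float = 500.0
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz", "EOG")
    eog_channel: str = "EOG"
    #: If True, each trial is target with probability p_target instead of a
    #: fixed round(n * p) target count.
    bernoulli_targets: bool = False

    def __post_init__(self):
        if not 0 < self.p_target < 1:
            raise ValueError("p_target must be in (0, 1)")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] <= 0:
            raise ValueError("isi_range must satisfy 0 < lo <= hi")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class SubjectERPParams:
    """Per-subject rendering parameters (the ground truth of one subject).

    ``latency``/``amplitude`` map (condition, channel) to the P300 bump
    center (ms post-stimulus) and peak height (µV).
    """

    latency: dict[tuple[str, str], float]
    amplitude: dict[tuple[str, str], float]
    p300_width_ms: float = 120.0  # FWHM of the Gaussian bump
    background_noise_sd: float = 4.0
    alpha_amplitude: float = 2.0  # 10 Hz sinusoid amplitude, µV
    blink_rate_per_min: float = 8.0
    blink_amplitude_eog: float = 150.0
    eog_propagation: dict[str, float] = field(
        default_factory=lambda: {"Fz": 0.30, "Cz": 0.15, "Pz": 0.06}
    )
    eog_noise_sd: float = 3.0
    line_noise_amplitude: float = 0.0  # optional 50 Hz sinusoid, µV

    def __post_init__(self):
        for key, lat in self.latency.items():
            if not 0 < lat:
                raise ValueError(f"latency must be positive for {key}")
        for key, amp in self.amplitude.items():
            if amp < 0:
                raise ValueError(f"amplitude must be >= 0 for {key}")
        if self.p300_width_ms <= 0:
            raise ValueError("p300_width_ms must be positive")


@dataclass
class GroupModel:
    """Cohort-level generative model for both groups.

    ``peaks`` and ``neuropsych`` default to the published HC/MCI group
    summary cells.  ``coupling`` maps a test name to its correlation with
    the latent (latency, amplitude) factors; the implied joint correlation
    matrix is the one-factor model
    ``score_i = c_i * L + d_i * A + sqrt(1 - c_i^2 - d_i^2) * eps_i``,
    which is positive semi-definite iff ``c_i^2 + d_i^2 <= 1`` per test.
    """

    n_subjects: dict[str, int] = field(default_factory=lambda: {"HC": 20, "MCI": 20})
    peaks: dict[str, dict[tuple[str, str], tuple[float, float, float, float]]] = field(
        default_factory=lambda: {g: dict(TABLE_PEAKS[g]) for g in GROUPS}
    )
    neuropsych: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {t: dict(v) for t, v in TABLE_NEUROPSYCH.items()}
    )
    demographics: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {t: dict(v) for t, v in TABLE_DEMOGRAPHICS.items()}
    )
    #: test -> (corr with latency factor, corr with amplitude factor)
    coupling: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "MMSE": (-0.25, 0.0),
            "OVMPT-T": (-0.35, 0.0),
            "OVMPT-IR": (-0.25, 0.0),
            "OVMPT-FR": (-0.25, 0.0),
            "OVMPT-TR": (0.0, 0.0),
            "DS-Forward": (-0.45, 0.0),
            "DS-Backward": (0.0, 0.45),
            "Stroop-Int": (0.30, -0.45),
            "Animal": (-0.30, 0.0),
            "BNT-15": (-0.35, 0.0),
            "GDS": (0.0, 0.0),
        }
    )
    #: Loading of each measured cell (channel x condition) on the subject's
    #: shared latent factor; the rest is cell-specific normal variation.
    cell_loading: float = 0.6
    #: Correlation between the latency and amplitude latent factors.
    factor_correlation: float = 0.0
    latency_bounds: tuple[float, float] = (250.0, 700.0)
    amplitude_floor: float = 0.5
    #: Behavioral count-report error: group -> (bias, sd) of the additive
    #: normal error before rounding.
    count_error: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (0.55, 1.61), "MCI": (-0.25, 2.29)}
    )
    #: If True, resample any simulated subject whose GDS exceeds 11
    #: (the study's depression exclusion rule).  Off by default because the
    #: published MCI GDS spread implies scores above 11 in the sample.
    enforce_gds_cutoff: bool = False
    render_defaults: SubjectERPParams | None = None

    def __post_init__(self):
        for test, (c, d) in self.coupling.items():
            if abs(c) > 1 or abs(d) > 1:
                raise ValueError(f"|coupling| must be <= 1 for test {test!r}")
            if c * c + d * d > 1.0 + 1e-12:
                raise ValueError(
                    f"infeasible coupling for test {test!r}: "
                    f"c^2 + d^2 = {c * c + d * d:.3f} > 1"
                )
        if not -1 <= self.factor_correlation <= 1:
            raise ValueError("factor_correlation must be in [-1, 1]")
        if not 0 <= self.cell_loading <= 1:
            raise ValueError("cell_loading must be in [0, 1]")
        for group in GROUPS:
            for cell, (lm, ls, am, asd) in self.peaks[group].items():
                if ls < 0 or asd < 0:
                    raise ValueError(f"negative sd in peaks[{group}][{cell}]")
            for test, per_group in self.neuropsych.items():
                if per_group[group][1] < 0:
                    raise ValueError(f"negative sd for test {test!r} in {group}")


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Child generator for one subject, stable under cohort-size changes."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,))
    )


def generate_event_sequence(
    cfg: SessionConfig, seed: int | np.random.Generator
) -> list[EventMarker]:
    """Draw one session's stimulus sequence.

    Exactly ``round(n_stimuli * p_target)`` targets (Bernoulli per trial if
    ``cfg.bernoulli_targets``) in seeded-shuffled order; onsets accumulate
    i.i.d. Uniform(isi_range) inter-stimulus intervals.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_stimuli
    if cfg.bernoulli_targets:
        is_target = rng.random(n) < cfg.p_target
    else:
        n_targets = round(n * cfg.p_target)
        is_target = np.zeros(n, dtype=bool)
        is_target[:n_targets] = True
        rng.shuffle(is_target)
    isis = rng.uniform(cfg.isi_range[0], cfg.isi_range[1], size=n)
    onsets = np.cumsum(isis)
    code_of = {v: k for k, v in DEFAULT_CODE_MAP.items()}
    events = []
    for onset, tgt in zip(onsets, is_target):
        cond = "target" if tgt else "nontarget"
        idx = int(round(onset * cfg.sampling_rate))
        events.append(EventMarker(idx, cond, code=code_of[cond]))
    return events


def _gaussian_bump(
    t_ms: np.ndarray, latency_ms: float, amplitude: float, width_fwhm_ms: float
) -> np.ndarray:
    sigma = width_fwhm_ms / 2.355
    return amplitude * np.exp(-0.5 * ((t_ms - latency_ms) / sigma) ** 2)


def _blink_waveform(fs: float) -> np.ndarray:
    """Unit-peak biphasic blink transient, ~300 ms."""
    t = np.arange(int(round(0.3 * fs))) * 1000.0 / fs
    w = np.exp(-0.5 * ((t - 110.0) / 38.0) ** 2) - 0.35 * np.exp(
        -0.5 * ((t - 215.0) / 55.0) ** 2
    )
    return w / np.max(w)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-power noise of length n, normalized to standard deviation sd.

    Synthesized directly in the frequency domain: complex Gaussian spectrum
    with amplitude proportional to f^-1/2 (power 1/f), one inverse FFT.
    """
    if sd == 0:
        return np.zeros(n)
    from scipy.fft import irfft, next_fast_len

    nfft = next_fast_len(n)
    nf = nfft // 2 + 1
    spec = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    freqs = np.fft.rfftfreq(nfft, d=1.0)
    with np.errstate(divide="ignore"):
        spec *= np.where(freqs > 0, freqs ** -0.5, 0.0)
    x = irfft(spec, nfft)[:n]
    return x * (sd / x.std())


def render_subject_recording(
    params: SubjectERPParams,
    events: list[EventMarker],
    cfg: SessionConfig,
    seed: int | np.random.Generator,
) -> ContinuousRecording:
    """Render one subject's continuous recording from ground-truth params.

    Each EEG channel is 1/f background noise + a 10 Hz alpha sinusoid with
    random phase + one condition/channel-specific Gaussian P300 bump per
    stimulus + propagated blink transients.  The EOG channel carries the
    blinks at full amplitude plus white noise, and no ERP.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    tail = int(round(2.0 * fs))
    n_samples = (events[-1].sample_index if events else 0) + tail
    t_sec = np.arange(n_samples) / fs

    # Blink train, shared across channels via propagation weights
    duration_min = n_samples / fs / 60.0
    n_blinks = rng.poisson(params.blink_rate_per_min * duration_min)
    blink = _blink_waveform(fs)
    blink_trace = np.zeros(n_samples)
    if n_blinks and params.blink_amplitude_eog > 0:
        starts = rng.integers(0, max(1, n_samples - blink.size), size=n_blinks)
        for s in starts:
            blink_trace[s : s + blink.size] += params.blink_amplitude_eog * blink

    epoch_len = int(round(cfg.stim_duration_ms / 1000.0 * fs))
    t_epoch_ms = np.arange(epoch_len) * 1000.0 / fs

    data = np.zeros((len(cfg.channels), n_samples))
    for ci, ch in enumerate(cfg.channels):
        if ch == cfg.eog_channel:
            data[ci] = blink_trace + params.eog_noise_sd * rng.standard_normal(
                n_samples
            )
            continue
        x = _pink_noise(rng, n_samples, params.background_noise_sd)
        if params.alpha_amplitude:
            x += params.alpha_amplitude * np.sin(
                2 * np.pi * 10.0 * t_sec + rng.uniform(0, 2 * np.pi)
            )
        if params.line_noise_amplitude:
            x += params.line_noise_amplitude * np.sin(
                2 * np.pi * 50.0 * t_sec + rng.uniform(0, 2 * np.pi)
            )
        for ev in events:
            key = (ev.condition, ch)
            amp = params.amplitude.get(key, 0.0)
            if amp == 0.0:
                continue
            bump = _gaussian_bump(
                t_epoch_ms, params.latency[key], amp, params.p300_width_ms
            )
            stop = min(ev.sample_index + epoch_len, n_samples)
            x[ev.sample_index : stop] += bump[: stop - ev.sample_index]
        x += params.eog_propagation.get(ch, 0.0) * blink_trace
        data[ci] = x

    # float32 matches acquisition-hardware precision and halves filter cost
    return ContinuousRecording(
        list(cfg.channels), fs, data.astype(np.float32), list(events)
    )


def _draw_subject_latents(
    model: GroupModel, group: str, rng: np.random.Generator
) -> tuple[dict, dict, dict]:
    """Draw one subject's (latency map, amplitude map, score map)."""
    rho = model.factor_correlation
    z_lat = rng.standard_normal()
    z_amp = rho * z_lat + math.sqrt(1 - rho * rho) * rng.standard_normal()

    lam = model.cell_loading
    resid = math.sqrt(1 - lam * lam)
    lat, amp = {}, {}
    lo, hi = model.latency_bounds
    for cell, (lm, ls, am, asd) in model.peaks[group].items():
        zl = lam * z_lat + resid * rng.standard_normal()
        za = lam * z_amp + resid * rng.standard_normal()
        lat[cell] = float(np.clip(lm + ls * zl, lo, hi))
        amp[cell] = float(max(am + asd * za, model.amplitude_floor))

    scores = {}
    for test, per_group in model.neuropsych.items():
        c, d = model.coupling.get(test, (0.0, 0.0))
        e = math.sqrt(max(0.0, 1 - c * c - d * d))
        z = c * z_lat + d * z_amp + e * rng.standard_normal()
        mean, sd = per_group[group]
        val = mean + sd * z
        dec, low, high = _SCORE_ROUNDING.get(test, (2, None, None))
        val = round(val, dec) if dec else round(val)
        if low is not None:
            val = max(val, low)
        if high is not None:
            val = min(val, high)
        scores[test] = float(val)
    return lat, amp, scores


def simulate_cohort_params(
    model: GroupModel,
    cfg: SessionConfig | None = None,
    seed: int = 0,
) -> tuple[CohortTable, list[SubjectERPParams]]:
    """Draw the cohort's latent structure without rendering any EEG.

    Cheap path used for large-sample calibration checks and by
    :func:`simulate_cohort`.  Subject order: all HC, then all MCI.
    """
    cfg = cfg or SessionConfig()
    defaults = model.render_defaults or SubjectERPParams(latency={}, amplitude={})
    rows, params_list = [], []
    idx = 0
    for group in GROUPS:
        for _ in range(model.n_subjects.get(group, 0)):
            rng = _subject_rng(seed, idx)
            while True:
                lat, amp, scores = _draw_subject_latents(model, group, rng)
                if not (model.enforce_gds_cutoff and scores.get("GDS", 0) > 11):
                    break
            params_list.append(
                replace(defaults, latency=lat, amplitude=amp)
            )
            events = generate_event_sequence(cfg, _subject_rng(seed, idx).spawn(1)[0])
            true_count = sum(ev.condition == "target" for ev in events)
            bias, sd = model.count_error[group]
            reported = max(0, true_count + int(round(rng.normal(bias, sd))))
            demo = {}
            for name, per_group in model.demographics.items():
                m, s = per_group[group]
                demo[name] = round(m + s * rng.standard_normal(), 1)
            sex = "F" if idx % 20 < 11 else "M"  # 11/9 split per 20, as published
            rows.append(
                {
                    "id": f"{group}{idx:03d}",
                    "group": group,
                    "age": demo.get("age"),
                    "education": demo.get("education"),
                    "sex": sex,
                    **scores,
                    "true_target_count": true_count,
                    "reported_count": reported,
                }
            )
            idx += 1
    return CohortTable(pd.DataFrame(rows)), params_list


def simulate_cohort(
    model: GroupModel,
    cfg: SessionConfig | None = None,
    seed: int = 0,
) -> tuple[list[ContinuousRecording], CohortTable, list[SubjectERPParams]]:
    """Simulate a full cohort: recordings, cohort table and ground truth.

    Deterministic given (model, cfg, seed); each subject derives its own
    child generator from the master seed, so subject k's data does not
    depend on cohort size.
    """
    cfg = cfg or SessionConfig()
    table, params_list = simulate_cohort_params(model, cfg, seed)
    recordings = []
    for idx, params in enumerate(params_list):
        events = generate_event_sequence(cfg, _subject_rng(seed, idx).spawn(1)[0])
        rec = render_subject_recording(
            params, events, cfg, _subject_rng(seed, idx).spawn(2)[1]
        )
        recordings.append(rec)
    return recordings, table, params_list


def iter_subject_recordings(model: GroupModel, cfg: SessionConfig, seed: int):
    """Yield ``(row, params, recording)`` one subject at a time.

    Memory-friendly streaming equivalent of :func:`simulate_cohort`,
    producing bit-identical subjects.
    """
    cfg = cfg or SessionConfig()
    table, params_list = simulate_cohort_params(model, cfg, seed)
    for idx, params in enumerate(params_list):
        events = generate_event_sequence(cfg, _subject_rng(seed, idx).spawn(1)[0])
        rec = render_subject_recording(
            params, events, cfg, _subject_rng(seed, idx).spawn(2)[1]
        )
        yield table.df.iloc[idx], params, rec


def check_count_accuracy(reported: int, true: int, tolerance: float = 0.10) -> bool:
    """Behavioral inclusion rule: relative count error within *tolerance*."""
    if reported < 0 or true < 0:
        raise ValueError("counts must be non-negative")
    if true == 0:
        raise ValueError("true count must be positive")
    return abs(reported - true) / true <= tolerance
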