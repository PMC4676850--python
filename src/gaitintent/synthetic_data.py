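"""Simulated gait-initiation sessions with the structure the analysis assumes.

A session follows the cue protocol of the emulated study: each trial is a
~10 s relaxation period opened by an auditory ``relax_cue``, a ``walk_cue``,
and a self-paced movement onset 1-3 s later; twenty trials form a phase, five
phases a session (100 trials).  The EEG carries, per trial, a movement-related
cortical potential (slow negative ramp starting 1.5 s before the onset,
maximally negative 200 ms after it, peaking over Cz/FC1/FC2), a mu-band
(10 Hz) oscillation whose amplitude drops by ``erd_depth`` from 1 s before
the onset (event-related desynchronization over C3/Cz/C4), spatially mixed
1/f background noise, and optional blink / high-amplitude artifacts.  The EMG
is band-limited noise with a burst starting at the true onset.

Ground truth (true onsets, artifact flags, latent motivation) is returned
alongside and serialized as a JSON sidecar, never embedded in the signal
file.  Randomness derives from one master seed; trial ``k`` uses the
counter-based sub-seed ``(seed, 1000 + k)`` so it is reproducible in
isolation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import (
    IMI_REVERSE_ITEMS,
    IMI_SUBSCALES,
    AcquisitionConfig,
    Event,
    SessionRecording,
)

__all__ = [
    "ProtocolParams",
    "SignalModelParams",
    "GroundTruth",
    "generate_session",
    "mrcp_waveform",
    "mu_signal",
    "generate_imi",
    "SCALP_POSITIONS",
]

#: Approximate 2-D scalp positions (x: left->right, y: back->front), unit head.
SCALP_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.41, 0.53), "Fz": (0.0, 0.50),
    "F4": (0.41, 0.53), "F8": (0.81, 0.59),
    "FC5": (-0.59, 0.28), "FC1": (-0.21, 0.26), "FC2": (0.21, 0.26),
    "FC6": (0.59, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0), "C4": (0.5, 0.0),
    "T8": (1.0, 0.0),
    "CP5": (-0.59, -0.28), "CP1": (-0.21, -0.26), "CP2": (0.21, -0.26),
    "CP6": (0.59, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.41, -0.53), "Pz": (0.0, -0.50),
    "P4": (0.41, -0.53), "P8": (0.81, -0.59),
    "POz": (0.0, -0.75), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95),
}


class ParameterError(ValueError):
    pass


@dataclass
class ProtocolParams:
    """Cue timing of the session protocol (times in seconds)."""

    n_phases: int = 5
    trials_per_phase: int = 20
    relax_duration_s: float = 10.0
    relax_jitter_s: float = 1.0
    onset_delay_range_s: tuple[float, float] = (1.0, 3.0)
    movement_duration_s: float = 2.0
    inter_trial_gap_s: float = 1.0
    break_duration_s: float = 5.0

    def __post_init__(self) -> None:
        self.onset_delay_range_s = tuple(self.onset_delay_range_s)
        if self.n_phases * self.trials_per_phase <= 0:
            raise ParameterError("protocol must contain at least one trial")
        if self.onset_delay_range_s[0] <= 0:
            raise ParameterError("onset delay after the walk cue must be > 0")
        if self.relax_duration_s - self.relax_jitter_s <= 6.0:
            raise ParameterError(
                "relaxation must exceed 6 s so a full pre-onset epoch exists"
            )

    @property
    def n_trials(self) -> int:
        return self.n_phases * self.trials_per_phase


@dataclass
class MRCPShape:
    """Slow negative pre-movement potential: piecewise ramp + raised-cosine
    trough.  Zero before ``ramp_start_s`` (relative to onset), monotone
    decrease to ``amplitude_uv`` at ``trough_latency_s``, raised-cosine
    recovery after (symmetric by default, see ``recovery_s``)."""

    amplitude_uv: float = -20.0
    ramp_start_s: float = -1.5
    trough_latency_s: float = 0.2
    #: recovery matches the descent duration by default, making the pulse
    #: symmetric about the trough so a zero-phase band-pass leaves the
    #: trough latency identifiable (an asymmetric pulse shifts the filtered
    #: extremum by construction); the protocol constrains only the ramp
    #: start and the trough.
    recovery_s: float = 1.7

    def __post_init__(self) -> None:
        if self.trough_latency_s <= self.ramp_start_s:
            raise ParameterError("trough latency must follow ramp start")


@dataclass
class MuShape:
    """Sensorimotor mu rhythm with pre-movement desynchronization."""

    center_freq_hz: float = 10.0
    baseline_amplitude_uv: float = 12.0
    erd_depth: float = 0.6
    erd_start_s: float = -1.0
    transition_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ParameterError("erd_depth must lie in [0, 1]")
        if self.transition_s > 0.25:
            raise ParameterError("envelope transition must be <= 250 ms")


@dataclass
class EMGBurst:
    """Tibialis-anterior activation: band-limited noise burst at the onset.

    The raised-cosine rise is calibrated so the Hilbert-envelope crossing of
    10 % of the burst peak falls ~100 ms after activation start (the same
    convention the onset detector inverts with its fixed 100 ms offset):
    rise time R gives the 10 % crossing at R*acos(0.8)/pi ~= 0.205 R.
    """

    band_hz: tuple[float, float] = (30.0, 100.0)
    baseline_rms_uv: float = 8.0
    amplitude_ratio: float = 30.0
    rise_time_s: float = 0.49
    fall_time_s: float = 0.3

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)


@dataclass
class ArtifactRates:
    blink_per_trial: float = 0.05
    high_amplitude_per_trial: float = 0.02
    premature_per_trial: float = 0.0  # movement before the walk cue
    blink_amplitude_uv: tuple[float, float] = (50.0, 100.0)
    high_amplitude_scale: float = 5.0

    def __post_init__(self) -> None:
        self.blink_amplitude_uv = tuple(self.blink_amplitude_uv)


@dataclass
class SignalModelParams:
    """Amplitudes, topographies and artifact rates of the signal model."""

    background_exponent: float = 1.0
    background_rms_uv: float = 10.0
    n_background_sources: int = 15
    shared_fraction: float = 0.8  # variance fraction from spatially mixed sources
    #: depth of the slow log-normal amplitude modulation of the shared
    #: sources; real EEG background is bursty (leptokurtic), which is also
    #: what makes the sources identifiable to ICA
    burstiness: float = 0.6
    mrcp: MRCPShape = field(default_factory=MRCPShape)
    mu: MuShape = field(default_factory=MuShape)
    emg_burst: EMGBurst = field(default_factory=EMGBurst)
    artifacts: ArtifactRates = field(default_factory=ArtifactRates)

    def __post_init__(self) -> None:
        for name, cls in (
            ("mrcp", MRCPShape),
            ("mu", MuShape),
            ("emg_burst", EMGBurst),
            ("artifacts", ArtifactRates),
        ):
            v = getattr(self, name)
            if isinstance(v, dict):
                v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
                setattr(self, name, cls(**v))


@dataclass
class GroundTruth:
    """Per-trial truth for a simulated session."""

    onset_times: list[float]
    walk_cue_times: list[float]
    blink: list[bool]
    high_amplitude: list[bool]
    premature: list[bool]
    latent_motivation: float = 0.0

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------


def mrcp_waveform(t: np.ndarray, mrcp: MRCPShape) -> np.ndarray:
    """MRCP amplitude (microvolts) on time grid ``t`` (seconds, onset at 0).

    Zero before ``ramp_start_s``; monotone raised-cosine descent to the trough
    (``amplitude_uv`` exactly at ``trough_latency_s``); raised-cosine recovery
    to zero over ``recovery_s``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    t0, t1 = mrcp.ramp_start_s, mrcp.trough_latency_s
    fall = (t >= t0) & (t <= t1)
    frac = (t[fall] - t0) / (t1 - t0)
    out[fall] = mrcp.amplitude_uv * 0.5 * (1.0 - np.cos(np.pi * frac))
    rec = (t > t1) & (t < t1 + mrcp.recovery_s)
    frac = (t[rec] - t1) / mrcp.recovery_s
    out[rec] = mrcp.amplitude_uv * 0.5 * (1.0 + np.cos(np.pi * frac))
    return out


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Raised-cosine step from 0 to 1 on [0, 1]."""
    y = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * y))


def mu_envelope(t: np.ndarray, mu: MuShape, onset: float,
                recover_at: float | None = None) -> np.ndarray:
    """Amplitude envelope of the mu rhythm around one movement onset."""
    t = np.asarray(t, dtype=float)
    drop = _smoothstep((t - (onset + mu.erd_start_s)) / max(mu.transition_s, 1e-9))
    if recover_at is not None:
        drop = drop * (1.0 - _smoothstep((t - recover_at) / 0.5))
    return mu.baseline_amplitude_uv * (1.0 - mu.erd_depth * drop)


def mu_signal(t: np.ndarray, mu: MuShape, onset: float, phase: float = 0.0,
              recover_at: float | None = None) -> np.ndarray:
    """Mu oscillation (microvolts): sinusoid at ``center_freq_hz`` whose
    envelope is the baseline amplitude before ``onset + erd_start_s`` and
    ``baseline * (1 - erd_depth)`` after, with a <=250 ms smooth transition."""
    t = np.asarray(t, dtype=float)
    return mu_envelope(t, mu, onset, recover_at) * np.sin(
        2.0 * np.pi * mu.center_freq_hz * t + phase
    )


def _pink_noise(n: int, exponent: float, rng: np.random.Generator,
                shape: tuple[int, ...] = ()) -> np.ndarray:
    """1/f^exponent noise, unit RMS, along the last axis."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _gaussian_topography(center: tuple[float, float], sigma: float,
                         channels: tuple[str, ...]) -> np.ndarray:
    pos = np.array([SCALP_POSITIONS.get(c, (0.0, 0.0)) for c in channels])
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * sigma**2))
    return w / w.max()


def _bandpass_noise(n: int, band: tuple[float, float], fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [band[0], min(band[1], 0.49 * fs * 2 / 2)],
                     btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


# ---------------------------------------------------------------------------
# Session generator
# ---------------------------------------------------------------------------


def generate_session(
    protocol: ProtocolParams | None = None,
    model: SignalModelParams | None = None,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
    subject_id: str = "S01",
    session_index: int = 1,
) -> tuple[SessionRecording, GroundTruth]:
    """Generate one subject-session plus its ground truth."""
    protocol = protocol or ProtocolParams()
    model = model or SignalModelParams()
    acq = acq or AcquisitionConfig()
    fs = acq.sampling_rate
    rng_prot = np.random.default_rng([int(seed), 1])
    rng_bg = np.random.default_rng([int(seed), 2])

    # -- timeline ----------------------------------------------------------
    events: list[Event] = []
    onsets: list[float] = []
    walk_cues: list[float] = []
    premature: list[bool] = []
    t = 1.0
    trial_spans: list[tuple[float, float]] = []  # [relax_cue, trial_end)
    for phase in range(protocol.n_phases):
        for k in range(protocol.trials_per_phase):
            relax = t
            relax_dur = protocol.relax_duration_s + protocol.relax_jitter_s * float(
                rng_prot.uniform(-1.0, 1.0)
            )
            walk = relax + relax_dur
            is_premature = bool(
                rng_prot.random() < model.artifacts.premature_per_trial
            )
            if is_premature:
                onset = float(rng_prot.uniform(walk - 2.0, walk - 0.2))
            else:
                onset = walk + float(rng_prot.uniform(*protocol.onset_delay_range_s))
            end = max(onset, walk) + protocol.movement_duration_s
            events.append(Event(relax, "relax_cue"))
            events.append(Event(walk, "walk_cue"))
            onsets.append(onset)
            walk_cues.append(walk)
            premature.append(is_premature)
            trial_spans.append((relax, end + protocol.inter_trial_gap_s))
            t = end + protocol.inter_trial_gap_s
        if phase < protocol.n_phases - 1:
            events.append(Event(t, "phase_break"))
            t += protocol.break_duration_s
    total_s = int(np.ceil(t + 1.0))
    n = int(round(total_s * fs))
    tt = np.arange(n) / fs

    n_trials = protocol.n_trials
    n_eeg = len(acq.eeg_channel_names)

    # -- background EEG: spatially mixed 1/f sources + independent floor ----
    k_src = model.n_background_sources
    sources = _pink_noise(n, model.background_exponent, rng_bg, (k_src,))
    if model.burstiness > 0:
        env_sos = sps.butter(2, min(0.5, 0.45 * fs), btype="lowpass", fs=fs,
                             output="sos")
        mod = sps.sosfilt(env_sos, rng_bg.standard_normal((k_src, n)), axis=-1)
        mod = np.exp(model.burstiness * mod / mod.std(axis=-1, keepdims=True))
        sources = sources * mod
        sources /= sources.std(axis=-1, keepdims=True)
    centers = rng_bg.uniform(-0.9, 0.9, size=(k_src, 2))
    mixing = np.stack(
        [
            _gaussian_topography(tuple(c), float(rng_bg.uniform(0.3, 0.8)),
                                 acq.eeg_channel_names)
            for c in centers
        ],
        axis=1,
    ) * rng_bg.choice([-1.0, 1.0], size=(1, k_src))
    shared = mixing @ sources
    shared /= shared.std(axis=1, keepdims=True)
    indep = _pink_noise(n, model.background_exponent, rng_bg, (n_eeg,))
    sf = model.shared_fraction
    eeg = model.background_rms_uv * (
        np.sqrt(sf) * shared + np.sqrt(1.0 - sf) * indep
    )

    # -- EMG baseline -------------------------------------------------------
    rng_emg = np.random.default_rng([int(seed), 3])
    emg = np.stack(
        [
            model.emg_burst.baseline_rms_uv
            * _bandpass_noise(n, model.emg_burst.band_hz, fs, rng_emg)
            for _ in acq.emg_channel_names
        ]
    )

    mrcp_topo = _gaussian_topography((0.0, 0.17), 0.45, acq.eeg_channel_names)
    mu_topo = _gaussian_topography((-0.5, 0.0), 0.4, acq.eeg_channel_names)
    mu_topo = mu_topo + _gaussian_topography((0.5, 0.0), 0.4, acq.eeg_channel_names)
    mu_topo = mu_topo / mu_topo.max()
    blink_topo = _gaussian_topography((0.0, 0.95), 0.35, acq.eeg_channel_names)

    blink_flags: list[bool] = []
    bad_flags: list[bool] = []
    for k in range(n_trials):
        rng_k = np.random.default_rng([int(seed), 1000 + k])
        relax, end = trial_spans[k]
        onset = onsets[k]
        i0, i1 = int(relax * fs), min(int(end * fs), n)
        seg_t = tt[i0:i1]

        # MRCP, time-locked to the true onset
        eeg[:, i0:i1] += np.outer(
            mrcp_topo, mrcp_waveform(seg_t - onset, model.mrcp)
        )

        # mu rhythm with ERD, fresh phase each trial
        phase = float(rng_k.uniform(0.0, 2.0 * np.pi))
        recover = onset + protocol.movement_duration_s
        eeg[:, i0:i1] += np.outer(
            mu_topo, mu_signal(seg_t, model.mu, onset, phase, recover_at=recover)
        )

        # EMG burst from the true onset
        env = np.zeros_like(seg_t)
        rise = _smoothstep((seg_t - onset) / model.emg_burst.rise_time_s)
        fall = 1.0 - _smoothstep(
            (seg_t - (onset + protocol.movement_duration_s))
            / model.emg_burst.fall_time_s
        )
        env = rise * fall
        plateau = (
            model.emg_burst.amplitude_ratio * model.emg_burst.baseline_rms_uv
        )
        for ch in range(emg.shape[0]):
            gain = float(rng_k.uniform(0.8, 1.0))
            burst = _bandpass_noise(len(seg_t), model.emg_burst.band_hz, fs, rng_k)
            emg[ch, i0:i1] += gain * plateau * env * burst

        # artifacts
        has_blink = bool(rng_k.random() < model.artifacts.blink_per_trial)
        if has_blink:
            bt = float(rng_k.uniform(relax + 0.5, walk_cues[k]))
            amp = float(rng_k.uniform(*model.artifacts.blink_amplitude_uv))
            dur = float(rng_k.uniform(0.33, 1.0))  # 1-3 Hz single lobe
            mask = (tt >= bt) & (tt < bt + dur)
            lobe = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (tt[mask] - bt) / dur))
            eeg[:, mask] += np.outer(blink_topo, lobe)
        blink_flags.append(has_blink)

        is_bad = bool(rng_k.random() < model.artifacts.high_amplitude_per_trial)
        if is_bad:
            eeg[:, i0:i1] *= model.artifacts.high_amplitude_scale
        bad_flags.append(is_bad)

    rec = SessionRecording(eeg, emg, events, subject_id, session_index, acq)
    rng_subj = np.random.default_rng([int(seed), 4])
    truth = GroundTruth(
        onset_times=[float(o) for o in onsets],
        walk_cue_times=[float(w) for w in walk_cues],
        blink=blink_flags,
        high_amplitude=bad_flags,
        premature=premature,
        latent_motivation=float(rng_subj.standard_normal()),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Intrinsic Motivation Inventory generator
# ---------------------------------------------------------------------------

#: Subscales whose items are driven by the latent motivation (the study found
#: performance correlated with interest/enjoyment and value/usefulness).
_DRIVEN_SUBSCALES = ("interest_enjoyment", "value_usefulness")


def generate_imi(
    n_subjects: int,
    n_sessions: int,
    coupling: float = 0.35,
    noise_sd: float = 1.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic 37-item IMI responses on a 1-7 Likert scale.

    ``coupling`` is the slope from the latent per-subject-session motivation
    (standard normal) to the item propensities of the motivation-driven
    subscales; ``noise_sd`` is the per-item response noise.  A synthetic
    detection performance is linked deterministically to the latent score so
    that item noise alone sets the observable motivation-performance
    correlation (defaults calibrated near r ~ 0.6).  Returns the item table
    and the latent truth (motivation + performance) per subject-session.
    """
    if not np.isfinite(coupling):
        raise ParameterError("coupling must be finite")
    rng = np.random.default_rng([int(seed), 7])
    rows = []
    truth_rows = []
    for s in range(n_subjects):
        for sess in range(1, n_sessions + 1):
            m = float(rng.standard_normal())
            row: dict[str, object] = {"subject": f"S{s + 1:02d}", "session": sess}
            for name, items in IMI_SUBSCALES.items():
                k = len(items)
                if name in _DRIVEN_SUBSCALES:
                    center = 4.0 + coupling * m
                else:
                    center = 4.0 + 1.0 * float(rng.standard_normal())
                for j, item in enumerate(items):
                    dither = (j + 0.5) / k - 0.5
                    val = center + dither + noise_sd * float(rng.standard_normal())
                    score = int(np.clip(np.round(val), 1, 7))
                    if item in IMI_REVERSE_ITEMS:
                        score = 8 - score
                    row[f"item_{item}"] = score
            rows.append(row)
            truth_rows.append(
                {
                    "subject": f"S{s + 1:02d}",
                    "session": sess,
                    "latent_motivation": m,
                    "performance_percent": float(np.clip(64.0 + 15.0 * m, 0, 100)),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
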