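"""EMG-defined movement onsets, protocol-violation rejection and epoching.

The movement onset is computed per trial from the tibialis-anterior EMG: the
signal between the relaxation cue and five seconds after the walk cue is
Hilbert transformed, the envelope is thresholded at 10 % of its highest value
within that window, and the onset is placed 100 ms before the first upward
threshold crossing.  Trials whose onset falls before the walk cue violate the
protocol and are rejected; kept trials yield exactly six seconds of EEG
ending at the onset.

The two EMG channels are fused by taking, per trial, the channel with the
larger envelope peak; the 10 % threshold uses the per-trial maximum within
the search window; the envelope is lightly smoothed (50 ms centered moving
average, configurable) before thresholding to suppress single-sample spikes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .core_io import SessionRecording

__all__ = [
    "OnsetParams",
    "EpochedTrial",
    "OnsetDecision",
    "emg_envelope",
    "detect_onset",
    "compute_onsets",
    "epoch_trials",
]


class ContractError(ValueError):
    pass


@dataclass
class OnsetParams:
    threshold_fraction: float = 0.10
    pre_crossing_offset_s: float = 0.100
    post_cue_search_s: float = 5.0  # search window ends walk_cue + 5 s
    epoch_length_s: float = 6.0
    smoothing_s: float = 0.050

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ContractError("threshold_fraction must lie in (0, 1)")
        if self.pre_crossing_offset_s < 0:
            raise ContractError("pre-crossing offset must be >= 0")
        if self.epoch_length_s <= 0:
            raise ContractError("epoch length must be positive")


@dataclass
class OnsetDecision:
    trial_index: int
    onset_time: float | None
    channel: int | None = None
    threshold: float | None = None


@dataclass
class EpochedTrial:
    """Six seconds of EEG ending at the EMG-derived movement onset.

    ``eeg`` spans ``[-epoch_length, 0)`` seconds relative to ``onset_time``
    (half-open: the onset sample itself is excluded, so no post-onset data
    leaks into the trial).
    """

    eeg: np.ndarray  # channels x samples
    sampling_rate: float
    onset_time: float
    trial_index: int
    kept: bool = True
    reason: str = ""
    subject_id: str = ""
    session_index: int = 1
    #: onset-relative time of the sample after the last one; 0 for the
    #: classification epochs, positive for extended analysis segments
    t_end: float = 0.0

    @property
    def times(self) -> np.ndarray:
        n = self.eeg.shape[1]
        return self.t_end - n / self.sampling_rate + np.arange(n) / self.sampling_rate


def emg_envelope(segment: np.ndarray, smoothing_s: float = 0.0,
                 sampling_rate: float = 256.0) -> np.ndarray:
    """Magnitude of the analytic signal of the mean-removed EMG segment.

    Optionally smoothed with a centered moving average of ``smoothing_s``.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ContractError("segment must contain at least 2 samples")
    env = np.abs(hilbert(x - x.mean()))
    if smoothing_s > 0:
        w = max(1, int(round(smoothing_s * sampling_rate)))
        kernel = np.ones(w) / w
        pad = np.pad(env, (w // 2, w - 1 - w // 2), mode="edge")
        env = np.convolve(pad, kernel, mode="valid")
    return env


def detect_onset(
    envelope: np.ndarray,
    params: OnsetParams,
    walk_cue_time: float,
    t0: float,
    sampling_rate: float,
) -> float | None:
    """Onset time from an envelope covering the search window.

    ``envelope`` starts at session time ``t0`` (the relaxation cue) and must
    extend to ``walk_cue_time + post_cue_search_s``.  The threshold is
    ``threshold_fraction`` of the envelope maximum over the window; the onset
    is the first upward crossing minus ``pre_crossing_offset_s``.  Returns
    ``None`` when the envelope never crosses (e.g. an all-zero envelope).
    """
    env = np.asarray(envelope, dtype=float)
    peak = float(env.max(initial=0.0))
    if peak <= 0:
        return None
    thr = params.threshold_fraction * peak
    above = env >= thr
    if not above.any():
        return None
    idx = int(np.argmax(above))  # first sample at/above; counts as a crossing
    t_cross = t0 + idx / sampling_rate
    return t_cross - params.pre_crossing_offset_s


def compute_onsets(
    session: SessionRecording, params: OnsetParams | None = None
) -> list[OnsetDecision]:
    """Per-trial onset decisions for a whole session.

    For each trial the EMG between the relaxation cue and five seconds after
    the walk cue is enveloped per channel; the channel with the larger
    envelope peak is used for thresholding.
    """
    params = params or OnsetParams()
    fs = session.acquisition.sampling_rate
    out: list[OnsetDecision] = []
    for k, (relax, walk) in enumerate(session.trial_cues()):
        i0 = int(round(relax * fs))
        i1 = min(int(round((walk + params.post_cue_search_s) * fs)),
                 session.n_samples)
        if i1 - i0 < 2:
            out.append(OnsetDecision(k, None))
            continue
        envs = [
            emg_envelope(session.emg[ch, i0:i1], params.smoothing_s, fs)
            for ch in range(session.emg.shape[0])
        ]
        ch = int(np.argmax([e.max(initial=0.0) for e in envs]))
        onset = detect_onset(envs[ch], params, walk, i0 / fs, fs)
        thr = params.threshold_fraction * float(envs[ch].max(initial=0.0))
        out.append(OnsetDecision(k, onset, ch, thr))
    return out


def epoch_trials(
    session: SessionRecording,
    onsets: list[OnsetDecision],
    params: OnsetParams | None = None,
) -> list[EpochedTrial]:
    """Cut six-second pre-onset EEG epochs; flag protocol violations.

    Trials with an onset before the walk cue ("pre-cue onset"), no onset, or
    fewer than ``epoch_length_s`` seconds of pre-onset data are marked
    not-kept with a reason.  Kept trials carry exactly the epoch length of
    EEG ending at (and excluding) the onset sample.
    """
    params = params or OnsetParams()
    cues = session.trial_cues()
    if len(onsets) != len(cues):
        raise ContractError(
            f"{len(onsets)} onset decisions for {len(cues)} trials"
        )
    fs = session.acquisition.sampling_rate
    n_epoch = int(round(params.epoch_length_s * fs))
    trials: list[EpochedTrial] = []
    for dec, (relax, walk) in zip(onsets, cues):
        make = lambda kept, reason, onset: EpochedTrial(
            eeg=np.zeros((session.eeg.shape[0], 0)) if not kept else None,
            sampling_rate=fs,
            onset_time=onset if onset is not None else float("nan"),
            trial_index=dec.trial_index,
            kept=kept,
            reason=reason,
            subject_id=session.subject_id,
            session_index=session.session_index,
        )
        if dec.onset_time is None:
            trials.append(make(False, "no onset detected", None))
            continue
        if dec.onset_time <= walk:
            trials.append(make(False, "pre-cue onset", dec.onset_time))
            continue
        i1 = int(np.floor(dec.onset_time * fs))
        i0 = i1 - n_epoch
        if i0 < 0:
            trials.append(make(False, "insufficient pre-onset data",
                               dec.onset_time))
            continue
        t = make(True, "", dec.onset_time)
        t.eeg = session.eeg[:, i0:i1].copy()
        trials.append(t)
    return trials


def cut_segment(
    session: SessionRecording,
    onset_time: float,
    start_offset_s: float,
    end_offset_s: float,
    trial_index: int = 0,
) -> EpochedTrial:
    """Cut an onset-aligned EEG segment ``[onset+start, onset+end)``.

    Unlike the fixed pre-onset classification epochs this may extend past the
    onset; used for neurophysiological characterization (grand averages and
    time-frequency maps around the movement).
    """
    fs = session.acquisition.sampling_rate
    i0 = int(np.floor((onset_time + start_offset_s) * fs))
    i1 = int(np.floor((onset_time + end_offset_s) * fs))
    if i0 < 0 or i1 > session.n_samples:
        raise ContractError("segment outside the recording")
    return EpochedTrial(
        eeg=session.eeg[:, i0:i1].copy(),
        sampling_rate=fs,
        onset_time=onset_time,
        trial_index=trial_index,
        subject_id=session.subject_id,
        session_index=session.session_index,
        t_end=end_offset_s,
    )


def rejection_log(trials: list[EpochedTrial]) -> list[dict]:
    return [
        {
            "trial_index": t.trial_index,
            "kept": t.kept,
            "reason": t.reason,
            "onset_time": None if np.isnan(t.onset_time) else t.onset_time,
        }
        for t in trials
    ]


def save_rejection_log(trials: list[EpochedTrial], path: str | os.PathLike) -> None:
    Path(path).write_text(json.dumps(rejection_log(trials), indent=1))
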