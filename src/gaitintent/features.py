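"""Per-trial labeled window sequences of MRCP and ERD features.

Features come from the ten sensorimotor channels (F3, Fz, F4, FC1, FC2, C3,
Cz, C4, CP1, CP2), extracted with a one-second sliding window stepped by
125 ms over the six-second pre-onset epoch.  Windows whose center lies
strictly after -1.5 s (relative to onset) are labeled pre-movement, the rest
relaxation; for the 6 s / 1 s / 125 ms geometry this yields 41 windows of
which 8 are pre-movement.  MRCP features are the ten 10 Hz samples per
channel of the 0.1-1 Hz signal in the window (the 125 ms step does not
commensurate with the 100 ms sample period, so windows live on the
continuous time axis and map to the nearest 10 Hz samples, always exactly
ten per channel); ERD features are the log mean-square of the 8-13 Hz
band-passed signal per channel.

Training-fold features are normalized to unit Euclidean length per feature
dimension; the scale factors are carried unchanged to test folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import ANALYSIS_CHANNELS
from .emg_onset import EpochedTrial
from .neurophys import LowFreqTrial, MRCPParams, mrcp_filter

__all__ = [
    "FeatureParams",
    "WindowSequence",
    "enumerate_windows",
    "mrcp_features",
    "erd_features",
    "mu_bandpass",
    "build_window_sequence",
    "normalize_fit",
    "normalize_apply",
]

LOG_POWER_FLOOR = 1e-12  # uV^2


class ContractError(ValueError):
    pass


@dataclass
class FeatureParams:
    channels: tuple[str, ...] = ANALYSIS_CHANNELS
    window_length_s: float = 1.0
    step_s: float = 0.125
    boundary_s: float = -1.5
    mu_band_hz: tuple[float, float] = (8.0, 13.0)
    mu_filter_order: int = 4
    mrcp_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.mu_band_hz = tuple(self.mu_band_hz)
        if not self.window_length_s > self.step_s > 0:
            raise ContractError("require window_length > step > 0")


@dataclass
class WindowSequence:
    """Ordered feature windows of one trial.

    ``labels`` is 0 for relaxation, 1 for pre-movement, fixed purely by
    window geometry and the boundary; ``mrcp`` is (n_windows, 10 * 10) and
    ``erd`` (n_windows, 10).
    """

    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray
    mrcp: np.ndarray
    erd: np.ndarray
    trial_index: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def enumerate_windows(
    epoch_length_s: float, params: FeatureParams | None = None
) -> list[tuple[float, float, int]]:
    """Sliding-window geometry: (start, end, label) with times relative to
    onset.  Starts run from ``-epoch_length`` in steps of ``step_s`` up to
    ``-window_length``; label is pre-movement (1) iff the window center is
    strictly greater than the boundary."""
    params = params or FeatureParams()
    if epoch_length_s < params.window_length_s:
        raise ContractError("epoch shorter than the window")
    n = int(np.floor((epoch_length_s - params.window_length_s) / params.step_s + 1e-9)) + 1
    out = []
    for k in range(n):
        start = -epoch_length_s + k * params.step_s
        end = start + params.window_length_s
        center = 0.5 * (start + end)
        label = 1 if center > params.boundary_s + 1e-12 else 0
        out.append((start, end, label))
    return out


def mrcp_features(
    low: LowFreqTrial, window: tuple[float, float], params: FeatureParams | None = None
) -> np.ndarray:
    """The ten consecutive 10 Hz samples per channel nearest to the window.

    ``low.data`` must already be restricted to the feature channels (rows in
    ``params.channels`` order).  Returns a flat vector of length
    ``n_channels * 10``.
    """
    params = params or FeatureParams()
    start, end = window[0], window[1]
    n_per = int(round(params.window_length_s * params.mrcp_rate_hz))
    t0 = low.times[0]
    i0 = int(round((start - t0) * params.mrcp_rate_hz))
    if i0 < 0 or i0 + n_per > low.data.shape[1]:
        raise ContractError("window outside the epoch")
    return low.data[:, i0 : i0 + n_per].ravel()


def mu_bandpass(trial: EpochedTrial, params: FeatureParams | None = None) -> np.ndarray:
    """Zero-phase 8-13 Hz band-pass of the full epoch (all rows kept)."""
    params = params or FeatureParams()
    sos = sps.butter(params.mu_filter_order, params.mu_band_hz,
                     btype="bandpass", fs=trial.sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, trial.eeg, axis=1)


def erd_features(
    mu_filtered: np.ndarray,
    window: tuple[float, float],
    sampling_rate: float,
    epoch_length_s: float,
) -> np.ndarray:
    """Natural-log mean-square of the band-passed signal in the window,
    floored at ``log(1e-12)`` for silent channels."""
    start, end = window[0], window[1]
    i0 = int(round((start + epoch_length_s) * sampling_rate))
    i1 = int(round((end + epoch_length_s) * sampling_rate))
    if i0 < 0 or i1 > mu_filtered.shape[1]:
        raise ContractError("window outside the epoch")
    power = (mu_filtered[:, i0:i1] ** 2).mean(axis=1)
    return np.log(np.maximum(power, LOG_POWER_FLOOR))


def build_window_sequence(
    trial: EpochedTrial,
    channel_rows: np.ndarray,
    params: FeatureParams | None = None,
    mrcp_params: MRCPParams | None = None,
) -> WindowSequence:
    """Full feature extraction for one epoched trial.

    ``channel_rows`` maps the feature channels to rows of ``trial.eeg``.
    """
    params = params or FeatureParams()
    fs = trial.sampling_rate
    epoch_length = trial.eeg.shape[1] / fs
    low = mrcp_filter(trial, mrcp_params)
    low_sel = LowFreqTrial(low.data[channel_rows], low.times,
                           low.trial_index, low.onset_time)
    mu = mu_bandpass(trial, params)[channel_rows]
    windows = enumerate_windows(epoch_length, params)
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    labels = np.array([w[2] for w in windows])
    X_mrcp = np.stack([mrcp_features(low_sel, w, params) for w in windows])
    X_erd = np.stack(
        [erd_features(mu, w, fs, epoch_length) for w in windows]
    )
    return WindowSequence(starts, ends, labels, X_mrcp, X_erd,
                          trial.trial_index)


def normalize_fit(train: np.ndarray) -> np.ndarray:
    """Per-dimension Euclidean norms over the training windows (zero-norm
    dimensions get scale 1)."""
    if train.size == 0:
        raise ContractError("training set must be nonempty")
    norms = np.linalg.norm(train, axis=0)
    return np.where(norms > 0, norms, 1.0)


def normalize_apply(scale: np.ndarray, windows: np.ndarray) -> np.ndarray:
    return windows / scale
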