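"""MRCP and ERD characterization.

* MRCP: zero-phase second-order Butterworth band-pass at 0.1-1 Hz, then
  downsampling to 10 Hz (the band-pass itself is the anti-alias filter; the
  10 Hz grid is anchored at the epoch start, so t = -6 s carries a sample).
* ERD: Morlet wavelet power (6 cycles, 0.5 Hz frequency resolution on
  0.5-30 Hz) expressed as percentage change from the mean power in a
  [-4, -2] s baseline, with a trial-resampling bootstrap significance mask.
  Frequencies below 0.5 Hz are excluded: a 6-cycle Morlet there outlasts the
  6-s epoch.
* Grand averages are balanced hierarchical means: trials within session,
  sessions within subject, then subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .emg_onset import EpochedTrial

__all__ = [
    "MRCPParams",
    "ERDParams",
    "TFMap",
    "LowFreqTrial",
    "mrcp_filter",
    "tf_power",
    "erd_map",
    "grand_average",
]


class ContractError(ValueError):
    pass


@dataclass
class MRCPParams:
    band_hz: tuple[float, float] = (0.1, 1.0)
    filter_order: int = 2
    downsample_to_hz: float = 10.0

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)
        lo, hi = self.band_hz
        if not (0 < lo < hi < self.downsample_to_hz / 2):
            raise ContractError("require band low < high < downsample rate / 2")


@dataclass
class ERDParams:
    freq_range_hz: tuple[float, float] = (0.5, 30.0)
    freq_resolution_hz: float = 0.5
    n_cycles: float = 6.0
    baseline_s: tuple[float, float] = (-4.0, -2.0)
    alpha: float = 0.05
    n_boot: int = 1000
    time_decim: int = 16  # TF time axis kept at fs / decim

    def __post_init__(self) -> None:
        self.freq_range_hz = tuple(self.freq_range_hz)
        self.baseline_s = tuple(self.baseline_s)
        if not 0.0 < self.alpha < 1.0:
            raise ContractError("alpha must lie in (0, 1)")

    @property
    def freqs(self) -> np.ndarray:
        lo = max(self.freq_range_hz[0], self.freq_resolution_hz)
        return np.arange(lo, self.freq_range_hz[1] + 1e-9,
                         self.freq_resolution_hz)


@dataclass
class LowFreqTrial:
    """One trial after MRCP band-pass and downsampling to 10 Hz."""

    data: np.ndarray  # channels x samples (epoch_length * 10)
    times: np.ndarray  # seconds relative to onset
    trial_index: int = 0
    onset_time: float = float("nan")


@dataclass
class TFMap:
    """Time-frequency map: power or ERD%, axes strictly increasing."""

    values: np.ndarray  # channels x freqs x times
    freqs: np.ndarray
    times: np.ndarray
    units: str = "power"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ContractError("axes must be strictly increasing")
        if self.mask is not None and self.mask.shape != self.values.shape:
            raise ContractError("mask shape must equal values shape")


def mrcp_filter(trial: EpochedTrial, params: MRCPParams | None = None) -> LowFreqTrial:
    """Zero-phase 0.1-1 Hz band-pass, then decimation to 10 Hz.

    Uses forward-backward filtering (no phase shift) and polyphase
    resampling; output length is ``epoch_length * downsample_to`` samples per
    channel with the first sample at the epoch start.
    """
    params = params or MRCPParams()
    fs = trial.sampling_rate
    if fs < 2 * params.band_hz[1]:
        raise ContractError("sampling rate below twice the band upper edge")
    n = trial.eeg.shape[1]
    if n / fs < 3.0 / params.band_hz[0]:
        warnings.warn("epoch shorter than 3 filter time-constants; "
                      "edge transients may dominate", stacklevel=2)
    sos = sps.butter(params.filter_order, params.band_hz, btype="bandpass",
                     fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trial.eeg, axis=1)
    from fractions import Fraction

    frac = Fraction(params.downsample_to_hz / fs).limit_denominator(10000)
    down = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    n_out = int(round(n * params.downsample_to_hz / fs))
    down = down[:, :n_out]
    times = trial.times[0] + np.arange(n_out) / params.downsample_to_hz
    return LowFreqTrial(down, times, trial.trial_index, trial.onset_time)


def tf_power(trial: EpochedTrial, params: ERDParams | None = None) -> TFMap:
    """Morlet wavelet power of one trial on the 0.5 Hz frequency grid."""
    from mne.time_frequency import tfr_array_morlet

    params = params or ERDParams()
    fs = trial.sampling_rate
    epoch_s = trial.eeg.shape[1] / fs
    # a fixed-cycle wavelet must fit inside the epoch (MNE's Morlet support
    # is ~1.6 * cycles / f, i.e. +-5 sigma_t); below the frequency where that
    # would outlast the epoch, cycles shrink proportionally
    n_cycles = np.minimum(params.n_cycles, 0.6 * params.freqs * epoch_s)
    power = tfr_array_morlet(
        trial.eeg[None], fs, params.freqs, n_cycles=n_cycles,
        output="power", decim=params.time_decim, zero_mean=True,
    )[0]
    times = trial.times[:: params.time_decim][: power.shape[-1]]
    return TFMap(power, params.freqs.copy(), times, units="power")


def erd_map(trial_maps: Sequence[TFMap], params: ERDParams | None = None,
            seed: int = 0) -> TFMap:
    """Across-trial ERD% map with a bootstrap significance mask.

    ERD%(f, t) = 100 * (P(f, t) - B(f)) / B(f), where P is the across-trial
    mean power and B(f) the mean of P over the baseline interval, so the
    baseline columns of each frequency row average to zero.  The mask comes
    from trial-level resampling: ``n_boot`` bootstrap means are evaluated at
    the baseline columns and centered at each column's observed mean (so the
    null captures the sampling variability of the across-trial mean, not the
    column-to-column spread on top of it), pooled per frequency, and map
    points outside the two-sided ``alpha`` percentile band are significant.
    """
    params = params or ERDParams()
    if not trial_maps:
        raise ContractError("need at least one trial map")
    P = np.stack([m.values for m in trial_maps])  # trials x ch x f x t
    freqs, times = trial_maps[0].freqs, trial_maps[0].times
    b0, b1 = params.baseline_s
    bcols = np.where((times >= b0) & (times < b1))[0]
    if bcols.size == 0:
        raise ContractError("baseline interval contains no time bins")
    mean_map = P.mean(axis=0)  # ch x f x t
    B = mean_map[:, :, bcols].mean(axis=2)  # ch x f
    if np.any(B <= 0):
        raise ContractError("zero baseline power")
    erd = 100.0 * (mean_map - B[:, :, None]) / B[:, :, None]

    rng = np.random.default_rng(seed)
    n_trials = P.shape[0]
    Pb = P[:, :, :, bcols]  # trials x ch x f x nb
    lo = np.empty(B.shape)
    hi = np.empty(B.shape)
    idx = rng.integers(0, n_trials, size=(params.n_boot, n_trials))
    # bootstrap means at baseline columns only, channel by channel (memory)
    for c in range(P.shape[1]):
        boots = Pb[:, c].reshape(n_trials, -1)
        bm = idx_mean(boots, idx)  # n_boot x (f * nb)
        bm = bm.reshape(params.n_boot, len(freqs), len(bcols))
        null = 100.0 * (bm - mean_map[c][:, bcols][None]) / B[c][None, :, None]
        null = null.transpose(1, 0, 2).reshape(len(freqs), -1)
        lo[c] = np.percentile(null, 100.0 * params.alpha / 2.0, axis=1)
        hi[c] = np.percentile(null, 100.0 * (1.0 - params.alpha / 2.0), axis=1)
    mask = (erd < lo[:, :, None]) | (erd > hi[:, :, None])
    return TFMap(erd, freqs.copy(), times.copy(), units="erd_percent", mask=mask)


def idx_mean(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Mean of ``data`` rows under each bootstrap index set (rows of idx)."""
    n = data.shape[0]
    counts = np.zeros((idx.shape[0], n))
    for b in range(idx.shape[0]):
        counts[b] = np.bincount(idx[b], minlength=n)
    return (counts / idx.shape[1]) @ data


def grand_average(
    items: Sequence[np.ndarray],
    subjects: Sequence[str] | None = None,
    sessions: Sequence[int] | None = None,
) -> np.ndarray:
    """Balanced hierarchical mean: trials -> sessions -> subjects.

    With unbalanced counts this differs from the pooled mean: every session
    contributes equally within its subject, and every subject equally to the
    grand average.  Without subject/session tags it is a plain mean.
    """
    arrays = [np.asarray(a, dtype=float) for a in items]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ContractError("all items must share axes")
    if subjects is None:
        return np.mean(arrays, axis=0)
    subjects = list(subjects)
    sessions = list(sessions) if sessions is not None else [1] * len(arrays)
    per_subject = []
    for subj in dict.fromkeys(subjects):
        per_session = []
        sess_ids = [s for u, s in zip(subjects, sessions) if u == subj]
        for sess in dict.fromkeys(sess_ids):
            sel = [a for a, u, s in zip(arrays, subjects, sessions)
                   if u == subj and s == sess]
            per_session.append(np.mean(sel, axis=0))
        per_subject.append(np.mean(per_session, axis=0))
    return np.mean(per_subject, axis=0)
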