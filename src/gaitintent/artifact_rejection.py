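"""Trial-level statistical rejection and ICA-based component cleaning.

Two stages, both learned on training trials only and applicable unchanged to
held-out trials:

* joint-probability rejection: per channel, each trial's mean log-probability
  of its samples under the channel's empirical (histogram) distribution over
  all trials; trials scoring beyond ``jointprob_sd`` standard deviations from
  the mean score on any channel are dropped;
* FastICA cleaning: components fitted on concatenated training trials whose
  scalp-projected amplitude exceeds mean + ``ica_component_sd`` SD of the
  component amplitude scores are removed, and the remainder back-projected to
  sensor space.

ICA is estimated on a 1-40 Hz band-passed copy of the data for stability,
while the resulting unmixing is applied to the unfiltered signals.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .emg_onset import EpochedTrial

__all__ = [
    "ArtifactParams",
    "IcaModel",
    "jointprob_reject",
    "fit_ica",
    "apply_ica",
]


class ContractError(ValueError):
    pass


@dataclass
class ArtifactParams:
    jointprob_sd: float = 3.0
    jointprob_bins: int = 500
    ica_component_sd: float = 2.0
    ica_max_iter: int = 1000
    ica_tol: float = 1e-2
    #: PCA dimensionality kept before ICA; estimating a full-rank unmixing on
    #: channels dominated by a white sensor-noise floor does not converge, so
    #: the decomposition runs in the top principal subspace (standard EEG
    #: practice).  None keeps all channels.
    ica_n_components: int | None = 20
    ica_seed: int = 0
    ica_band_hz: tuple[float, float] = (1.0, 40.0)
    component_statistic: str = "max_abs"  # or "rms"

    def __post_init__(self) -> None:
        self.ica_band_hz = tuple(self.ica_band_hz)
        if self.jointprob_sd <= 0 or self.ica_component_sd <= 0:
            raise ContractError("SD multipliers must be positive")
        if self.component_statistic not in ("max_abs", "rms"):
            raise ContractError("component_statistic must be 'max_abs' or 'rms'")


def _trial_scores(data: np.ndarray, n_bins: int) -> np.ndarray:
    """Joint log-probability score per trial and channel.

    ``data`` has shape (trials, channels, samples).  For each channel a
    histogram density over the pooled samples of all trials estimates the
    channel's empirical distribution; a trial's score is the mean log density
    of its own samples under it.
    """
    n_trials, n_ch, _ = data.shape
    scores = np.empty((n_trials, n_ch))
    for c in range(n_ch):
        pooled = data[:, c, :].ravel()
        hist, edges = np.histogram(pooled, bins=n_bins, density=True)
        # probability floor: unseen values get the smallest nonzero density
        floor = hist[hist > 0].min() if (hist > 0).any() else 1.0
        logp = np.log(np.maximum(hist, floor))
        for k in range(n_trials):
            idx = np.clip(
                np.searchsorted(edges, data[k, c, :], side="right") - 1,
                0,
                n_bins - 1,
            )
            scores[k, c] = logp[idx].mean()
    return scores


def jointprob_reject(
    trials: list[EpochedTrial], params: ArtifactParams | None = None
) -> list[int]:
    """Indices (in original order) of trials surviving joint-probability
    rejection.  Channels with zero score variance reject nothing."""
    params = params or ArtifactParams()
    if len(trials) < 5:
        raise ContractError("need at least 5 trials to estimate distributions")
    data = np.stack([t.eeg for t in trials])
    scores = _trial_scores(data, params.jointprob_bins)
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.abs(scores - mean) / sd, 0.0)
    keep = ~(z > params.jointprob_sd).any(axis=1)
    return [i for i in range(len(trials)) if keep[i]]


@dataclass
class IcaModel:
    """Fitted FastICA decomposition with an artifact-component mask."""

    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    kept: np.ndarray  # bool per component
    channel_means: np.ndarray
    component_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_channels(self) -> int:
        return self.unmixing.shape[1]

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "unmixing": self.unmixing.tolist(),
                    "mixing": self.mixing.tolist(),
                    "kept": self.kept.astype(int).tolist(),
                    "channel_means": self.channel_means.tolist(),
                    "component_scores": self.component_scores.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "IcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["unmixing"]),
            np.array(d["mixing"]),
            np.array(d["kept"], dtype=bool),
            np.array(d["channel_means"]),
            np.array(d["component_scores"]),
        )


def fit_ica(
    trials: list[EpochedTrial], params: ArtifactParams | None = None
) -> IcaModel:
    """Fit FastICA on concatenated trials and flag large components.

    Each component's amplitude score is the maximum absolute value (or RMS)
    of its scalp-projected time course; components scoring above
    mean + ``ica_component_sd`` * SD of all scores are rejected.  On
    non-convergence the fit is retried with a fresh seed up to 3 times.
    """
    params = params or ArtifactParams()
    fs = trials[0].sampling_rate
    X = np.concatenate([t.eeg for t in trials], axis=1)  # channels x samples
    if X.shape[1] <= X.shape[0]:
        raise ContractError("need more samples than channels to fit ICA")
    lo, hi = params.ica_band_hz
    sos = sps.butter(4, [lo, min(hi, 0.45 * fs)], btype="bandpass", fs=fs,
                     output="sos")
    Xf = sps.sosfiltfilt(sos, X, axis=1)

    last_err: Exception | None = None
    for attempt in range(3):
        n_comp = params.ica_n_components
        if n_comp is not None:
            n_comp = min(n_comp, X.shape[0])
        # each retry uses a fresh seed and a 5x coarser stopping tolerance
        ica = FastICA(
            n_components=n_comp,
            max_iter=params.ica_max_iter,
            tol=params.ica_tol * 5**attempt,
            random_state=params.ica_seed + attempt,
            whiten="unit-variance",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(Xf.T).T  # components x samples
                break
            except ConvergenceWarning as err:  # pragma: no cover - rare
                last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"FastICA failed to converge after 3 seeds: {last_err}")

    mixing = ica.mixing_  # channels x components
    unmixing = ica.components_
    means = ica.mean_
    if params.component_statistic == "max_abs":
        amp = np.abs(sources).max(axis=1) * np.abs(mixing).max(axis=0)
    else:
        amp = np.sqrt((sources**2).mean(axis=1)) * np.sqrt(
            (mixing**2).mean(axis=0)
        )
    thr = amp.mean() + params.ica_component_sd * amp.std()
    kept = amp <= thr
    if not kept.any():
        kept = np.ones_like(kept, dtype=bool)
    return IcaModel(unmixing, mixing, kept, means, amp)


def apply_ica(model: IcaModel, trials: list[EpochedTrial]) -> list[EpochedTrial]:
    """Back-project the kept components; idempotent affine projection."""
    out: list[EpochedTrial] = []
    P = model.mixing[:, model.kept] @ model.unmixing[model.kept, :]
    mu = model.channel_means
    for t in trials:
        if t.eeg.shape[0] != model.n_channels:
            raise ContractError(
                f"trial has {t.eeg.shape[0]} channels, model expects "
                f"{model.n_channels}"
            )
        cleaned = P @ (t.eeg - mu[:, None]) + mu[:, None]
        nt = EpochedTrial(
            eeg=cleaned,
            sampling_rate=t.sampling_rate,
            onset_time=t.onset_time,
            trial_index=t.trial_index,
            kept=t.kept,
            reason=t.reason,
            subject_id=t.subject_id,
            session_index=t.session_index,
        )
        out.append(nt)
    return out
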