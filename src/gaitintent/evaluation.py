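"""Nested chronological cross-validation, the trial-correct metric, chance
level, feature diagnostics, session transfer and motivation correlations.

Evaluation follows the carry-over discipline of the emulated protocol: on
each outer training fold, joint-probability rejection, FastICA, feature
normalization and hyperparameter/threshold selection are learned, then
applied unchanged to the test fold; no trial is ever removed from a test
fold.  A test trial counts as correct only with at least one detection in
the pre-movement window block and none in the relaxation block.

The chance level of that metric is estimated by relocating a contiguous
block of ``n_pre`` predicted-positive windows uniformly among the
``n_windows - n_pre + 1`` possible positions; only full containment in the
true pre-movement block satisfies the metric, giving the analytic value
``100 / (n_windows - n_pre + 1)`` percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .artifact_rejection import ArtifactParams, apply_ica, fit_ica, jointprob_reject
from .detector import EnsembleModel, HyperGrid, SLDAModel, detect, fit_ensemble
from .emg_onset import EpochedTrial
from .features import (
    FeatureParams,
    WindowSequence,
    build_window_sequence,
    normalize_apply,
    normalize_fit,
)
from .neurophys import MRCPParams
from .core_io import IMI_REVERSE_ITEMS, IMI_SUBSCALES, PipelineConfig

__all__ = [
    "CVParams",
    "CVResult",
    "ChanceParams",
    "chronological_folds",
    "run_nested_cv",
    "trial_correct",
    "chance_level",
    "chance_level_analytic",
    "session_transfer",
    "r2_pointbiserial",
    "feature_consistency",
    "weight_ratio",
    "imi_scores",
    "correlate_performance",
]


class ContractError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class CVParams:
    outer_folds: int = 5
    inner_folds: int = 5
    chronological: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ContractError("folds must be >= 2")


@dataclass
class ChanceParams:
    n_windows: int = 41
    n_pre: int = 8
    n_draws: int = 100_000
    scheme: str = "block_relocation"

    def __post_init__(self) -> None:
        if not 0 < self.n_pre <= self.n_windows:
            raise ContractError("require 0 < n_pre <= n_windows")
        if self.scheme != "block_relocation":
            raise ContractError(f"unknown chance scheme {self.scheme!r}")


@dataclass
class FoldResult:
    test_indices: list[int]
    outputs: list[np.ndarray]
    labels: list[np.ndarray]
    correct: list[bool]
    model_summary: dict
    mrcp_weights: np.ndarray
    erd_weights: np.ndarray

    @property
    def percent_correct(self) -> float:
        return 100.0 * float(np.mean(self.correct)) if self.correct else float("nan")


@dataclass
class CVResult:
    folds: list[FoldResult]

    @property
    def fold_percentages(self) -> list[float]:
        return [f.percent_correct for f in self.folds]

    @property
    def percent_correct(self) -> float:
        flags = [c for f in self.folds for c in f.correct]
        return 100.0 * float(np.mean(flags))

    def report(self) -> dict:
        return {
            "percent_correct": self.percent_correct,
            "fold_percentages": self.fold_percentages,
            "folds": [
                {
                    "test_indices": f.test_indices,
                    "correct": [bool(c) for c in f.correct],
                    "outputs": [o.tolist() for o in f.outputs],
                    "model": f.model_summary,
                }
                for f in self.folds
            ],
        }


def chronological_folds(n_trials: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split ``n_trials`` chronologically ordered trials into ``k`` contiguous
    test blocks (sizes differing by at most one); each block is the test fold
    once and everything else trains."""
    if k > n_trials:
        raise ContractError("more folds than trials")
    sizes = np.full(k, n_trials // k)
    sizes[: n_trials % k] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    out = []
    all_idx = np.arange(n_trials)
    for f in range(k):
        test = all_idx[bounds[f] : bounds[f + 1]]
        train = np.concatenate([all_idx[: bounds[f]], all_idx[bounds[f + 1] :]])
        out.append((train, test))
    return out


def trial_correct(pred: Sequence[int], labels: Sequence[int]) -> bool:
    """Nonzero sensitivity and maximum specificity: at least one detection in
    the pre-movement block and none in the relaxation block."""
    pred = np.asarray(pred).astype(int)
    labels = np.asarray(labels).astype(int)
    if pred.shape != labels.shape:
        raise ContractError("pred and labels must have the same length")
    tp = np.any((pred == 1) & (labels == 1))
    fp = np.any((pred == 1) & (labels == 0))
    return bool(tp and not fp)


def chance_level(params: ChanceParams | None = None, seed: int = 0) -> float:
    """Monte-Carlo chance percentage under contiguous-block relocation."""
    params = params or ChanceParams()
    rng = np.random.default_rng(seed)
    n_pos = params.n_windows - params.n_pre + 1
    positions = rng.integers(0, n_pos, size=params.n_draws)
    # only the block flush with the true (trailing) pre-movement block has
    # zero false positives and nonzero sensitivity
    return 100.0 * float(np.mean(positions == n_pos - 1))


def chance_level_analytic(params: ChanceParams | None = None) -> float:
    params = params or ChanceParams()
    return 100.0 / (params.n_windows - params.n_pre + 1)


# ---------------------------------------------------------------------------
# Nested cross-validation pipeline
# ---------------------------------------------------------------------------


def _prepare_fold(
    train_trials: list[EpochedTrial],
    test_trials: list[EpochedTrial],
    config: PipelineConfig,
):
    """Training-fold preprocessing, carried unchanged to the test fold."""
    artifact: ArtifactParams = config.artifact
    feature: FeatureParams = config.feature
    mrcp: MRCPParams = config.mrcp
    keep = jointprob_reject(train_trials, artifact)
    kept_train = [train_trials[i] for i in keep]
    ica = fit_ica(kept_train, artifact)
    clean_train = apply_ica(ica, kept_train)
    clean_test = apply_ica(ica, test_trials)
    rows = config.acquisition.analysis_indices()
    seq_train = [build_window_sequence(t, rows, feature, mrcp) for t in clean_train]
    seq_test = [build_window_sequence(t, rows, feature, mrcp) for t in clean_test]
    mrcp_scale = normalize_fit(np.concatenate([s.mrcp for s in seq_train]))
    erd_scale = normalize_fit(np.concatenate([s.erd for s in seq_train]))
    return seq_train, seq_test, mrcp_scale, erd_scale, ica


def run_nested_cv(
    trials: list[EpochedTrial],
    config: PipelineConfig | None = None,
    min_trials: int = 25,
) -> CVResult:
    """5 x 5-fold nested chronological cross-validation over kept trials.

    Per outer fold: joint-probability rejection, ICA, normalization and the
    inner hyperparameter/threshold search run on training trials only; the
    fitted parameters are applied unchanged to every test trial (none is
    removed), and per-trial binary outputs plus trial-correct flags are
    recorded.
    """
    config = config or PipelineConfig()
    trials = [t for t in trials if t.kept]
    if len(trials) < min_trials:
        raise ContractError(f"need at least {min_trials} kept trials")
    cv: CVParams = config.cv
    folds = chronological_folds(len(trials), cv.outer_folds)
    results: list[FoldResult] = []
    for tr_idx, te_idx in folds:
        seq_train, seq_test, m_scale, e_scale, _ = _prepare_fold(
            [trials[i] for i in tr_idx], [trials[i] for i in te_idx], config
        )
        model = fit_ensemble(
            seq_train, config.grid, cv.inner_folds,
            mrcp_scale=m_scale, erd_scale=e_scale,
        )
        outputs = [detect(model, s) for s in seq_test]
        labels = [s.labels for s in seq_test]
        flags = [trial_correct(o, l) for o, l in zip(outputs, labels)]
        results.append(
            FoldResult(
                [int(i) for i in te_idx],
                outputs,
                labels,
                flags,
                model.summary(),
                model.mrcp_model.weights.copy(),
                model.erd_model.weights.copy(),
            )
        )
    return CVResult(results)


def session_transfer(
    train_trials: list[EpochedTrial],
    test_trials: list[EpochedTrial],
    config: PipelineConfig | None = None,
) -> float:
    """Train (with inner CV) on one session, apply unchanged to another;
    returns the trial-correct percentage on the test session."""
    config = config or PipelineConfig()
    train_trials = [t for t in train_trials if t.kept]
    test_trials = [t for t in test_trials if t.kept]
    if train_trials[0].eeg.shape[0] != test_trials[0].eeg.shape[0]:
        raise ContractError("sessions have different channel counts")
    seq_train, seq_test, m_scale, e_scale, _ = _prepare_fold(
        train_trials, test_trials, config
    )
    model = fit_ensemble(
        seq_train, config.grid, config.cv.inner_folds,
        mrcp_scale=m_scale, erd_scale=e_scale,
    )
    flags = [
        trial_correct(detect(model, s), s.labels) for s in seq_test
    ]
    return 100.0 * float(np.mean(flags))


# ---------------------------------------------------------------------------
# Feature diagnostics
# ---------------------------------------------------------------------------


def r2_pointbiserial(feature: np.ndarray, labels: np.ndarray) -> float:
    """Squared Pearson correlation between a feature and the 0/1 labels;
    zero by convention for constant features."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels).size < 2:
        raise ContractError("both classes must be present")
    if np.std(feature) == 0:
        return 0.0
    r = np.corrcoef(feature, labels)[0, 1]
    return float(r * r)


def feature_consistency(models: Sequence[SLDAModel]) -> np.ndarray:
    """Percentage of models in which each feature carries nonzero weight."""
    W = np.stack([m.weights for m in models])
    return 100.0 * (np.abs(W) > 0).mean(axis=0)


def weight_ratio(ensembles: Sequence[EnsembleModel]) -> float:
    """Sum of |weights| over ERD features divided by the sum over MRCP
    features, aggregated over models; NaN when no MRCP weight survives."""
    erd = sum(np.abs(m.erd_model.weights).sum() for m in ensembles)
    mrcp = sum(np.abs(m.mrcp_model.weights).sum() for m in ensembles)
    if mrcp == 0:
        return float("nan")
    return float(erd / mrcp)


# ---------------------------------------------------------------------------
# Intrinsic Motivation Inventory
# ---------------------------------------------------------------------------


def imi_scores(data: pd.DataFrame) -> pd.DataFrame:
    """Six subscale means per subject-session from 37 Likert items (1-7).

    Reverse-flagged items are mapped ``s -> 8 - s`` before averaging; missing
    items are skipped (mean over answered items).
    """
    item_cols = [c for c in data.columns if c.startswith("item_")]
    vals = data[item_cols].to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 1) & (vals <= 7) & (vals == np.round(vals)))
    if not ok.all():
        raise DataError("item scores must be integers in [1, 7]")
    out = data[[c for c in ("subject", "session") if c in data.columns]].copy()
    for name, items in IMI_SUBSCALES.items():
        cols = []
        for item in items:
            col = data[f"item_{item}"].astype(float)
            if item in IMI_REVERSE_ITEMS:
                col = 8.0 - col
            cols.append(col)
        out[name] = pd.concat(cols, axis=1).mean(axis=1, skipna=True)
    return out


def correlate_performance(
    performance: Sequence[float], scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of detection performance with each IMI subscale,
    with Bonferroni-Holm adjustment across the six subscales."""
    perf = np.asarray(performance, dtype=float)
    if len(perf) < 3:
        raise ContractError("need at least 3 paired observations")
    rows = []
    for name in IMI_SUBSCALES:
        x = scores[name].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(perf) == 0:
            rows.append({"subscale": name, "r": float("nan"),
                         "p_raw": float("nan")})
            continue
        r, p = stats.pearsonr(perf, x)
        rows.append({"subscale": name, "r": float(r), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    valid = df["p_raw"].notna()
    adj = np.full(len(df), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = multipletests(
            df.loc[valid, "p_raw"], method="holm"
        )[1]
    df["p_adjusted"] = adj
    return df
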