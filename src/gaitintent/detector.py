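"""Two-layer sparse discriminant detector of the pre-movement state.

The first layer holds two sparse linear discriminant models (SLDA), one on
MRCP amplitude features and one on mu-band log-power features.  SLDA is
solved in its optimal-scoring form: discriminant estimation is rewritten as
elastic-net regression of class scores onto the features, alternating the
regression and the score re-estimation until the weights settle, which
yields an l1-sparse discriminant direction.  A shared-variance two-Gaussian
model on the projected training scores maps projections to posterior
probabilities (generative, as in classical LDA).  The second layer is a
linear discriminant on the two first-layer probabilities, and a probability
threshold turns the combined posterior into a per-window binary detection,
computed causally (no future windows used).

Hyperparameters (l1, l2 per first-layer model, shared threshold) are chosen
by chronological inner cross-validation maximizing the trial-correct
percentage, with ties broken toward larger l1 (sparser) and larger threshold
(fewer false positives).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import ElasticNet

from .features import WindowSequence, normalize_apply

__all__ = [
    "SLDAModel",
    "EnsembleModel",
    "HyperGrid",
    "fit_slda",
    "slda_proba",
    "fit_ensemble",
    "detect",
]


class ContractError(ValueError):
    pass


@dataclass
class HyperGrid:
    """Search grids for the first-layer penalties and the threshold."""

    l1: tuple[float, ...] = (0.0, 0.001, 0.01, 0.1, 1.0)
    l2: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    threshold: tuple[float, ...] = tuple(
        float(x) for x in np.round(np.arange(0.05, 0.951, 0.05), 2)
    )

    def __post_init__(self) -> None:
        self.l1 = tuple(self.l1)
        self.l2 = tuple(self.l2)
        self.threshold = tuple(self.threshold)
        if not (self.l1 and self.l2 and self.threshold):
            raise ContractError("grids must be nonempty")
        if min(self.l1) < 0 or min(self.l2) < 0:
            raise ContractError("penalties must be >= 0")


@dataclass
class SLDAModel:
    """One sparse discriminant direction with a generative probability map."""

    weights: np.ndarray
    feature_mean: np.ndarray
    l1: float
    l2: float
    proj_mean_rest: float = 0.0
    proj_mean_pre: float = 1.0
    proj_var: float = 1.0
    prior_pre: float = 0.5
    #: True when every weight vanished under the penalty and only the
    #: degenerate-penalty guard kept a single weight alive
    degenerate: bool = False

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.feature_mean) @ self.weights


def _elastic_net_direction(Xc: np.ndarray, z: np.ndarray, l1: float,
                           l2: float) -> np.ndarray:
    """argmin (1/2n)||z - Xc b||^2 + l1 ||b||_1 + (l2/2) ||b||^2."""
    n, p = Xc.shape
    if l1 == 0.0:
        # ridge closed form: (X'X/n + l2 I)^-1 X'z/n
        G = Xc.T @ Xc / n + l2 * np.eye(p)
        return np.linalg.solve(G, Xc.T @ z / n)
    alpha = l1 + l2
    enet = ElasticNet(
        alpha=alpha,
        l1_ratio=l1 / alpha,
        fit_intercept=False,
        max_iter=5000,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Xc, z)
    return enet.coef_.astype(float)


def fit_slda(X: np.ndarray, y: np.ndarray, l1: float = 0.0,
             l2: float = 0.001, max_iter: int = 100,
             tol: float = 1e-6) -> SLDAModel:
    """Two-class sparse discriminant analysis by optimal scoring.

    Alternates (a) elastic-net regression of the current class scores onto
    the centered features and (b) re-estimation of the optimal scores, until
    the weight change drops below ``tol`` or ``max_iter`` sweeps.  If every
    weight is shrunk to zero, the single largest-magnitude pre-thresholding
    weight is kept so the model stays usable (degenerate-penalty guard).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ContractError("both classes must be present")
    n = len(y)
    mask1 = y == classes.max()
    n0, n1 = int((~mask1).sum()), int(mask1.sum())
    mean = X.mean(axis=0)
    Xc = X - mean

    # optimal scores for two classes: theta with sum pi_k theta_k = 0,
    # sum pi_k theta_k^2 = 1
    theta0, theta1 = -np.sqrt(n1 / (n0 * n)), np.sqrt(n0 / (n1 * n))
    z = np.where(mask1, theta1, theta0) * np.sqrt(n)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        beta_new = _elastic_net_direction(Xc, z, l1, l2)
        # score re-estimation: for 2 classes the optimal scores keep their
        # direction, at most flipping sign with the fit; renormalize
        proj = Xc @ beta_new
        m0, m1 = proj[~mask1].mean(), proj[mask1].mean()
        if m1 < m0:  # orient the direction toward the positive class
            beta_new = -beta_new
        if np.linalg.norm(beta_new - beta) < tol * max(1.0, np.linalg.norm(beta_new)):
            beta = beta_new
            break
        beta = beta_new

    degenerate = False
    if not np.any(beta):
        # keep the largest pre-thresholding weight at its unpenalized-l1
        # (univariate ridge) value so its scale stays comparable
        corr = Xc.T @ z / n
        j = int(np.argmax(np.abs(corr)))
        beta = np.zeros_like(beta)
        beta[j] = corr[j] / ((Xc[:, j] ** 2).mean() + l2)
        degenerate = True
        warnings.warn("all SLDA weights vanished under the penalty; keeping "
                      "the largest pre-thresholding weight", stacklevel=2)

    proj = Xc @ beta
    p0, p1 = proj[~mask1], proj[mask1]
    var = (p0.var(ddof=0) * n0 + p1.var(ddof=0) * n1) / n
    return SLDAModel(
        weights=beta,
        feature_mean=mean,
        l1=l1,
        l2=l2,
        proj_mean_rest=float(p0.mean()),
        proj_mean_pre=float(p1.mean()),
        proj_var=float(max(var, 1e-18)),
        prior_pre=n1 / n,
        degenerate=degenerate,
    )


def slda_proba(model: SLDAModel, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the pre-movement class per window.

    Shared-variance Gaussians with empirical priors on the projection; the
    output is monotone in the projected score.
    """
    s = model.project(X)
    v = model.proj_var
    d0 = (s - model.proj_mean_rest) ** 2 / (2 * v)
    d1 = (s - model.proj_mean_pre) ** 2 / (2 * v)
    log_odds = (d0 - d1) + np.log(model.prior_pre / (1 - model.prior_pre))
    return 1.0 / (1.0 + np.exp(-np.clip(log_odds, -500, 500)))


@dataclass
class EnsembleModel:
    """Two first-layer SLDA models, a 2-input linear discriminant combiner
    and the detection threshold."""

    mrcp_model: SLDAModel
    erd_model: SLDAModel
    second_layer: LinearDiscriminantAnalysis
    probability_threshold: float
    mrcp_scale: np.ndarray | None = None
    erd_scale: np.ndarray | None = None
    inner_score: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ContractError("threshold must lie in [0, 1]")

    def window_proba(self, seq: WindowSequence) -> np.ndarray:
        Xm, Xe = seq.mrcp, seq.erd
        if self.mrcp_scale is not None:
            Xm = normalize_apply(self.mrcp_scale, Xm)
        if self.erd_scale is not None:
            Xe = normalize_apply(self.erd_scale, Xe)
        p = np.column_stack(
            [slda_proba(self.mrcp_model, Xm), slda_proba(self.erd_model, Xe)]
        )
        return self.second_layer.predict_proba(p)[:, 1]

    def summary(self) -> dict:
        return {
            "mrcp": {"l1": self.mrcp_model.l1, "l2": self.mrcp_model.l2,
                     "n_nonzero": self.mrcp_model.n_nonzero},
            "erd": {"l1": self.erd_model.l1, "l2": self.erd_model.l2,
                    "n_nonzero": self.erd_model.n_nonzero},
            "threshold": self.probability_threshold,
            "inner_score": self.inner_score,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        lda = self.second_layer
        Path(path).write_text(json.dumps({
            "mrcp_weights": self.mrcp_model.weights.tolist(),
            "erd_weights": self.erd_model.weights.tolist(),
            "threshold": self.probability_threshold,
            "summary": self.summary(),
            "second_layer": {
                "coef": lda.coef_.tolist(),
                "intercept": lda.intercept_.tolist(),
            },
        }))


def _trial_correct_flags(per_trial_pred: list[np.ndarray],
                         per_trial_labels: list[np.ndarray]) -> np.ndarray:
    from .evaluation import trial_correct

    return np.array([
        trial_correct(p, l) for p, l in zip(per_trial_pred, per_trial_labels)
    ])


def _inner_folds(n: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    from .evaluation import chronological_folds

    return chronological_folds(n, min(k, n))


def _stack(seqs: Sequence[WindowSequence], attr: str) -> np.ndarray:
    return np.concatenate([getattr(s, attr) for s in seqs])


def fit_ensemble(
    train: Sequence[WindowSequence],
    grid: HyperGrid | None = None,
    inner_folds: int = 5,
    mrcp_scale: np.ndarray | None = None,
    erd_scale: np.ndarray | None = None,
) -> EnsembleModel:
    """Fit the two-layer detector with chronological inner cross-validation.

    Per first-layer model, (l1, l2) is chosen to maximize the mean inner
    trial-correct percentage of that layer alone (over its best threshold);
    the second layer is then fitted on the two first-layer out-of-fold
    probabilities, and the shared probability threshold maximizes the inner
    ensemble trial-correct percentage.  Ties prefer larger l1, then larger
    threshold.  The first-layer models are refitted on all training windows.
    """
    grid = grid or HyperGrid()
    train = list(train)
    if len(train) < 2:
        raise ContractError("need at least two training trials")
    folds = _inner_folds(len(train), inner_folds)

    def seq_feats(seq: WindowSequence, which: str) -> np.ndarray:
        X = seq.mrcp if which == "mrcp" else seq.erd
        scale = mrcp_scale if which == "mrcp" else erd_scale
        return normalize_apply(scale, X) if scale is not None else X

    labels = [s.labels for s in train]
    thr_grid = sorted(grid.threshold)

    best: dict[str, tuple[float, float]] = {}
    oof: dict[str, list[np.ndarray]] = {}
    val_order: list[int] = []
    usable_folds = []
    for tr_idx, va_idx in folds:
        y_tr = np.concatenate([labels[i] for i in tr_idx])
        if np.unique(y_tr).size < 2:
            warnings.warn("inner fold lacks a class; skipped", stacklevel=2)
            continue
        usable_folds.append((tr_idx, va_idx))
    if not usable_folds:
        raise ContractError("no usable inner folds")
    for _, va_idx in usable_folds:
        val_order.extend(int(i) for i in va_idx)

    for which in ("mrcp", "erd"):
        per_combo: dict[tuple[float, float], list[list[np.ndarray]]] = {}
        combo_ok: dict[tuple[float, float], bool] = {}
        for l1 in grid.l1:
            for l2 in grid.l2:
                combo_probs: list[list[np.ndarray]] = []
                ok = True
                for tr_idx, va_idx in usable_folds:
                    X_tr = np.concatenate([seq_feats(train[i], which) for i in tr_idx])
                    y_tr = np.concatenate([labels[i] for i in tr_idx])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m = fit_slda(X_tr, y_tr, l1, l2)
                    ok = ok and not m.degenerate
                    combo_probs.append(
                        [slda_proba(m, seq_feats(train[i], which)) for i in va_idx]
                    )
                per_combo[(l1, l2)] = combo_probs
                combo_ok[(l1, l2)] = ok

        # pick (l1, l2) by the layer's own best-threshold inner performance;
        # at equal score a combo whose fits never collapsed to the all-zero
        # guard outranks a degenerate one, then larger penalties win
        best_key, best_combo = None, None
        for l1 in grid.l1:
            for l2 in grid.l2:
                probs = per_combo[(l1, l2)]
                score, _ = _best_threshold_score(
                    probs, usable_folds, labels, thr_grid
                )
                key = (score, combo_ok[(l1, l2)], (l1, l2))
                if best_key is None or key > best_key:
                    best_key, best_combo = key, (l1, l2)
        best[which] = best_combo
        oof[which] = [p for fold in per_combo[best_combo] for p in fold]

    # second layer on out-of-fold first-layer probabilities
    P_oof = np.column_stack(
        [np.concatenate(oof["mrcp"]), np.concatenate(oof["erd"])]
    )
    y_oof = np.concatenate([labels[i] for i in val_order])
    lda = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(P_oof, y_oof)

    # shared threshold on the ensemble out-of-fold probability
    p_ens = lda.predict_proba(P_oof)[:, 1]
    per_trial, pos = [], 0
    for i in val_order:
        n_w = len(labels[i])
        per_trial.append(p_ens[pos : pos + n_w])
        pos += n_w
    best_thr, best_thr_score = thr_grid[-1], -1.0
    for thr in thr_grid:
        preds = [(p > thr).astype(int) for p in per_trial]
        flags = _trial_correct_flags(preds, [labels[i] for i in val_order])
        score = 100.0 * flags.mean()
        if score >= best_thr_score:  # ties -> larger threshold
            best_thr_score, best_thr = score, thr

    X_all_m = np.concatenate([seq_feats(s, "mrcp") for s in train])
    X_all_e = np.concatenate([seq_feats(s, "erd") for s in train])
    y_all = np.concatenate(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mrcp_model = fit_slda(X_all_m, y_all, *best["mrcp"])
        erd_model = fit_slda(X_all_e, y_all, *best["erd"])
    return EnsembleModel(
        mrcp_model,
        erd_model,
        lda,
        float(best_thr),
        mrcp_scale=mrcp_scale,
        erd_scale=erd_scale,
        inner_score=best_thr_score,
    )


def _best_threshold_score(
    combo_probs: list[list[np.ndarray]],
    usable_folds: list,
    labels: list[np.ndarray],
    thr_grid: list[float],
) -> tuple[float, float]:
    """Best mean trial-correct percentage over the threshold grid (ties ->
    larger threshold); returns (score, threshold)."""
    best_score, best_thr = -1.0, thr_grid[-1]
    va_labels = [
        labels[i] for (_, va_idx) in usable_folds for i in va_idx
    ]
    flat = [p for fold in combo_probs for p in fold]
    for thr in thr_grid:
        preds = [(p > thr).astype(int) for p in flat]
        flags = _trial_correct_flags(preds, va_labels)
        score = 100.0 * flags.mean()
        if score >= best_score:
            best_score, best_thr = score, thr
    return best_score, best_thr


def detect(model: EnsembleModel, sequence: WindowSequence) -> np.ndarray:
    """Binary output per window: 1 iff the combined second-layer posterior
    exceeds the threshold.  Each window depends only on its own features."""
    p = model.window_proba(sequence)
    return (p > model.probability_threshold).astype(int)
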