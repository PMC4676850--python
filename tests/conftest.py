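"""Shared fixtures: synthetic sessions at two scales.

The small session (10 trials) exercises contracts cheaply; the benchmark
session uses the full default protocol (5 phases x 20 trials) and default
signal model, shared across the heavy end-to-end tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gaitintent import emg_onset, synthetic_data as sd
from gaitintent.core_io import PipelineConfig
from gaitintent.detector import HyperGrid


@pytest.fixture(scope="session")
def small_protocol() -> sd.ProtocolParams:
    return sd.ProtocolParams(n_phases=2, trials_per_phase=5,
                             relax_duration_s=9.0, relax_jitter_s=0.5)


@pytest.fixture(scope="session")
def small_session(small_protocol):
    return sd.generate_session(small_protocol, seed=42)


@pytest.fixture(scope="session")
def small_trials(small_session):
    rec, _ = small_session
    return emg_onset.epoch_trials(rec, emg_onset.compute_onsets(rec))


@pytest.fixture(scope="session")
def bench_session():
    """Default-parameter 100-trial session (the high-SNR benchmark)."""
    return sd.generate_session(seed=11)


@pytest.fixture(scope="session")
def bench_trials(bench_session):
    rec, _ = bench_session
    return emg_onset.epoch_trials(rec, emg_onset.compute_onsets(rec))


@pytest.fixture(scope="session")
def bench_cv(bench_trials):
    """Nested chronological CV on the benchmark session (shared: expensive)."""
    from gaitintent.evaluation import run_nested_cv

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_nested_cv(bench_trials, PipelineConfig())


@pytest.fixture()
def reduced_grid() -> HyperGrid:
    """Small hyperparameter grid for fast ensemble fits in unit tests."""
    return HyperGrid(l1=(0.0, 0.01), l2=(0.01,),
                     threshold=(0.2, 0.5, 0.8, 0.95))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
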