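"""Data model, file I/O and configuration for the walking-intention pipeline.

Signals travel as microvolt arrays of shape ``(n_channels, n_samples)`` on a
shared time axis (seconds from recording start, 0-based sample indices,
half-open ``[start, end)`` intervals).  The on-disk container is EDF+C with an
annotation track for the cue events; a plain CSV bundle (one delimited file
per signal block plus an events table) is supported for transparency.  Ground
truth for simulated sessions always lives in a JSON sidecar, never inside the
EDF.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EEG_CHANNELS_30",
    "ANALYSIS_CHANNELS",
    "EVENT_KINDS",
    "IMI_SUBSCALES",
    "IMI_REVERSE_ITEMS",
    "ConfigurationError",
    "FormatError",
    "AcquisitionConfig",
    "Event",
    "SessionRecording",
    "PipelineConfig",
    "read_session",
    "write_session",
    "run_cli",
    "load_config",
    "save_config",
]

#: 30-channel 10/10 montage of the recording cap.
EEG_CHANNELS_30 = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1",
    "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2",
    "CP6", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
)

#: The ten channels over pre/post-central sensorimotor cortex used for features.
ANALYSIS_CHANNELS = ("F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2")

EVENT_KINDS = ("relax_cue", "walk_cue", "phase_break")

#: Intrinsic Motivation Inventory: the six subscales in use, item count 37.
#: The published inventory lists only subscale names; this item->subscale map
#: ships as editable data (items are 1-based column names ``item_1..item_37``).
IMI_SUBSCALES: dict[str, tuple[int, ...]] = {
    "interest_enjoyment": (1, 2, 3, 4, 5, 6, 7),
    "perceived_competence": (8, 9, 10, 11, 12, 13),
    "effort_importance": (14, 15, 16, 17, 18),
    "pressure_tension": (19, 20, 21, 22, 23),
    "perceived_choice": (24, 25, 26, 27, 28, 29, 30),
    "value_usefulness": (31, 32, 33, 34, 35, 36, 37),
}

#: Items scored in the negative direction (mapped s -> 8 - s before averaging).
IMI_REVERSE_ITEMS: tuple[int, ...] = (4, 15, 18, 19, 22, 25, 27, 29)


class ConfigurationError(ValueError):
    """Raised when a configuration or file is inconsistent with the montage."""


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionConfig:
    """Recording montage and rate.

    Defaults follow the study protocol: 256 Hz, 30 EEG channels on the 10/10
    system referenced to linked ears, and two bipolar EMG channels over the
    left/right tibialis anterior.
    """

    sampling_rate: float = 256.0
    eeg_channel_names: tuple[str, ...] = EEG_CHANNELS_30
    emg_channel_names: tuple[str, ...] = ("EMG_TA_left", "EMG_TA_right")
    reference_scheme: str = "linked_ears"

    def __post_init__(self) -> None:
        self.eeg_channel_names = tuple(self.eeg_channel_names)
        self.emg_channel_names = tuple(self.emg_channel_names)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(set(self.eeg_channel_names)) != len(self.eeg_channel_names):
            raise ConfigurationError("EEG channel names must be unique")
        missing = [c for c in ANALYSIS_CHANNELS if c not in self.eeg_channel_names]
        if missing:
            raise ConfigurationError(
                f"montage lacks required analysis channel(s): {', '.join(missing)}"
            )

    def analysis_indices(self) -> np.ndarray:
        return np.array([self.eeg_channel_names.index(c) for c in ANALYSIS_CHANNELS])


@dataclass(frozen=True)
class Event:
    time: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise FormatError(f"unknown event kind {self.kind!r}")


@dataclass
class SessionRecording:
    """One subject-session of raw EEG + EMG with cue events.

    ``eeg`` and ``emg`` are microvolt arrays sharing the time axis; events are
    strictly increasing in time, and each trial is a ``relax_cue`` followed by
    a ``walk_cue``.
    """

    eeg: np.ndarray
    emg: np.ndarray
    events: list[Event]
    subject_id: str = "S01"
    session_index: int = 1
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.acquisition.sampling_rate

    def trial_cues(self) -> list[tuple[float, float]]:
        """Pairs of (relax_cue, walk_cue) times, one per trial, in order."""
        pairs: list[tuple[float, float]] = []
        pending: float | None = None
        for ev in self.events:
            if ev.kind == "relax_cue":
                pending = ev.time
            elif ev.kind == "walk_cue":
                if pending is None:
                    raise FormatError("walk_cue without a preceding relax_cue")
                pairs.append((pending, ev.time))
                pending = None
        return pairs

    def validate(self) -> None:
        if self.eeg.ndim != 2 or self.emg.ndim != 2:
            raise FormatError("eeg and emg must be 2-D (channels x samples)")
        if self.eeg.shape[0] != len(self.acquisition.eeg_channel_names):
            raise ConfigurationError(
                f"expected {len(self.acquisition.eeg_channel_names)} EEG channels, "
                f"got {self.eeg.shape[0]}"
            )
        if self.emg.shape[0] != len(self.acquisition.emg_channel_names):
            raise ConfigurationError("EMG channel count does not match montage")
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise FormatError("eeg and emg must share the time axis")
        times = [ev.time for ev in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise FormatError("events must be strictly increasing in time")
        self.trial_cues()  # raises on unpaired cues


# ---------------------------------------------------------------------------
# EDF+C writer (16-bit); reading goes through MNE
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _physical_range(x: np.ndarray) -> tuple[float, float]:
    """Physical min/max with 5 % headroom around the data range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-6)
    lo -= 0.05 * span
    hi += 0.05 * span
    return lo, hi


def _write_edf(rec: SessionRecording, path: Path) -> None:
    fs = rec.acquisition.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    fs_i = int(round(fs))
    data = np.vstack([rec.eeg, rec.emg])
    labels = list(rec.acquisition.eeg_channel_names) + list(
        rec.acquisition.emg_channel_names
    )
    n_records = math.ceil(data.shape[1] / fs_i)
    padded = np.zeros((data.shape[0], n_records * fs_i))
    padded[:, : data.shape[1]] = data
    # pad with the final sample value to avoid step discontinuities
    if data.shape[1] < padded.shape[1]:
        padded[:, data.shape[1]:] = data[:, -1:]

    # Timestamp + event TALs per record.
    tals: list[bytes] = []
    ev_by_record: dict[int, list[Event]] = {}
    for ev in rec.events:
        ev_by_record.setdefault(min(int(ev.time), n_records - 1), []).append(ev)
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for ev in ev_by_record.get(r, []):
            tal += f"+{ev.time:.4f}\x14{ev.kind}\x14\x00".encode("ascii")
        tals.append(tal)
    ann_bytes = max(max(len(t) for t in tals) + 2, 60)
    ann_samples = (ann_bytes + 1) // 2  # 2 bytes per 16-bit sample

    n_sig = len(labels) + 1
    header_bytes = 256 * (n_sig + 1)

    phys = [_physical_range(padded[i]) for i in range(len(labels))]
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field(f"Startdate X X X X {rec.subject_id}", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(header_bytes), 8))
        f.write(_edf_field("EDF+C", 44))
        f.write(_edf_field(str(n_records), 8))
        f.write(_edf_field("1", 8))
        f.write(_edf_field(str(n_sig), 4))

        all_labels = labels + ["EDF Annotations"]
        for lab in all_labels:
            f.write(_edf_field(lab, 16))
        for _ in all_labels:
            f.write(_edf_field("", 80))
        for i in range(n_sig):
            f.write(_edf_field("uV" if i < len(labels) else "", 8))
        for i in range(n_sig):
            f.write(_edf_field(f"{phys[i][0]:.8g}"[:8] if i < len(labels) else "-1", 8))
        for i in range(n_sig):
            f.write(_edf_field(f"{phys[i][1]:.8g}"[:8] if i < len(labels) else "1", 8))
        for _ in range(n_sig):
            f.write(_edf_field(str(dig_min), 8))
        for _ in range(n_sig):
            f.write(_edf_field(str(dig_max), 8))
        for _ in range(n_sig):
            f.write(_edf_field("", 80))
        for i in range(n_sig):
            f.write(_edf_field(str(fs_i if i < len(labels) else ann_samples), 8))
        for _ in range(n_sig):
            f.write(_edf_field("", 32))

        # physical min strings were truncated to 8 chars; recompute the exact
        # values the header now declares so quantization matches on read-back
        hdr_phys = [
            (float(f"{lo:.8g}"[:8]), float(f"{hi:.8g}"[:8])) for lo, hi in phys
        ]
        for r in range(n_records):
            for i in range(len(labels)):
                lo, hi = hdr_phys[i]
                seg = padded[i, r * fs_i : (r + 1) * fs_i]
                dig = np.round(
                    (seg - lo) / (hi - lo) * (dig_max - dig_min) + dig_min
                ).astype("<i2")
                f.write(dig.tobytes())
            tal = tals[r].ljust(2 * ann_samples, b"\x00")
            f.write(tal)


def _read_edf(path: Path, acq: AcquisitionConfig) -> SessionRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [
        c
        for c in list(acq.eeg_channel_names) + list(acq.emg_channel_names)
        if c not in raw.ch_names
    ]
    if missing:
        raise ConfigurationError(f"file lacks channel(s): {', '.join(missing)}")
    fs = float(raw.info["sfreq"])
    get = lambda names: np.vstack(
        [raw.get_data(picks=[raw.ch_names.index(c)])[0] for c in names]
    )
    eeg = get(acq.eeg_channel_names) * 1e6  # MNE loads EDF 'uV' channels as volts
    emg = get(acq.emg_channel_names) * 1e6
    events: list[Event] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in EVENT_KINDS:
            events.append(Event(float(onset), str(desc)))
    events.sort(key=lambda e: e.time)
    times = [e.time for e in events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise FormatError("non-monotone event track")
    acq2 = dataclasses.replace(acq, sampling_rate=fs)
    subject = "S01"
    meta_path = Path(str(path) + ".meta.json")
    session_index = 1
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        subject = meta.get("subject_id", subject)
        session_index = meta.get("session_index", session_index)
    return SessionRecording(eeg, emg, events, subject, session_index, acq2)


# ---------------------------------------------------------------------------
# CSV bundle
# ---------------------------------------------------------------------------


def _write_csv_bundle(rec: SessionRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.eeg.T, columns=list(rec.acquisition.eeg_channel_names)).to_csv(
        path / "eeg.csv", index=False
    )
    pd.DataFrame(rec.emg.T, columns=list(rec.acquisition.emg_channel_names)).to_csv(
        path / "emg.csv", index=False
    )
    pd.DataFrame(
        {"time": [e.time for e in rec.events], "kind": [e.kind for e in rec.events]}
    ).to_csv(path / "events.csv", index=False)
    (path / "meta.json").write_text(
        json.dumps(
            {
                "sampling_rate": rec.acquisition.sampling_rate,
                "subject_id": rec.subject_id,
                "session_index": rec.session_index,
                "reference_scheme": rec.acquisition.reference_scheme,
            },
            indent=1,
        )
    )


def _read_csv_bundle(path: Path, acq: AcquisitionConfig) -> SessionRecording:
    meta = json.loads((path / "meta.json").read_text())
    eeg_df = pd.read_csv(path / "eeg.csv")
    emg_df = pd.read_csv(path / "emg.csv")
    missing = [c for c in acq.eeg_channel_names if c not in eeg_df.columns]
    missing += [c for c in acq.emg_channel_names if c not in emg_df.columns]
    if missing:
        raise ConfigurationError(f"file lacks channel(s): {', '.join(missing)}")
    ev_df = pd.read_csv(path / "events.csv")
    events = [Event(float(t), str(k)) for t, k in zip(ev_df["time"], ev_df["kind"])]
    acq2 = dataclasses.replace(acq, sampling_rate=float(meta["sampling_rate"]))
    return SessionRecording(
        eeg_df[list(acq.eeg_channel_names)].to_numpy().T,
        emg_df[list(acq.emg_channel_names)].to_numpy().T,
        events,
        meta.get("subject_id", "S01"),
        int(meta.get("session_index", 1)),
        acq2,
    )


def write_session(
    rec: SessionRecording, path: str | os.PathLike, format: str = "edf"
) -> None:
    """Write a session to ``path`` as EDF+C (16-bit) or a CSV bundle.

    EDF quantizes to 16 bits between per-channel physical limits set from the
    data range with 5 % headroom; the CSV bundle is lossless.
    """
    rec.validate()
    if rec.eeg.shape[0] == 0:
        raise ConfigurationError("EEG channels are required")
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
        Path(str(path) + ".meta.json").write_text(
            json.dumps(
                {"subject_id": rec.subject_id, "session_index": rec.session_index}
            )
        )
    elif format in ("csv", "csv-bundle"):
        _write_csv_bundle(rec, path)
    else:
        raise FormatError(f"unknown format {format!r}")


def read_session(
    path: str | os.PathLike,
    format: str = "edf",
    acquisition: AcquisitionConfig | None = None,
) -> SessionRecording:
    """Read a session written by :func:`write_session`."""
    acq = acquisition or AcquisitionConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        return _read_edf(path, acq)
    if format in ("csv", "csv-bundle"):
        return _read_csv_bundle(path, acq)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Pipeline configuration (YAML)
# ---------------------------------------------------------------------------


def _lazy(modname: str, clsname: str):
    def factory():
        import importlib

        mod = importlib.import_module(f"gaitintent.{modname}")
        return getattr(mod, clsname)()

    return factory


@dataclass
class PipelineConfig:
    """Nested configuration for every pipeline stage plus the master seed."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    protocol: "object" = field(default_factory=_lazy("synthetic_data", "ProtocolParams"))
    signal_model: "object" = field(
        default_factory=_lazy("synthetic_data", "SignalModelParams")
    )
    onset: "object" = field(default_factory=_lazy("emg_onset", "OnsetParams"))
    artifact: "object" = field(default_factory=_lazy("artifact_rejection", "ArtifactParams"))
    mrcp: "object" = field(default_factory=_lazy("neurophys", "MRCPParams"))
    erd: "object" = field(default_factory=_lazy("neurophys", "ERDParams"))
    feature: "object" = field(default_factory=_lazy("features", "FeatureParams"))
    cv: "object" = field(default_factory=_lazy("evaluation", "CVParams"))
    grid: "object" = field(default_factory=_lazy("detector", "HyperGrid"))
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_config(cfg: PipelineConfig, path: str | os.PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def run_cli(argv: list[str] | None = None) -> int:
    """Entry point of the command-line interface (see :mod:`gaitintent.cli`)."""
    from .cli import run_cli as _run

    return _run(argv)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    from gaitintent import artifact_rejection, detector, emg_onset, evaluation
    from gaitintent import features as features_mod
    from gaitintent import neurophys, synthetic_data

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")

    classes = {
        "acquisition": AcquisitionConfig,
        "protocol": synthetic_data.ProtocolParams,
        "signal_model": synthetic_data.SignalModelParams,
        "onset": emg_onset.OnsetParams,
        "artifact": artifact_rejection.ArtifactParams,
        "mrcp": neurophys.MRCPParams,
        "erd": neurophys.ERDParams,
        "feature": features_mod.FeatureParams,
        "cv": evaluation.CVParams,
        "grid": detector.HyperGrid,
    }
    kwargs = {}
    for key, cls in classes.items():
        if key in raw:
            sub = raw[key]
            if not isinstance(sub, dict):
                raise ConfigurationError(f"config section {key!r} must be a mapping")
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(sub) - fields
            if unknown:
                raise ConfigurationError(
                    f"unknown option(s) in {key!r}: {', '.join(sorted(unknown))}"
                )
            # YAML round-trips tuples as lists; dataclass __post_init__ fixes types
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            kwargs[key] = cls(**sub)
    if "seed" in raw:
        kwargs["seed"] = raw["seed"]
    return PipelineConfig(**kwargs)
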