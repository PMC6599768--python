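"""Recording containers and run configuration.

Recordings travel as self-describing HDF5 files: per-channel float arrays
plus a JSON sidecar attribute holding sample rate, channel labels, events
and metadata.  A write -> read round-trip is bit-exact.  Real EDF recordings
can be imported onto the same Recording contract (import only; the
environment ships no EDF writer).

The run configuration is a plain YAML document with full defaults; unknown
keys are rejected loudly so a config file plus a seed fully reproduces a
run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .preprocess import PreprocessConfig
from .synthetic import Recording

_FORMAT = "fpvs-recording-v1"


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["sample_rate"] = float(recording.sample_rate)
        f.attrs["channel_labels"] = json.dumps(list(recording.channel_labels))
        f.attrs["metadata"] = json.dumps(recording.metadata, default=str)
        f.create_dataset("data", data=recording.data)
        f.create_dataset(
            "event_samples", data=np.array([i for i, _ in recording.events], dtype=np.int64)
        )
        f.create_dataset(
            "event_codes",
            data=np.array([c for _, c in recording.events], dtype=object),
            dtype=h5py.string_dtype(),
        )


def read_recording(path: str | Path) -> Recording:
    """Read a recording container, validating its structure."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in ("sample_rate", "channel_labels", "metadata"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: container missing required field {attr!r}")
        for ds in ("data", "event_samples", "event_codes"):
            if ds not in f:
                raise ValueError(f"{path}: container missing dataset {ds!r}")
        labels = tuple(json.loads(f.attrs["channel_labels"]))
        data = f["data"][()]
        if data.ndim != 2 or data.shape[0] != len(labels):
            raise ValueError(
                f"{path}: data has {data.shape[0] if data.ndim == 2 else '?'} rows "
                f"but {len(labels)} channel labels"
            )
        samples = f["event_samples"][()]
        codes = [c.decode() if isinstance(c, bytes) else str(c) for c in f["event_codes"][()]]
        if len(samples) != len(codes):
            raise ValueError(f"{path}: event samples/codes length mismatch")
        return Recording(
            sample_rate=float(f.attrs["sample_rate"]),
            channel_labels=labels,
            data=data,
            events=list(zip((int(s) for s in samples), codes)),
            metadata=json.loads(f.attrs["metadata"]),
        )


def read_recording_edf(path: str | Path) -> Recording:
    """Import an EDF file onto the Recording contract (µV, annotations->events)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    events = []
    for ann in raw.annotations:
        idx = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= idx < data.shape[1]:
            events.append((idx, str(ann["description"])))
    return Recording(
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        data=data,
        events=events,
        metadata={"source": str(path), "format": "edf"},
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationSettings:
    """Scalar knobs of the synthetic study exposed in the run config."""

    n_subjects: int = 16
    n_sequences_per_condition: int = 4
    n_identities: int = 6
    steady_duration: float = 70.0
    sample_rate: float = 512.0
    noise_rms: float = 5.0
    noise_exponent: float = 1.0
    oddball_attenuation: float = 0.2
    base_amplitude_scale: float = 1.0
    oddball_amplitude_scale: float = 1.0
    conditions: list[str] = field(default_factory=lambda: ["upright", "inverted"])


@dataclass
class AnalysisSettings:
    per_side: int = 10                 # noise bins per side
    z_threshold: float = 3.1           # one-tailed p < 0.001 under normality
    harmonic_cap: float = 20.0         # Hz, scan limit for harmonic selection
    stop_rule: str = "scan-to-limit"   # or "consecutive"
    excluded_multiples: int = 7        # base-rate overlap in oddball harmonics
    oddball_harmonics: list[int] | str = field(
        default_factory=lambda: [1, 2, 3, 4, 5, 6, 8, 9]
    )                                  # fixed set, or "auto" for grand-average selection
    base_harmonics: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    per_identity: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fpvs-run"
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sections = {
            "simulation": SimulationSettings,
            "preprocess": PreprocessConfig,
            "analysis": AnalysisSettings,
        }
        kwargs: dict = {}
        for name, typ in sections.items():
            sub = raw.pop(name, {})
            _check_keys(sub, typ, name)
            kwargs[name] = typ(**sub)
        _check_keys(raw, cls, "top level", skip=set(sections))
        kwargs.update(raw)
        return cls(**kwargs)


def _check_keys(raw: dict, typ: type, where: str, skip: set[str] = frozenset()) -> None:
    known = {f.name for f in dataclasses.fields(typ)} | set(skip)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) at {where}: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_dict(raw)
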