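"""Preprocessing for frequency-tagged EEG.

Fixed stage order: band-pass filter -> segment into sequence epochs ->
downsample -> repair bad channels -> common-average re-reference -> crop to
an exact integer number of oddball cycles.  The final crop guarantees that
both the base and oddball stimulation frequencies fall exactly on FFT bins,
which is what makes the narrow-band spectral quantification leakage-free.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal

from . import montage
from .synthetic import (
    EVENT_SEQ_OFF,
    EVENT_SEQ_ON,
    EVENT_STEADY_ON,
    Recording,
)


@dataclass
class PreprocessConfig:
    bandpass_low: float = 0.1        # Hz, high-pass corner
    bandpass_high: float = 100.0     # Hz, low-pass corner
    filter_order: int = 4            # per edge, applied forward-backward
    epoch_pre: float = 2.0           # s retained before each sequence onset
    epoch_post: float = 2.0          # s retained after each sequence offset
    target_rate: float = 256.0       # Hz after downsampling
    bad_channel_threshold: float = 100.0  # µV absolute deflection
    max_bad_fraction: float = 0.05   # of scalp channels
    min_bad_sequences: int = 2       # epochs a channel must exceed threshold in
    interp_neighbors: int = 4        # nearest good channels used for repair
    crop_reference: str = EVENT_STEADY_ON
    crop_cycles_frequency: float = 6.0 / 7.0  # Hz, oddball fundamental

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.bandpass_high >= self.target_rate / 2:
            raise ValueError(
                f"bandpass_high={self.bandpass_high} Hz must stay below the "
                f"target Nyquist {self.target_rate / 2} Hz"
            )
        if not (0 < self.max_bad_fraction < 1):
            raise ValueError("max_bad_fraction must be in (0, 1)")


#: An epoch is a fixed-duration recording segment aligned to a sequence onset.
Epoch = Recording


class TooManyBadChannels(RuntimeError):
    """More channels exceed the artifact threshold than may be repaired."""


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def bandpass_filter(recording: Recording, config: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth band-pass (high-pass + low-pass cascade).

    Each corner is a ``filter_order``-th order Butterworth section applied
    forward-backward (zero phase), so the effective attenuation is the
    squared one-pass magnitude.  In-band amplitudes are preserved to within
    the design's passband ripple; DC is removed by the high-pass edge.
    """
    nyq = recording.sample_rate / 2
    if config.bandpass_high >= nyq:
        raise ValueError(
            f"low-pass corner {config.bandpass_high} Hz >= Nyquist {nyq} Hz"
        )
    hp = scipy.signal.butter(
        config.filter_order, config.bandpass_low, "highpass",
        fs=recording.sample_rate, output="sos",
    )
    lp = scipy.signal.butter(
        config.filter_order, config.bandpass_high, "lowpass",
        fs=recording.sample_rate, output="sos",
    )
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    data = scipy.signal.sosfiltfilt(hp, data, axis=1)
    data = scipy.signal.sosfiltfilt(lp, data, axis=1)
    return dataclasses.replace(recording, data=data, events=list(recording.events))


def segment_epochs(recording: Recording, config: PreprocessConfig) -> list[Epoch]:
    """Cut one epoch per sequence-onset event, with pre/post context.

    Each epoch runs from ``epoch_pre`` s before a ``SEQ_ON`` event to
    ``epoch_post`` s after the matching ``SEQ_OFF`` event.  Epochs that would
    extend past the recorded data are rejected with a warning rather than
    silently shortened.
    """
    fs = recording.sample_rate
    n_pre = round(config.epoch_pre * fs)
    n_post = round(config.epoch_post * fs)
    offs = recording.events_of(EVENT_SEQ_OFF)
    epochs: list[Epoch] = []
    for onset in recording.events_of(EVENT_SEQ_ON):
        later = [o for o in offs if o > onset]
        if not later:
            warnings.warn(f"SEQ_ON at sample {onset} has no matching SEQ_OFF; skipped")
            continue
        off = later[0]
        start, stop = onset - n_pre, off + n_post
        if start < 0 or stop > recording.n_samples:
            warnings.warn(
                f"epoch around SEQ_ON at sample {onset} would span "
                f"[{start}, {stop}) outside the recording; rejected"
            )
            continue
        events = [
            (i - start, c) for i, c in recording.events if start <= i < stop
        ]
        epochs.append(
            Recording(
                sample_rate=fs,
                channel_labels=recording.channel_labels,
                data=recording.data[:, start:stop].copy(),
                events=events,
                metadata=dict(recording.metadata),
            )
        )
    return epochs


def downsample(epoch: Epoch, target_rate: float) -> Epoch:
    """Decimate to ``target_rate`` by keeping every ``factor``-th sample.

    The data must already be low-passed below the target Nyquist (the
    band-pass stage guarantees this), so no extra anti-alias filter is
    applied.  Event indices are rescaled to the new rate.
    """
    ratio = epoch.sample_rate / target_rate
    factor = round(ratio)
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"sample rate {epoch.sample_rate} Hz is not an integer multiple "
            f"of target rate {target_rate} Hz"
        )
    if factor == 1:
        return dataclasses.replace(
            epoch, data=epoch.data.copy(), events=list(epoch.events)
        )
    data = epoch.data[:, ::factor].copy()
    events = [
        (min(round(i / factor), data.shape[1] - 1), c) for i, c in epoch.events
    ]
    return Recording(
        sample_rate=target_rate,
        channel_labels=epoch.channel_labels,
        data=data,
        events=events,
        metadata=dict(epoch.metadata),
    )


def flag_bad_channels(
    epochs: list[Epoch],
    config: PreprocessConfig,
    scalp_labels: tuple[str, ...] = montage.SCALP_LABELS,
) -> list[str]:
    """Scalp channels whose absolute deflection exceeds the threshold in at
    least ``min_bad_sequences`` epochs (or in all epochs if fewer exist)."""
    if not epochs:
        return []
    needed = min(config.min_bad_sequences, len(epochs))
    counts: dict[str, int] = {l: 0 for l in scalp_labels}
    for ep in epochs:
        peak = np.abs(ep.data).max(axis=1)
        for label in scalp_labels:
            if peak[ep.channel_index(label)] > config.bad_channel_threshold:
                counts[label] += 1
    return [l for l in scalp_labels if counts[l] >= needed]


def interpolate_bad_channels(
    epoch: Epoch,
    config: PreprocessConfig,
    sensor_positions: dict[str, np.ndarray] | None = None,
    bad_labels: list[str] | None = None,
    scalp_labels: tuple[str, ...] = montage.SCALP_LABELS,
) -> tuple[Epoch, list[str]]:
    """Rebuild artifact-ridden channels from their nearest good neighbours.

    Each flagged channel is replaced by an inverse-distance-weighted average
    of the ``interp_neighbors`` nearest non-flagged scalp channels.  If
    ``bad_labels`` is not given, channels are flagged on this epoch alone.
    Raises :class:`TooManyBadChannels` when more than
    ``max_bad_fraction`` of the scalp channels are flagged.
    """
    if sensor_positions is None:
        sensor_positions = montage.sensor_positions()
    if bad_labels is None:
        bad_labels = flag_bad_channels([epoch], config, scalp_labels)
    limit = config.max_bad_fraction * len(scalp_labels)
    if len(bad_labels) > limit:
        raise TooManyBadChannels(
            f"{len(bad_labels)} bad channels exceed the repairable maximum "
            f"({config.max_bad_fraction:.0%} of {len(scalp_labels)} = {limit:.1f}); "
            f"subject should be excluded"
        )
    if not bad_labels:
        return dataclasses.replace(
            epoch, data=epoch.data.copy(), events=list(epoch.events)
        ), []

    data = epoch.data.copy()
    good = [l for l in scalp_labels if l not in bad_labels]
    for label in bad_labels:
        p = sensor_positions[label]
        dists = np.array([np.linalg.norm(sensor_positions[g] - p) for g in good])
        nearest = np.argsort(dists)[: config.interp_neighbors]
        w = 1.0 / np.maximum(dists[nearest], 1e-6)
        w /= w.sum()
        neighbour_rows = np.array(
            [data[epoch.channel_index(good[j])] for j in nearest]
        )
        data[epoch.channel_index(label)] = w @ neighbour_rows
    out = dataclasses.replace(epoch, data=data, events=list(epoch.events))
    out.metadata = dict(epoch.metadata, repaired_channels=list(bad_labels))
    return out, list(bad_labels)


def rereference_average(
    epoch: Epoch, scalp_labels: tuple[str, ...] = montage.SCALP_LABELS
) -> Epoch:
    """Re-reference to the common average of the scalp channels.

    After this stage the mean across scalp channels is exactly zero at every
    sample; auxiliary (non-scalp) channels are left untouched.  Pairwise
    channel differences are preserved exactly.
    """
    missing = [l for l in scalp_labels if l not in epoch.channel_labels]
    if missing:
        raise ValueError(f"scalp channel(s) missing from epoch: {missing}")
    idx = [epoch.channel_index(l) for l in scalp_labels]
    data = epoch.data.copy()
    data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return dataclasses.replace(epoch, data=data, events=list(epoch.events))


def crop_integer_cycles(epoch: Epoch, config: PreprocessConfig) -> Epoch:
    """Crop from steady-stimulation onset to a whole number of oddball cycles.

    The retained window starts at the ``crop_reference`` event and holds the
    largest integer number of oddball cycles that (a) fits in the available
    steady stimulation and (b) spans an integer number of samples.  The
    resulting duration D makes both the oddball fundamental (1 cycle each)
    and the base rate (``oddball_period`` cycles each) exact bin frequencies
    k/D of the subsequent FFT.
    """
    refs = epoch.events_of(config.crop_reference)
    if not refs:
        raise ValueError(f"no {config.crop_reference!r} event in epoch")
    start = refs[0]
    fs = epoch.sample_rate

    available_s = (epoch.n_samples - start) / fs
    steady = epoch.metadata.get("steady_duration")
    if steady is not None:
        available_s = min(available_s, float(steady))

    f_odd = Fraction(config.crop_cycles_frequency).limit_denominator(10**6)
    fs_frac = Fraction(fs).limit_denominator(10**6)
    samples_per_cycle = fs_frac / f_odd
    n_max = int(available_s * float(f_odd) + 1e-9)
    n = n_max
    while n >= 1 and (n * samples_per_cycle).denominator != 1:
        n -= 1
    if n < 1:
        raise ValueError(
            f"only {available_s:.3f} s available after {config.crop_reference!r}: "
            f"less than one oddball cycle of {float(1 / f_odd):.4f} s that ends "
            f"on a sample"
        )
    n_samples = int(n * samples_per_cycle)
    data = epoch.data[:, start : start + n_samples].copy()
    events = [
        (i - start, c) for i, c in epoch.events if start <= i < start + n_samples
    ]
    meta = dict(epoch.metadata, n_oddball_cycles=n, crop_duration=n_samples / fs)
    return Recording(
        sample_rate=fs,
        channel_labels=epoch.channel_labels,
        data=data,
        events=events,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def preprocess_recording(
    recording: Recording,
    config: PreprocessConfig | None = None,
    sensor_positions: dict[str, np.ndarray] | None = None,
    scalp_labels: tuple[str, ...] = montage.SCALP_LABELS,
) -> tuple[list[Epoch], list[str]]:
    """Run the full preprocessing chain on one recording.

    Stages run in the fixed order filter -> epoch -> downsample ->
    interpolate -> re-reference -> crop.  Channels are flagged across all
    epochs of the recording (a channel must be artifact-ridden in at least
    ``min_bad_sequences`` epochs) before being repaired in each.  Returns the
    cropped epochs and the repaired channel labels.
    """
    if config is None:
        config = PreprocessConfig()
    filtered = bandpass_filter(recording, config)
    epochs = segment_epochs(filtered, config)
    epochs = [downsample(ep, config.target_rate) for ep in epochs]
    bad = flag_bad_channels(epochs, config, scalp_labels)
    repaired: list[Epoch] = []
    for ep in epochs:
        ep, _ = interpolate_bad_channels(
            ep, config, sensor_positions, bad_labels=bad, scalp_labels=scalp_labels
        )
        repaired.append(ep)
    referenced = [rereference_average(ep, scalp_labels) for ep in repaired]
    cropped = [crop_integer_cycles(ep, config) for ep in referenced]
    return cropped, bad
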