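"""Frequency-domain quantification of frequency-tagged EEG.

The quantities of interest live at known stimulation frequencies and their
harmonics, so the analysis is built on amplitude spectra (FFT magnitude
normalized by N/2, in µV) of integer-cycle segments, a local noise estimate
from neighbouring frequency bins, and three derived measures per bin:

* SNR (divide baseline):        amplitude / local noise mean
* baseline-subtracted (SB, µV): amplitude - local noise mean
* z-score:                      (amplitude - noise mean) / noise sd

A response is quantified by summing SB amplitudes over the significant
harmonic set (determined once on grand-averaged data, with z > 3.1), then
averaged over region-of-interest channels.  Individual-level significance
sums raw amplitudes over the same harmonic set and z-scores that sum against
identically-constructed sums at neighbouring bin offsets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import montage
from .preprocess import Epoch
from .synthetic import Recording


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum (µV), bin k at frequency k * resolution."""

    resolution: float                 # Hz
    amplitudes: np.ndarray            # (n_channels, n_bins)
    channel_labels: tuple[str, ...]
    duration: float                   # s of the transformed segment
    n_samples: int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes)
        if self.amplitudes.shape[0] != len(self.channel_labels):
            raise ValueError("one amplitude row per channel label required")
        if self.amplitudes.shape[1] != self.n_samples // 2 + 1:
            raise ValueError("bins must equal n_samples // 2 + 1")

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.resolution

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in spectrum") from None

    def bin_of(self, frequency: float, tol: float = 1e-6) -> int:
        """Index of the bin at ``frequency``; must be an exact bin frequency."""
        k = frequency / self.resolution
        if abs(k - round(k)) > tol:
            raise ValueError(
                f"{frequency} Hz is not an exact bin frequency "
                f"(resolution {self.resolution} Hz)"
            )
        k = round(k)
        if not 0 <= k < self.n_bins:
            raise ValueError(f"{frequency} Hz outside the spectrum")
        return k

    def roi_mean(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.channel_index(l) for l in labels]
        return self.amplitudes[idx].mean(axis=0)


@dataclass(frozen=True)
class NoiseEstimate:
    """Local noise level around one frequency bin."""

    center_bin: int
    used_offsets: tuple[int, ...]   # signed offsets that survived trimming
    mean: float                     # µV
    sd: float                       # µV


@dataclass(frozen=True)
class HarmonicSet:
    """Harmonic indices retained for quantification.

    ``excluded_multiples`` marks the overlap with the base stimulation rate:
    for an oddball at base/7, harmonic 7 (and 14, ...) coincides with the
    base response and is never part of the oddball quantification.
    """

    fundamental: float
    indices: tuple[int, ...]
    excluded_multiples: int = 7

    def __post_init__(self) -> None:
        if any(k % self.excluded_multiples == 0 for k in self.indices):
            raise ValueError(
                f"harmonic indices {self.indices} include a multiple of "
                f"{self.excluded_multiples} (base-rate overlap)"
            )
        if tuple(sorted(self.indices)) != self.indices:
            raise ValueError("harmonic indices must be sorted ascending")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(k * self.fundamental for k in self.indices)


@dataclass
class HarmonicResponse:
    """Summed baseline-subtracted response per channel over a harmonic set."""

    harmonic_set: HarmonicSet
    channel_labels: tuple[str, ...]
    summed_amplitude: np.ndarray   # (n_channels,), µV
    snr: np.ndarray                # (n_channels, n_harmonics)
    z: np.ndarray                  # (n_channels, n_harmonics)

    def channel_value(self, label: str) -> float:
        return float(self.summed_amplitude[self.channel_labels.index(label)])


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    channel_labels: tuple[str, ...]


ROI_MEDIAL_OCCIPITAL = ROIDefinition("medial-occipital", montage.ROI_MEDIAL_OCCIPITAL)
ROI_OT_LEFT = ROIDefinition("OT-left", montage.ROI_OT_LEFT)
ROI_OT_RIGHT = ROIDefinition("OT-right", montage.ROI_OT_RIGHT)
ROI_OT_BILATERAL = ROIDefinition("OT-bilateral", montage.ROI_OT_BILATERAL)

BUILTIN_ROIS = {
    r.name: r
    for r in (ROI_MEDIAL_OCCIPITAL, ROI_OT_LEFT, ROI_OT_RIGHT, ROI_OT_BILATERAL)
}


# ---------------------------------------------------------------------------
# Averaging and spectra
# ---------------------------------------------------------------------------

def average_time_domain(
    epochs: Sequence[Epoch],
    grouping: Callable[[dict], bool] | None = None,
) -> Epoch:
    """Pointwise mean of epochs in the time domain.

    Time-domain averaging attenuates EEG activity not phase-locked to the
    stimulus by 1/sqrt(n) while leaving the phase-locked response unchanged.
    ``grouping`` optionally selects epochs by their metadata.
    """
    selected = [
        ep for ep in epochs if grouping is None or grouping(ep.metadata)
    ]
    if not selected:
        raise ValueError("no epochs to average (empty selection)")
    first = selected[0]
    for ep in selected[1:]:
        if ep.data.shape != first.data.shape:
            raise ValueError(
                f"heterogeneous epoch shapes: {ep.data.shape} vs {first.data.shape}"
            )
        if ep.sample_rate != first.sample_rate:
            raise ValueError("heterogeneous sample rates")
        if ep.channel_labels != first.channel_labels:
            raise ValueError("heterogeneous channel orders")
    data = np.mean([ep.data for ep in selected], axis=0)
    meta = dict(first.metadata, n_averaged=len(selected))
    return Recording(
        sample_rate=first.sample_rate,
        channel_labels=first.channel_labels,
        data=data,
        events=list(first.events),
        metadata=meta,
    )


def amplitude_spectrum(epoch: Epoch) -> AmplitudeSpectrum:
    """FFT amplitude spectrum normalized by N/2, in µV.

    With this normalization a sinusoid of amplitude ``a`` at an exact bin
    frequency maps to the value ``a`` at that bin.  The epoch should already
    be cropped to an integer number of cycles of the frequencies of interest
    (no window is applied).
    """
    n = epoch.n_samples
    if n == 0:
        raise ValueError("empty epoch has no spectrum")
    amps = np.abs(np.fft.rfft(epoch.data, axis=1)) / (n / 2)
    return AmplitudeSpectrum(
        resolution=epoch.sample_rate / n,
        amplitudes=amps,
        channel_labels=epoch.channel_labels,
        duration=n / epoch.sample_rate,
        n_samples=n,
    )


def grand_average_spectrum(
    spectra: Sequence[AmplitudeSpectrum],
    collapse_channels: bool = False,
    label: str = "grand",
) -> AmplitudeSpectrum:
    """Average amplitude spectra across inputs (and optionally channels).

    Grand averaging operates on amplitude spectra, not on derived SNR or
    z values; SNR of a grand average is computed from the averaged spectrum.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.amplitudes.shape != first.amplitudes.shape:
            raise ValueError("heterogeneous spectrum shapes")
        if abs(s.resolution - first.resolution) > 1e-12:
            raise ValueError("heterogeneous spectral resolutions")
    mean = np.mean([s.amplitudes for s in spectra], axis=0)
    if collapse_channels:
        mean = mean.mean(axis=0, keepdims=True)
        labels: tuple[str, ...] = (label,)
    else:
        labels = first.channel_labels
    return AmplitudeSpectrum(
        resolution=first.resolution,
        amplitudes=mean,
        channel_labels=labels,
        duration=first.duration,
        n_samples=first.n_samples,
    )


# ---------------------------------------------------------------------------
# Noise estimation and per-bin measures
# ---------------------------------------------------------------------------

def _candidate_offsets(per_side: int) -> np.ndarray:
    """Signed neighbour offsets: +-2 .. +-(per_side + 1).

    The immediately adjacent bins (+-1) are excluded to protect against
    residual spectral leakage from the bin of interest.
    """
    one_side = np.arange(2, per_side + 2)
    return np.concatenate([-one_side[::-1], one_side])


def estimate_noise(
    spectrum: AmplitudeSpectrum,
    channel: str,
    bin: int,
    per_side: int = 10,
) -> NoiseEstimate:
    """Local noise mean/sd from neighbouring bins around ``bin``.

    From the ``2 * per_side`` candidate amplitudes at offsets
    +-2..+-(per_side+1), the single largest and single smallest are removed
    (so the signal, were it to leak, is not projected into the noise), and
    the mean and sample standard deviation of the remaining values are
    returned.
    """
    offsets = _candidate_offsets(per_side)
    lo, hi = bin + offsets.min(), bin + offsets.max()
    if lo < 0 or hi >= spectrum.n_bins:
        raise ValueError(
            f"bin {bin} needs neighbours in [{lo}, {hi}] but the spectrum has "
            f"bins [0, {spectrum.n_bins - 1}]"
        )
    row = spectrum.amplitudes[spectrum.channel_index(channel)]
    values = row[bin + offsets]
    keep = np.ones(len(values), dtype=bool)
    keep[np.argmax(values)] = False
    keep[np.argmin(values)] = False
    if keep.sum() == len(values) - 1:   # max and min at the same index
        keep[np.flatnonzero(keep)[0]] = False
    used = values[keep]
    return NoiseEstimate(
        center_bin=bin,
        used_offsets=tuple(int(o) for o in offsets[keep]),
        mean=float(used.mean()),
        sd=float(used.std(ddof=1)),
    )


def snr_at(
    spectrum: AmplitudeSpectrum, channel: str, bin: int, per_side: int = 10
) -> float:
    """Signal-to-noise ratio: bin amplitude divided by the local noise mean."""
    noise = estimate_noise(spectrum, channel, bin, per_side)
    amp = spectrum.amplitudes[spectrum.channel_index(channel), bin]
    return float(amp / noise.mean) if noise.mean > 0 else float("inf")


def subtract_at(
    spectrum: AmplitudeSpectrum, channel: str, bin: int, per_side: int = 10
) -> float:
    """Baseline-subtracted amplitude (µV): bin amplitude minus noise mean."""
    noise = estimate_noise(spectrum, channel, bin, per_side)
    amp = spectrum.amplitudes[spectrum.channel_index(channel), bin]
    return float(amp - noise.mean)


def z_at(
    spectrum: AmplitudeSpectrum, channel: str, bin: int, per_side: int = 10
) -> float:
    """z-score of the bin amplitude against the local noise distribution.

    A zero noise sd (a perfectly flat neighbourhood, possible only on
    degenerate inputs) yields a signed infinity rather than a clipped value.
    """
    noise = estimate_noise(spectrum, channel, bin, per_side)
    amp = spectrum.amplitudes[spectrum.channel_index(channel), bin]
    if noise.sd == 0:
        diff = amp - noise.mean
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float((amp - noise.mean) / noise.sd)


def snr_to_percent_increase(snr: float) -> float:
    """Express an SNR as percent amplitude increase over the noise level.

    SNR 35 corresponds to a 3400% increase; SNR 3 to 200%.
    """
    return (snr - 1.0) * 100.0


# ---------------------------------------------------------------------------
# Harmonic selection and summation
# ---------------------------------------------------------------------------

def find_significant_harmonics(
    grand_spectrum: AmplitudeSpectrum,
    fundamental: float,
    z_threshold: float = 3.1,
    excluded_multiples: int = 7,
    stop_rule: str = "scan-to-limit",
    freq_cap: float = 20.0,
    per_side: int = 10,
    channel: str | None = None,
) -> HarmonicSet:
    """Select significant harmonics of ``fundamental`` on grand-averaged data.

    Harmonics k = 1, 2, ... are tested in order, skipping multiples of
    ``excluded_multiples`` (the base-rate overlap).  With the default
    "scan-to-limit" rule every harmonic up to ``freq_cap`` Hz is tested and
    those with z > ``z_threshold`` retained; "consecutive" stops at the first
    non-significant harmonic instead.  The harmonic set selected here is
    meant to be reused unchanged for every subject and condition.
    """
    if stop_rule not in ("scan-to-limit", "consecutive"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    if channel is None:
        if len(grand_spectrum.channel_labels) != 1:
            raise ValueError(
                "grand_spectrum has multiple channels; pass channel= or "
                "collapse channels first"
            )
        channel = grand_spectrum.channel_labels[0]
    grand_spectrum.bin_of(fundamental)  # validates exact bin frequency

    selected: list[int] = []
    k = 0
    while True:
        k += 1
        if k % excluded_multiples == 0:
            continue
        freq = k * fundamental
        if freq > freq_cap + 1e-9:
            break
        z = z_at(grand_spectrum, channel, grand_spectrum.bin_of(freq), per_side)
        if z > z_threshold:
            selected.append(k)
        elif stop_rule == "consecutive":
            break
    return HarmonicSet(
        fundamental=fundamental,
        indices=tuple(selected),
        excluded_multiples=excluded_multiples,
    )


def sum_harmonics(
    spectrum: AmplitudeSpectrum,
    harmonic_set: HarmonicSet,
    per_side: int = 10,
) -> HarmonicResponse:
    """Sum baseline-subtracted amplitudes over the harmonic set, per channel.

    SNR and z are additionally reported per channel and harmonic.
    """
    if not harmonic_set.indices:
        raise ValueError("empty harmonic set: nothing to sum")
    bins = np.array([spectrum.bin_of(f) for f in harmonic_set.frequencies])
    offsets = _candidate_offsets(per_side)
    if bins.min() + offsets.min() < 0 or bins.max() + offsets.max() >= spectrum.n_bins:
        raise ValueError("harmonic bin too close to the spectrum edge")
    amps = spectrum.amplitudes                       # (n_ch, n_bins)
    amp = amps[:, bins]                              # (n_ch, n_harm)
    # neighbours: (n_ch, n_harm, n_offsets); trimming one extreme each end is
    # equivalent (by value) to removing the single largest and smallest
    neigh = np.sort(amps[:, bins[:, None] + offsets[None, :]], axis=2)[:, :, 1:-1]
    mean = neigh.mean(axis=2)
    sd = neigh.std(axis=2, ddof=1)
    summed = (amp - mean).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(mean > 0, amp / mean, np.inf)
        zval = np.where(
            sd > 0,
            (amp - mean) / np.where(sd > 0, sd, 1.0),
            np.where(amp == mean, 0.0, np.sign(amp - mean) * np.inf),
        )
    return HarmonicResponse(
        harmonic_set=harmonic_set,
        channel_labels=spectrum.channel_labels,
        summed_amplitude=summed,
        snr=snr,
        z=zval,
    )


def roi_aggregate(response: HarmonicResponse, roi: ROIDefinition) -> float:
    """Mean summed amplitude (µV) over the ROI's channels."""
    missing = [l for l in roi.channel_labels if l not in response.channel_labels]
    if missing:
        raise ValueError(f"ROI {roi.name!r} references missing channel(s): {missing}")
    vals = [response.channel_value(l) for l in roi.channel_labels]
    return float(np.mean(vals))


def data_driven_roi(
    channel_values: dict[str, float],
    k: int = 4,
    name: str = "data-driven",
    montage_order: tuple[str, ...] = montage.SCALP_LABELS,
) -> ROIDefinition:
    """The k channels with the largest (condition-averaged) summed response.

    Ties at the cut are broken by fixed montage order, deterministically.
    """
    labels = [l for l in montage_order if l in channel_values]
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} available channels")
    # stable sort on negated value keeps montage order among exact ties
    order = sorted(labels, key=lambda l: -channel_values[l])
    return ROIDefinition(name, tuple(order[:k]))


# ---------------------------------------------------------------------------
# Individual-level significance
# ---------------------------------------------------------------------------

def individual_significance(
    subject_spectrum: AmplitudeSpectrum,
    harmonic_set: HarmonicSet,
    roi: ROIDefinition,
    per_side: int = 10,
) -> float:
    """z-score of a subject's summed-harmonic response over an ROI.

    The ROI-averaged spectrum's raw amplitudes are summed over the harmonic
    set (fixed beforehand on grand-averaged data, never per subject); the
    null distribution is the identically-formed sum at every neighbour
    offset j in +-2..+-(per_side+1) (the same j applied to each harmonic),
    with the largest and smallest of the pooled sums removed.
    """
    row = subject_spectrum.roi_mean(roi.channel_labels)
    bins = np.array([subject_spectrum.bin_of(f) for f in harmonic_set.frequencies])
    offsets = _candidate_offsets(per_side)
    lo = bins.min() + offsets.min()
    hi = bins.max() + offsets.max()
    if lo < 0 or hi >= subject_spectrum.n_bins:
        raise ValueError("insufficient neighbour bins around the harmonic set")
    signal = float(row[bins].sum())
    null = np.array([row[bins + j].sum() for j in offsets])
    keep = np.ones(len(null), dtype=bool)
    keep[np.argmax(null)] = False
    keep[np.argmin(null)] = False
    used = null[keep]
    sd = used.std(ddof=1)
    if sd == 0:
        diff = signal - used.mean()
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float((signal - used.mean()) / sd)
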