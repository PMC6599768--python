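"""Synthetic fast-periodic-visual-stimulation (FPVS) EEG.

This module builds oddball stimulation schedules and generates multichannel
EEG recordings with known ground truth, emulating the structure of a
familiar-face frequency-tagging experiment: faces shown at a 6 Hz base rate,
every 7th stimulus a familiar "oddball" face (6/7 ≈ 0.8571 Hz), 70 s of
steady stimulation flanked by 2 s contrast fade-in/out, recorded from a
128-channel scalp montage (plus 4 ocular channels) at 512 Hz.

The neural response model is deliberately minimal: each tagged response is a
sum of sinusoidal harmonics with per-harmonic amplitude and phase, scaled by
a smooth per-channel topography, superimposed on 1/f^alpha Gaussian noise.
The downstream analysis observes only harmonic amplitudes, so this is the
smallest model that exercises every analysis stage with exact ground truth.
An "inverted" (upside-down faces) condition multiplies the oddball response
by a configurable attenuation factor, emulating the face-inversion effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

from . import montage

# Event codes written into every simulated recording.
EVENT_SEQ_ON = "SEQ_ON"          # sequence (fade-in) onset
EVENT_STEADY_ON = "STEADY_ON"    # end of fade-in, start of full-contrast stimulation
EVENT_CYCLE_MIN = "CYCLE_MIN"    # contrast minimum of each base-rate cycle
EVENT_SEQ_OFF = "SEQ_OFF"        # sequence (fade-out) offset

CONDITIONS = ("upright", "inverted")

# The emulated study design: 6 faces per second, every 7th one familiar.
BASE_RATE = 6.0
ODDBALL_PERIOD = 7


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulationSchedule:
    """Ordered stimulus slots at the base rate with oddball positions.

    ``slots`` covers the steady-stimulation part only; slot ``i`` is an
    oddball iff ``(i + 1) % oddball_period == 0``, and oddball slots draw
    from ``familiar_ids`` while all others draw from ``unfamiliar_ids``.
    """

    base_rate: float              # Hz
    oddball_period: int           # stimuli per oddball
    steady_duration: float        # s
    fade_in: float                # s
    fade_out: float               # s
    slots: tuple[tuple[str, bool], ...]
    familiar_ids: tuple[str, ...]
    unfamiliar_ids: tuple[str, ...]

    @property
    def oddball_rate(self) -> float:
        return oddball_frequency(self.base_rate, self.oddball_period)

    @property
    def n_oddballs(self) -> int:
        return sum(1 for _, is_odd in self.slots if is_odd)

    @property
    def duration(self) -> float:
        """Total sequence duration including fades (s)."""
        return self.fade_in + self.steady_duration + self.fade_out


@dataclass(frozen=True)
class PeriodicResponseSpec:
    """A periodic neural response: harmonic sum with a scalp topography.

    ``harmonics`` holds (harmonic index >= 1, amplitude in µV, phase in rad);
    ``topography`` maps channel label -> dimensionless gain. Channels absent
    from the map receive gain 0.
    """

    fundamental: float
    harmonics: tuple[tuple[int, float, float], ...]
    topography: dict[str, float]

    def __post_init__(self) -> None:
        for k, amp, _ in self.harmonics:
            if k < 1:
                raise ValueError(f"harmonic index must be >= 1, got {k}")
            if amp < 0:
                raise ValueError(f"harmonic amplitude must be >= 0, got {amp}")
        for label, g in self.topography.items():
            if not np.isfinite(g):
                raise ValueError(f"non-finite gain for channel {label!r}")

    @property
    def total_amplitude(self) -> float:
        """Sum of harmonic amplitudes (µV) at a gain-1 channel."""
        return float(sum(a for _, a, _ in self.harmonics))

    def scaled(self, factor: float) -> "PeriodicResponseSpec":
        """Return a copy with every harmonic amplitude multiplied by ``factor``."""
        return dataclasses.replace(
            self,
            harmonics=tuple((k, a * factor, p) for k, a, p in self.harmonics),
        )


@dataclass
class SimulationConfig:
    """Everything needed to generate a deterministic synthetic study."""

    seed: int = 0
    sample_rate: float = 512.0
    channel_labels: tuple[str, ...] = montage.ALL_LABELS
    base_response: PeriodicResponseSpec | None = None
    oddball_response: PeriodicResponseSpec | None = None
    noise_rms: float = 5.0          # µV per channel
    noise_exponent: float = 1.0     # alpha in 1/f^alpha power
    oddball_attenuation: float = 0.2  # applied in the inverted condition
    n_subjects: int = 16
    n_sequences_per_condition: int = 12
    pre_pad: float = 3.0            # s of pre-stimulation baseline
    post_pad: float = 3.0           # s of post-stimulation baseline

    def __post_init__(self) -> None:
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        if self.oddball_attenuation < 0:
            raise ValueError("oddball_attenuation must be >= 0")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")


@dataclass
class Recording:
    """Multichannel EEG time series (µV) with event markers."""

    sample_rate: float
    channel_labels: tuple[str, ...]
    data: np.ndarray                      # (n_channels, n_samples), µV
    events: list[tuple[int, str]]         # (sample index, code)
    metadata: dict

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n = self.data.shape[1]
        for idx, code in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event {code!r} at sample {idx} outside data range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def events_of(self, code: str) -> list[int]:
        return [i for i, c in self.events if c == code]


# ---------------------------------------------------------------------------
# Schedule construction
# ---------------------------------------------------------------------------

def oddball_frequency(base_rate: float, oddball_period: int) -> float:
    """Frequency at which the oddball stimulus appears (Hz)."""
    if oddball_period < 2:
        raise ValueError(
            f"oddball_period must be >= 2 (every stimulus would be an oddball); "
            f"got {oddball_period}"
        )
    return base_rate / oddball_period


def build_schedule(
    base_rate: float,
    oddball_period: int,
    steady_duration: float,
    familiar_ids: Sequence[str],
    unfamiliar_ids: Sequence[str],
    seed: int = 0,
    fade_in: float = 2.0,
    fade_out: float = 2.0,
    no_immediate_repeat: bool = False,
) -> StimulationSchedule:
    """Build a randomized oddball schedule for one stimulation sequence.

    The steady part holds ``base_rate * steady_duration`` slots (must be a
    whole number divisible into whole oddball cycles); every
    ``oddball_period``-th slot shows a familiar face, all others unfamiliar
    faces, and each image is shown an equal number of times.  Image order is
    shuffled by ``seed``; ``no_immediate_repeat`` additionally forbids the
    same unfamiliar image in consecutive non-oddball slots.
    """
    oddball_frequency(base_rate, oddball_period)  # validates the period

    n_exact = base_rate * steady_duration
    n_slots = round(n_exact)
    if abs(n_exact - n_slots) > 1e-9:
        raise ValueError(
            f"base_rate x steady_duration = {base_rate} x {steady_duration} "
            f"= {n_exact} is not a whole number of stimuli"
        )
    if n_slots % oddball_period != 0:
        raise ValueError(
            f"{n_slots} slots do not divide into whole oddball cycles of "
            f"{oddball_period} stimuli"
        )
    n_odd = n_slots // oddball_period
    n_std = n_slots - n_odd
    if n_odd % len(familiar_ids) != 0:
        raise ValueError(
            f"{n_odd} oddball slots not divisible by {len(familiar_ids)} familiar images"
        )
    if n_std % len(unfamiliar_ids) != 0:
        raise ValueError(
            f"{n_std} standard slots not divisible by {len(unfamiliar_ids)} "
            f"unfamiliar images"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fam = np.repeat(np.asarray(familiar_ids, dtype=object), n_odd // len(familiar_ids))
    unfam = np.repeat(
        np.asarray(unfamiliar_ids, dtype=object), n_std // len(unfamiliar_ids)
    )
    rng.shuffle(fam)
    unfam = _shuffle_images(unfam, rng, no_immediate_repeat)

    slots: list[tuple[str, bool]] = []
    it_fam, it_unfam = iter(fam), iter(unfam)
    for i in range(n_slots):
        if (i + 1) % oddball_period == 0:
            slots.append((next(it_fam), True))
        else:
            slots.append((next(it_unfam), False))

    return StimulationSchedule(
        base_rate=base_rate,
        oddball_period=oddball_period,
        steady_duration=steady_duration,
        fade_in=fade_in,
        fade_out=fade_out,
        slots=tuple(slots),
        familiar_ids=tuple(familiar_ids),
        unfamiliar_ids=tuple(unfamiliar_ids),
    )


def _shuffle_images(
    images: np.ndarray, rng: np.random.Generator, no_immediate_repeat: bool
) -> np.ndarray:
    """Shuffle; optionally repair adjacent duplicates by random swaps."""
    rng.shuffle(images)
    if not no_immediate_repeat:
        return images
    n = len(images)
    for _ in range(100 * n):
        dup = np.flatnonzero(images[1:] == images[:-1])
        if dup.size == 0:
            return images
        i = int(dup[0]) + 1
        j = int(rng.integers(n))
        # swap only if it resolves position i without creating a clash at j
        if images[j] != images[i - 1] and (i + 1 >= n or images[j] != images[i + 1]):
            if j == 0 or (images[i] != images[j - 1] and
                          (j + 1 >= n or images[i] != images[j + 1])):
                images[i], images[j] = images[j], images[i]
    raise RuntimeError("could not find a no-immediate-repeat ordering")


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def _shaped_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sample_rate: float,
    rms: float,
    exponent: float,
    f_floor: float = 0.1,
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent.

    The shaping is flattened below ``f_floor`` (matching the analysis
    high-pass corner) to keep the spectrum integrable, and each channel is
    rescaled to exactly ``rms`` µV.
    """
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    # float32 is ample for a noise floor and halves generation cost
    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    fl = np.maximum(freqs, f_floor)
    shape = (fl ** (-exponent / 2.0)).astype(np.float32)
    shape[0] = 0.0  # no DC
    spec = np.fft.rfft(white, axis=1) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True, dtype=np.float64)
    std[std == 0] = 1.0
    return (x * (rms / std)).astype(np.float64)


def _fade_envelope(
    t: np.ndarray, fade_in: float, steady: float, fade_out: float
) -> np.ndarray:
    """Linear amplitude ramp: 0->1 over fade-in, 1 during steady, 1->0 out."""
    env = np.zeros_like(t)
    total = fade_in + steady + fade_out
    rising = (t >= 0) & (t < fade_in)
    env[rising] = t[rising] / fade_in if fade_in > 0 else 1.0
    env[(t >= fade_in) & (t < fade_in + steady)] = 1.0
    falling = (t >= fade_in + steady) & (t < total)
    if fade_out > 0:
        env[falling] = (total - t[falling]) / fade_out
    return env


def _response_gains(
    spec: PeriodicResponseSpec, channel_labels: tuple[str, ...]
) -> np.ndarray:
    known = set(channel_labels)
    unknown = [l for l in spec.topography if l not in known]
    if unknown:
        raise ValueError(f"topography references absent channel(s): {unknown}")
    return np.array([spec.topography.get(l, 0.0) for l in channel_labels])


def simulate_recording(
    schedule: StimulationSchedule,
    config: SimulationConfig,
    condition: str,
    subject: int = 0,
    sequence_index: int = 0,
    identity: str | None = None,
) -> Recording:
    """Generate one synthetic sequence recording.

    Output = 1/f noise + base periodic response + oddball periodic response,
    with the oddball amplitudes multiplied by ``config.oddball_attenuation``
    in the inverted condition.  Randomness is drawn from a stream derived
    deterministically from (config.seed, subject, condition, sequence_index),
    so subjects and sequences are independent but exactly reproducible.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")

    fs = config.sample_rate
    seq_duration = schedule.duration
    n_pre = round(config.pre_pad * fs)
    n_post = round(config.post_pad * fs)
    n_seq = round(seq_duration * fs)
    n_total = n_pre + n_seq + n_post

    stream = np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=(subject, CONDITIONS.index(condition), sequence_index),
    )
    rng = np.random.default_rng(stream)

    data = _shaped_noise(
        rng,
        len(config.channel_labels),
        n_total,
        fs,
        config.noise_rms,
        config.noise_exponent,
    )

    # Time axis relative to sequence (fade-in) onset; the envelope ramps the
    # response linearly over the fades and is exactly 1 in the steady window.
    t = (np.arange(n_total) - n_pre) / fs
    env = _fade_envelope(t, schedule.fade_in, schedule.steady_duration, schedule.fade_out)

    responses: list[tuple[PeriodicResponseSpec, float]] = []
    if config.base_response is not None:
        responses.append((config.base_response, 1.0))
    if config.oddball_response is not None:
        factor = config.oddball_attenuation if condition == "inverted" else 1.0
        responses.append((config.oddball_response, factor))

    for spec, factor in responses:
        gains = _response_gains(spec, config.channel_labels)
        if factor == 0 or not spec.harmonics:
            continue
        wave = np.zeros(n_total)
        for k, amp, phase in spec.harmonics:
            wave += amp * np.sin(2 * np.pi * k * spec.fundamental * t + phase)
        data += np.outer(gains * factor, wave * env)

    events: list[tuple[int, str]] = [(n_pre, EVENT_SEQ_ON)]
    events.append((n_pre + round(schedule.fade_in * fs), EVENT_STEADY_ON))
    n_cycles = round(seq_duration * schedule.base_rate)
    for i in range(n_cycles):
        events.append((n_pre + round(i * fs / schedule.base_rate), EVENT_CYCLE_MIN))
    events.append((n_pre + n_seq, EVENT_SEQ_OFF))
    events.sort()

    if identity is None:
        # image ids are "<identity>_img<k>"; fall back to the raw id
        first = schedule.familiar_ids[0] if schedule.familiar_ids else None
        identity = first.rsplit("_img", 1)[0] if first else None
    return Recording(
        sample_rate=fs,
        channel_labels=config.channel_labels,
        data=data,
        events=events,
        metadata={
            "subject": subject,
            "condition": condition,
            "identity": identity,
            "sequence_index": sequence_index,
            "base_rate": schedule.base_rate,
            "oddball_period": schedule.oddball_period,
            "steady_duration": schedule.steady_duration,
            "fade_in": schedule.fade_in,
            "fade_out": schedule.fade_out,
        },
    )


# ---------------------------------------------------------------------------
# Study-level defaults and iteration
# ---------------------------------------------------------------------------

def default_base_response() -> PeriodicResponseSpec:
    """General visual response at the 6 Hz base rate, medial-occipital focus.

    Five harmonics summing to 4.25 µV at the peak channels, the size of the
    summed base-rate response observed over medial-occipital cortex in this
    paradigm.
    """
    amps = [2.0, 1.0, 0.6, 0.4, 0.25]
    return PeriodicResponseSpec(
        fundamental=6.0,
        harmonics=tuple((k + 1, a, (k + 1) * np.pi / 4) for k, a in enumerate(amps)),
        topography=montage.gaussian_topography(montage.ROI_MEDIAL_OCCIPITAL),
    )


def default_oddball_response() -> PeriodicResponseSpec:
    """Familiar-face recognition response at 6/7 Hz, occipito-temporal focus.

    Harmonics 1-6, 8 and 9 (harmonic 7 coincides with the 6 Hz base rate and
    is not separately tagged), summing to 0.65 µV at the peak channels — the
    upright-condition occipito-temporal response size this paradigm reports.
    """
    indices = [1, 2, 3, 4, 5, 6, 8, 9]
    amps = [0.14, 0.12, 0.10, 0.09, 0.07, 0.06, 0.04, 0.03]
    return PeriodicResponseSpec(
        fundamental=6.0 / 7.0,
        harmonics=tuple(
            (k, a, k * np.pi / 4) for k, a in zip(indices, amps, strict=True)
        ),
        topography=montage.gaussian_topography(montage.ROI_OT_BILATERAL),
    )


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Simulation defaults matching the emulated study design.

    512 Hz sampling, 128 + 4 channels, 6 Hz base stimulation with every 7th
    stimulus an oddball, 70 s steady stimulation with 2 s fades, 16 subjects
    with 12 sequences per orientation condition, and a fivefold attenuation
    of the oddball response for inverted faces.
    """
    return SimulationConfig(
        seed=seed,
        base_response=default_base_response(),
        oddball_response=default_oddball_response(),
    )


def default_schedule(
    seed: int = 0,
    identity: str = "fam0",
    steady_duration: float = 70.0,
    n_familiar_images: int = 20,
    n_unfamiliar_images: int = 120,
) -> StimulationSchedule:
    """Schedule for one sequence of the emulated design.

    6 Hz base rate, oddball every 7th stimulus, 70 s steady stimulation: 420
    slots of which 60 are oddballs, 20 images of one familiar identity shown
    3x each and 120 unfamiliar images shown once each.
    """
    familiar = tuple(f"{identity}_img{i:02d}" for i in range(n_familiar_images))
    unfamiliar = tuple(f"unfam_img{i:03d}" for i in range(n_unfamiliar_images))
    return build_schedule(
        base_rate=6.0,
        oddball_period=7,
        steady_duration=steady_duration,
        familiar_ids=familiar,
        unfamiliar_ids=unfamiliar,
        seed=seed,
    )


def iter_study_recordings(
    config: SimulationConfig,
    conditions: tuple[str, ...] = CONDITIONS,
    n_identities: int = 6,
    steady_duration: float = 70.0,
) -> Iterator[Recording]:
    """Yield every recording of a simulated study, one at a time.

    Sequence ``i`` of each condition shows familiar identity
    ``fam{i % n_identities}``, so with 12 sequences and 6 identities each
    identity appears twice per condition, as in the emulated design.
    """
    n_slots = round(6.0 * steady_duration)
    n_odd = n_slots // ODDBALL_PERIOD if (n_slots % ODDBALL_PERIOD) == 0 else 0
    n_std = n_slots - n_odd
    # the full design uses 20 familiar and 120 unfamiliar images; shortened
    # sequences fall back to one showing per image
    n_fam_imgs = 20 if n_odd % 20 == 0 else n_odd
    n_unfam_imgs = 120 if n_std % 120 == 0 else n_std
    for subject in range(config.n_subjects):
        for condition in conditions:
            for i in range(config.n_sequences_per_condition):
                identity = f"fam{i % n_identities}"
                schedule = build_schedule(
                    base_rate=6.0,
                    oddball_period=7,
                    steady_duration=steady_duration,
                    familiar_ids=tuple(
                        f"{identity}_img{j:02d}" for j in range(n_fam_imgs)
                    ),
                    unfamiliar_ids=tuple(
                        f"unfam_img{j:03d}" for j in range(n_unfam_imgs)
                    ),
                    seed=int(
                        np.random.SeedSequence(
                            entropy=config.seed,
                            spawn_key=(subject, CONDITIONS.index(condition), i, 1),
                        ).generate_state(1)[0]
                        % (2**31)
                    ),
                )
                yield simulate_recording(
                    schedule, config, condition,
                    subject=subject, sequence_index=i, identity=identity,
                )


# ---------------------------------------------------------------------------
# Behavioural (fixation-task) simulation
# ---------------------------------------------------------------------------

def simulate_fixation_sequence(
    seed: int,
    duration: float = 70.0,
    n_targets: int = 15,
    miss_rate: float = 0.015,
    rt_mean: float = 0.398,
    rt_sd: float = 0.04,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate fixation-cross colour-change targets and key-press times.

    Targets occur at jittered times separated by at least 1.5 s (so one
    response window never overlaps the next target, as in any sane task
    design); each is answered with probability ``1 - miss_rate`` after a
    Gaussian reaction time clipped into a plausible range.  If the sequence
    is too short for ``n_targets`` at that spacing, fewer targets are used.
    Returns (target_times, response_times) in seconds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    usable = duration - 2.5
    slot = usable / n_targets
    if slot < 2.0:  # shortened sequences carry proportionally fewer targets
        n_targets = max(1, int(usable / 2.0))
        slot = usable / n_targets
    starts = 1.0 + np.arange(n_targets) * slot
    targets = starts + rng.uniform(0.0, slot - 1.5, size=n_targets)
    answered = rng.random(n_targets) >= miss_rate
    rts = np.clip(rng.normal(rt_mean, rt_sd, size=n_targets), 0.16, 0.99)
    responses = np.sort(targets[answered] + rts[answered])
    return targets, responses
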