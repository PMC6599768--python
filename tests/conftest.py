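"""Shared fixtures: small synthetic studies and the full recovery study."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fpvs
from fpvs.io import AnalysisSettings, RunConfig, SimulationSettings

ODDBALL_SET = fpvs.HarmonicSet(6.0 / 7.0, (1, 2, 3, 4, 5, 6, 8, 9))


def short_schedule(seed: int = 0, steady: float = 21.0) -> fpvs.StimulationSchedule:
    """A fast 21 s sequence keeping every divisibility property of the design.

    126 slots, 18 oddballs; 21 s at 256 Hz crops to 18 oddball cycles with an
    integer sample count, and the oddball bin (18) leaves room for the +-11
    neighbour offsets of the noise estimate.
    """
    return fpvs.build_schedule(
        base_rate=6.0,
        oddball_period=7,
        steady_duration=steady,
        familiar_ids=tuple(f"fam_img{i}" for i in range(18)),
        unfamiliar_ids=tuple(f"unfam_img{i}" for i in range(108)),
        seed=seed,
    )


def quiet_config(seed: int = 0, noise_rms: float = 0.0) -> fpvs.SimulationConfig:
    cfg = fpvs.default_study_config(seed=seed)
    return dataclasses.replace(cfg, noise_rms=noise_rms)


@pytest.fixture(scope="session")
def noise_free_epoch() -> fpvs.Epoch:
    """One fully preprocessed noise-free 21 s epoch with both responses."""
    rec = fpvs.simulate_recording(short_schedule(), quiet_config(), "upright")
    epochs, _ = fpvs.preprocess_recording(rec)
    return epochs[0]


def run_study(
    seed: int,
    oddball_scale: float,
    conditions: tuple[str, ...],
    n_subjects: int = 16,
    n_sequences: int = 4,
    noise_rms: float = 5.0,
) -> pd.DataFrame:
    """Simulate and analyse a study; return the per-subject ROI table.

    Study conditions follow the emulated design: 70 s steady stimulation,
    full 128-channel montage, default 1/f noise, oddball response scaled to
    the requested summed amplitude.
    """
    config = RunConfig(
        seed=seed,
        simulation=SimulationSettings(
            n_subjects=n_subjects,
            n_sequences_per_condition=n_sequences,
            noise_rms=noise_rms,
            oddball_amplitude_scale=oddball_scale,
            conditions=list(conditions),
        ),
    )
    from fpvs.pipeline import compute_subject_spectra, quantify, select_harmonics

    spectra, _, _ = compute_subject_spectra(config)
    base_set, odd_set = select_harmonics(spectra, config.analysis)
    _, roi_table = quantify(spectra, base_set, odd_set, config.analysis)
    return roi_table


@pytest.fixture(scope="session")
def recovery_study_065() -> pd.DataFrame:
    """16 subjects x 4 sequences, both orientations, injected 0.65 µV."""
    return run_study(seed=2024, oddball_scale=1.0,
                     conditions=("upright", "inverted"))


@pytest.fixture(scope="session")
def recovery_study_030() -> pd.DataFrame:
    return run_study(seed=2025, oddball_scale=0.3 / 0.65, conditions=("upright",))


@pytest.fixture(scope="session")
def recovery_study_010() -> pd.DataFrame:
    return run_study(seed=2026, oddball_scale=0.1 / 0.65, conditions=("upright",))


def ot_mean(roi_table: pd.DataFrame, condition: str) -> float:
    sub = roi_table[
        (roi_table.response == "oddball")
        & (roi_table.roi == "OT-bilateral")
        & (roi_table.condition == condition)
    ]
    return float(sub.summed_amplitude_uV.mean())
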