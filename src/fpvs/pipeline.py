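"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

The pipeline streams one simulated recording at a time through
preprocessing, keeps only the per-subject sequence-averaged epochs, and then
runs the frequency-domain quantification and group statistics, writing tidy
CSV tables (units in every numeric column header) plus a manifest that
records the config hash, seed and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, montage, spectral, synthetic
from .io import AnalysisSettings, RunConfig, save_config
from .preprocess import PreprocessConfig, preprocess_recording
from .spectral import (
    BUILTIN_ROIS,
    ROI_MEDIAL_OCCIPITAL,
    ROI_OT_BILATERAL,
    ROI_OT_LEFT,
    ROI_OT_RIGHT,
    AmplitudeSpectrum,
    HarmonicSet,
)
from .synthetic import BASE_RATE, CONDITIONS, ODDBALL_PERIOD, SimulationConfig

logger = logging.getLogger("fpvs")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def simulation_config_from_run(config: RunConfig) -> SimulationConfig:
    sim = config.simulation
    return SimulationConfig(
        seed=config.seed,
        sample_rate=sim.sample_rate,
        base_response=synthetic.default_base_response().scaled(sim.base_amplitude_scale),
        oddball_response=synthetic.default_oddball_response().scaled(
            sim.oddball_amplitude_scale
        ),
        noise_rms=sim.noise_rms,
        noise_exponent=sim.noise_exponent,
        oddball_attenuation=sim.oddball_attenuation,
        n_subjects=sim.n_subjects,
        n_sequences_per_condition=sim.n_sequences_per_condition,
    )


# ---------------------------------------------------------------------------
# Analysis on preprocessed, sequence-averaged spectra
# ---------------------------------------------------------------------------

def compute_subject_spectra(
    config: RunConfig,
) -> tuple[dict[tuple[int, str], AmplitudeSpectrum], dict, pd.DataFrame]:
    """Simulate and preprocess the whole study, one recording at a time.

    Returns per-(subject, condition) amplitude spectra of the time-domain
    sequence averages, per-(subject, condition, identity) spectra when
    per-identity analysis is on, and the scored fixation-task behaviour.
    """
    sim_config = simulation_config_from_run(config)
    sim = config.simulation
    pre = config.preprocess
    positions = montage.sensor_positions()

    by_cell: dict[tuple[int, str], list] = defaultdict(list)
    by_identity: dict[tuple[int, str, str], list] = defaultdict(list)
    behav_rows: list[dict] = []
    try:
        for rec in synthetic.iter_study_recordings(
            sim_config,
            conditions=tuple(sim.conditions),
            n_identities=sim.n_identities,
            steady_duration=sim.steady_duration,
        ):
            epochs, repaired = preprocess_recording(rec, pre, positions)
            if repaired:
                logger.info(
                    "subject %s %s seq %s: repaired channels %s",
                    rec.metadata["subject"], rec.metadata["condition"],
                    rec.metadata["sequence_index"], repaired,
                )
            for ep in epochs:
                key = (rec.metadata["subject"], rec.metadata["condition"])
                by_cell[key].append(ep)
                if config.analysis.per_identity:
                    by_identity[(*key, rec.metadata["identity"])].append(ep)
            targets, responses = synthetic.simulate_fixation_sequence(
                seed=int(
                    np.random.SeedSequence(
                        entropy=config.seed,
                        spawn_key=(
                            rec.metadata["subject"],
                            CONDITIONS.index(rec.metadata["condition"]),
                            rec.metadata["sequence_index"],
                            7,
                        ),
                    ).generate_state(1)[0]
                    % (2**31)
                ),
                duration=sim.steady_duration,
            )
            behav = inference.score_fixation_task(targets, responses)
            behav_rows.append(
                {
                    "subject": rec.metadata["subject"],
                    "condition": rec.metadata["condition"],
                    "sequence": rec.metadata["sequence_index"],
                    "accuracy_percent": behav.accuracy,
                    "mean_rt_ms": behav.mean_rt,
                    "n_targets": behav.n_targets,
                    "n_hits": behav.n_hits,
                    "n_false_alarms": behav.n_false_alarms,
                }
            )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise PipelineError(f"simulate/preprocess stage failed: {exc}") from exc

    spectra = {
        key: spectral.amplitude_spectrum(spectral.average_time_domain(eps))
        for key, eps in sorted(by_cell.items())
    }
    identity_spectra = {
        key: spectral.amplitude_spectrum(spectral.average_time_domain(eps))
        for key, eps in sorted(by_identity.items())
    }
    return spectra, identity_spectra, pd.DataFrame(behav_rows)


def select_harmonics(
    spectra: dict[tuple[int, str], AmplitudeSpectrum],
    analysis: AnalysisSettings,
) -> tuple[HarmonicSet, HarmonicSet]:
    """Harmonic sets for the base and oddball responses.

    The oddball set is either the configured fixed set or selected on the
    spectrum grand-averaged across subjects, channels and conditions
    (``oddball_harmonics: auto``).  The base set is always the configured
    consecutive-harmonic set.
    """
    oddball_fundamental = BASE_RATE / ODDBALL_PERIOD
    base_set = HarmonicSet(
        fundamental=BASE_RATE,
        indices=tuple(analysis.base_harmonics),
        excluded_multiples=10**9,  # the base response overlaps nothing
    )
    if analysis.oddball_harmonics == "auto":
        grand = spectral.grand_average_spectrum(
            list(spectra.values()), collapse_channels=True
        )
        odd_set = spectral.find_significant_harmonics(
            grand,
            oddball_fundamental,
            z_threshold=analysis.z_threshold,
            excluded_multiples=analysis.excluded_multiples,
            stop_rule=analysis.stop_rule,
            freq_cap=analysis.harmonic_cap,
            per_side=analysis.per_side,
        )
        logger.info("auto-selected oddball harmonics: %s", odd_set.indices)
    else:
        odd_set = HarmonicSet(
            fundamental=oddball_fundamental,
            indices=tuple(analysis.oddball_harmonics),
            excluded_multiples=analysis.excluded_multiples,
        )
    return base_set, odd_set


def quantify(
    spectra: dict[tuple[int, str], AmplitudeSpectrum],
    base_set: HarmonicSet,
    odd_set: HarmonicSet,
    analysis: AnalysisSettings,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed-harmonic responses per channel and per ROI for every cell."""
    channel_rows: list[dict] = []
    roi_rows: list[dict] = []
    for (subject, condition), spec in spectra.items():
        for name, hset in (("base", base_set), ("oddball", odd_set)):
            resp = spectral.sum_harmonics(spec, hset, analysis.per_side)
            scalp = [
                l for l in resp.channel_labels if l in montage.SCALP_LABELS
            ]
            for label in scalp:
                channel_rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "response": name,
                        "channel": label,
                        "summed_amplitude_uV": resp.channel_value(label),
                    }
                )
            whole_scalp = float(
                np.mean([resp.channel_value(l) for l in scalp])
            )
            roi_rows.append(
                {
                    "subject": subject, "condition": condition, "response": name,
                    "roi": "whole-scalp", "summed_amplitude_uV": whole_scalp,
                    "z": np.nan,
                }
            )
            for roi in BUILTIN_ROIS.values():
                roi_rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "response": name,
                        "roi": roi.name,
                        "summed_amplitude_uV": spectral.roi_aggregate(resp, roi),
                        "z": spectral.individual_significance(
                            spec, hset, roi, analysis.per_side
                        ),
                    }
                )
    return pd.DataFrame(channel_rows), pd.DataFrame(roi_rows)


def quantify_identities(
    identity_spectra: dict[tuple[int, str, str], AmplitudeSpectrum],
    odd_set: HarmonicSet,
    analysis: AnalysisSettings,
) -> pd.DataFrame:
    rows = []
    for (subject, condition, identity), spec in identity_spectra.items():
        resp = spectral.sum_harmonics(spec, odd_set, analysis.per_side)
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "identity": identity,
                "roi": ROI_OT_BILATERAL.name,
                "summed_amplitude_uV": spectral.roi_aggregate(resp, ROI_OT_BILATERAL),
            }
        )
    return pd.DataFrame(rows)


def group_statistics(
    roi_table: pd.DataFrame,
    identity_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """The study's group statistics on the summed-harmonic ROI table."""
    results: list[tuple[str, inference.StatsResult]] = []

    def on(response: str, roi: str) -> pd.DataFrame:
        sub = roi_table[(roi_table.response == response) & (roi_table.roi == roi)]
        return sub.rename(columns={"summed_amplitude_uV": inference.VALUE})

    for response, roi in [
        ("base", "whole-scalp"), ("base", "medial-occipital"),
        ("oddball", "whole-scalp"), ("oddball", "medial-occipital"),
        ("oddball", "OT-bilateral"),
    ]:
        res = inference.paired_test(on(response, roi), "condition",
                                    ("upright", "inverted"))
        results.append((f"{response} @ {roi}", res))

    for condition in ("upright", "inverted"):
        for roi in ("OT-left", "OT-right", "medial-occipital"):
            res = inference.one_sample_vs_zero(
                on("oddball", roi), where={"condition": condition}
            )
            res.effect = f"{condition} vs zero"
            results.append((f"oddball @ {roi}", res))

    hemi = roi_table[
        (roi_table.response == "oddball")
        & (roi_table.roi.isin(["OT-left", "OT-right"]))
    ].rename(columns={"roi": "hemisphere", "summed_amplitude_uV": inference.VALUE})
    for res in inference.rm_anova(hemi, ["condition", "hemisphere"]):
        results.append(("oddball orientation x hemisphere", res))

    if identity_table is not None and not identity_table.empty:
        idt = identity_table.rename(columns={"summed_amplitude_uV": inference.VALUE})
        if idt.identity.nunique() >= 2:
            for res in inference.rm_anova(idt, ["identity", "condition"]):
                results.append(("oddball identity x orientation", res))
            for res in inference.pairwise_bonferroni(idt, "identity"):
                results.append(("oddball identity pairwise", res))

    rows = []
    for context, res in results:
        rows.append(
            {
                "analysis": context,
                "effect": res.effect,
                "statistic": res.statistic,
                "dof_num": res.dof[0],
                "dof_den": res.dof[1],
                "p_value": res.p,
                "direction": res.direction,
                "correction": res.correction,
                "degenerate": res.degenerate,
                "gg_p_value": res.gg_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Top-level run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run the full study pipeline and write the artifact tree.

    Artifacts: ``config.yaml``, ``manifest.json``, ``tables/*.csv`` (channel,
    ROI, harmonic, behaviour, stats).  Deterministic for a fixed config and
    seed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    logger.info(
        "analysis defaults: per_side=%d, stop_rule=%s, interp_neighbors=%d",
        config.analysis.per_side, config.analysis.stop_rule,
        config.preprocess.interp_neighbors,
    )

    spectra, identity_spectra, behav = compute_subject_spectra(config)

    try:
        base_set, odd_set = select_harmonics(spectra, config.analysis)
        channel_table, roi_table = quantify(
            spectra, base_set, odd_set, config.analysis
        )
        identity_table = (
            quantify_identities(identity_spectra, odd_set, config.analysis)
            if identity_spectra
            else pd.DataFrame()
        )
        grand = spectral.grand_average_spectrum(
            list(spectra.values()), collapse_channels=True
        )
        harmonic_rows = []
        for name, hset in (("base", base_set), ("oddball", odd_set)):
            for k, freq in zip(hset.indices, hset.frequencies):
                b = grand.bin_of(freq)
                harmonic_rows.append(
                    {
                        "response": name,
                        "harmonic": k,
                        "frequency_Hz": freq,
                        "grand_z": spectral.z_at(grand, "grand", b,
                                                 config.analysis.per_side),
                        "grand_snr": spectral.snr_at(grand, "grand", b,
                                                     config.analysis.per_side),
                    }
                )
        harmonic_table = pd.DataFrame(harmonic_rows)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"analyze stage failed: {exc}") from exc

    try:
        stats_table = group_statistics(
            roi_table, identity_table if not identity_table.empty else None
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"report stage failed: {exc}") from exc

    channel_table.to_csv(tables / "channel_responses.csv", index=False)
    roi_table.to_csv(tables / "roi_responses.csv", index=False)
    harmonic_table.to_csv(tables / "harmonics.csv", index=False)
    behav.to_csv(tables / "behaviour.csv", index=False)
    stats_table.to_csv(tables / "stats.csv", index=False)
    if not identity_table.empty:
        identity_table.to_csv(tables / "identity_responses.csv", index=False)

    save_config(config, out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest(config), indent=2))
    return out


def manifest(config: RunConfig) -> dict:
    import scipy

    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    versions = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "versions": versions,
    }
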