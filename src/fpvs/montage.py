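"""High-density 128-channel scalp montage in extended 10-5 nomenclature.

The recording system emulated here is a 128-channel BioSemi-style cap whose
electrodes are relabelled to conventional 10-5 names.  Positions for 126 of
the labels come from the standard 10-5 template montage bundled with MNE;
``PO11`` and ``PO12`` are vendor extensions one ring below PO9/PO10 that do
not exist in the template, so their positions are synthesized by moving from
PO9/PO10 toward I1/I2 along the scalp and renormalizing to the same head
radius.

Four auxiliary electro-oculogram channels (``EXG1``–``EXG4``) ride along in
every recording but are never part of the scalp set used for re-referencing
or analysis.
"""

from __future__ import annotations

import functools

import numpy as np

#: 128 scalp labels, left-right symmetric, posterior coverage densified to
#: include the region-of-interest channels (OIz, Iz, Oz, POOz, P9/P10,
#: PO11/PO12) used by the frequency-tagging analysis.
SCALP_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
    "Iz", "I1", "I2", "OIz", "OI1", "OI2", "POOz",
    "AFp1", "AFp2",
    "AFF5h", "AFF6h", "AFF1h", "AFF2h",
    "FFT7h", "FFT8h", "FFC5h", "FFC6h", "FFC3h", "FFC4h", "FFC1h", "FFC2h",
    "FTT7h", "FTT8h", "FCC5h", "FCC6h", "FCC3h", "FCC4h", "FCC1h", "FCC2h",
    "TTP7h", "TTP8h", "CCP5h", "CCP6h", "CCP3h", "CCP4h", "CCP1h", "CCP2h",
    "TPP7h", "TPP8h", "CPP5h", "CPP6h", "CPP3h", "CPP4h", "CPP1h", "CPP2h",
    "PPO9h", "PPO10h", "PPO5h", "PPO6h", "PPO1h", "PPO2h",
    "POO9h", "POO10h", "POO1", "POO2",
    "PO11", "PO12",
)

#: Auxiliary (ocular) channels recorded alongside the scalp set.
AUX_LABELS: tuple[str, ...] = ("EXG1", "EXG2", "EXG3", "EXG4")

ALL_LABELS: tuple[str, ...] = SCALP_LABELS + AUX_LABELS

# Built-in regions of interest for the frequency-tagging analysis.
ROI_MEDIAL_OCCIPITAL: tuple[str, ...] = ("OIz", "Iz", "Oz", "POOz")
ROI_OT_LEFT: tuple[str, ...] = ("P9", "PO11")
ROI_OT_RIGHT: tuple[str, ...] = ("P10", "PO12")
ROI_OT_BILATERAL: tuple[str, ...] = ROI_OT_LEFT + ROI_OT_RIGHT


@functools.lru_cache(maxsize=1)
def sensor_positions() -> dict[str, np.ndarray]:
    """Return 3-D positions (metres, head frame) for every scalp label.

    Auxiliary channels have no scalp position and are not included.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        template = mne.channels.make_standard_montage("standard_1005")
    pos = template.get_positions()["ch_pos"]

    out: dict[str, np.ndarray] = {}
    for label in SCALP_LABELS:
        if label in ("PO11", "PO12"):
            continue
        out[label] = np.asarray(pos[label], dtype=float)

    def _extend(outer: str, inner: str) -> np.ndarray:
        p, q = pos[outer], pos[inner]
        v = p + 0.6 * (q - p)
        return np.asarray(v / np.linalg.norm(v) * np.linalg.norm(p), dtype=float)

    out["PO11"] = _extend("PO9", "I1")
    out["PO12"] = _extend("PO10", "I2")
    return out


def position_array(labels: tuple[str, ...] | list[str]) -> np.ndarray:
    """Stack sensor positions for ``labels`` into an (n, 3) array."""
    pos = sensor_positions()
    missing = [l for l in labels if l not in pos]
    if missing:
        raise KeyError(f"no sensor position for channel(s): {missing}")
    return np.array([pos[l] for l in labels])


def gaussian_topography(
    peak_labels: tuple[str, ...] | list[str],
    falloff_m: float = 0.035,
    zero_mean: bool = True,
) -> dict[str, float]:
    """Smooth per-channel gain map peaking (gain 1) at ``peak_labels``.

    The raw gain at channel ``c`` is
    ``max_p exp(-d(c, p)^2 / (2 * falloff_m^2))`` over the peak electrodes
    ``p`` with ``d`` the 3-D sensor distance, i.e. a Gaussian fall-off with
    spatial scale ``falloff_m`` (metres).

    With ``zero_mean`` (the default) the map is made average-reference
    consistent: scalp potentials of a compact dipolar source integrate to
    approximately zero over the head surface, so the gain map is shifted and
    rescaled to have exactly zero mean across the scalp channels while
    keeping gain 1 at the peaks.  A common-average re-reference then leaves
    the injected response unchanged.
    """
    pos = sensor_positions()
    peaks = position_array(tuple(peak_labels))
    gains: dict[str, float] = {}
    for label in SCALP_LABELS:
        d2 = np.sum((peaks - pos[label]) ** 2, axis=1)
        gains[label] = float(np.exp(-d2 / (2.0 * falloff_m**2)).max())
    if zero_mean:
        m = float(np.mean(list(gains.values())))
        gains = {l: (g - m) / (1.0 - m) for l, g in gains.items()}
    return gains
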