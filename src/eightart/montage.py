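"""Channel sets and electrode geometry.

The recording montage is 63 scalp electrodes (10–20 system) plus two primed
motor channels C3'/C4' used only for the lateralised readiness potential,
two mastoids used for offline re-referencing, and four EOG channels.  The
primed channels have no standardised position; they are treated as motor
channels placed just anterior to C3/C4 so that spherical-spline operations
remain well defined when they are present.

A reduced 11-channel scalp set covering every quantified component is used
for desk-scale simulations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FULL_SCALP",
    "REDUCED_SCALP",
    "EOG_CHANNELS",
    "MASTOID_CHANNELS",
    "LRP_CHANNELS",
    "scalp_positions",
    "make_mne_montage",
]

FULL_SCALP: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "FCz",
    "C3'", "C4'",
)

REDUCED_SCALP: tuple[str, ...] = (
    "FCz", "Cz", "Pz", "PO7", "PO8", "PO9", "PO10", "P1", "P2", "C3'", "C4'",
)

EOG_CHANNELS: tuple[str, ...] = ("VEOGU", "VEOGD", "HEOGL", "HEOGR")
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")
LRP_CHANNELS: tuple[str, ...] = ("C3'", "C4'")

_PRIME_SHIFT = np.array([0.0, 0.015, 0.0])  # 1.5 cm anterior


def scalp_positions(ch_names) -> dict[str, np.ndarray]:
    """Head-frame 3D positions (metres) for the given scalp channels."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005").get_positions()[
            "ch_pos"
        ]
    pos: dict[str, np.ndarray] = {}
    for name in ch_names:
        if name == "C3'":
            pos[name] = np.asarray(std["C3"]) + _PRIME_SHIFT
        elif name == "C4'":
            pos[name] = np.asarray(std["C4"]) + _PRIME_SHIFT
        elif name in std:
            pos[name] = np.asarray(std[name])
        else:
            raise KeyError(f"no standard position for channel {name!r}")
    return pos


def make_mne_montage(ch_names):
    import mne

    return mne.channels.make_dig_montage(
        ch_pos={k: v for k, v in scalp_positions(ch_names).items()},
        coord_frame="head",
    )
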