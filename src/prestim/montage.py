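"""Electrode geometry for the 64-channel 10-20/10-10 montage used throughout.

Channel positions come from the standard template montage shipped with MNE
and are projected onto a flat head circle with an azimuthal-equidistant
projection (vertex Cz at the origin, the Fpz--T8--Oz--T7 equator ring at
radius 1, x to the right, y to the front).  Electro-oculogram channels have
no scalp position; they are parked outside the head circle so that every
channel carries a coordinate while scalp interpolation can ignore them.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

#: 64 scalp electrodes of the extended 10-20 (10-10) system, including Fz.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Name of the vertical electro-oculogram channel.
VEOG = "VEOG"

#: Radius of the drawn head outline in projected units (slightly beyond the
#: 10-20 equator ring so below-equator sites such as Iz stay inside).
HEAD_RADIUS = 1.25

#: Parking coordinate for EOG channels (outside the head circle, frontal).
_EOG_POSITION = (0.15, 1.45)


def default_channel_names() -> tuple[str, ...]:
    """The simulator's default montage: 64 scalp channels plus VEOG."""
    return CHANNELS_64 + (VEOG,)


def is_eog(name: str) -> bool:
    """True for electro-oculogram channels (excluded from EEG statistics)."""
    return "EOG" in name.upper()


@functools.lru_cache(maxsize=1)
def _template_positions_3d() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            montage = mne.channels.make_standard_montage("standard_1020")
        except ValueError:  # pragma: no cover - newer template name
            montage = mne.channels.make_standard_montage("colin27_1020")
    return montage.get_positions()["ch_pos"]


def positions_2d(channel_names: tuple[str, ...] | list[str]) -> np.ndarray:
    """Project channel positions onto the flat head circle.

    Parameters
    ----------
    channel_names
        10-20 style labels; EOG channels are placed at a fixed spot outside
        the head circle.

    Returns
    -------
    (n_channels, 2) array of (x, y) coordinates; Cz maps to the origin and
    the 10-20 equator ring to radius 1.
    """
    pos3d = _template_positions_3d()
    # Approximate sphere centre of the template head (the vertex electrode
    # sits almost exactly above it).
    centre = np.array([0.0, -0.0092, 0.0])
    out = np.empty((len(channel_names), 2))
    for i, name in enumerate(channel_names):
        if is_eog(name):
            out[i] = _EOG_POSITION
            continue
        try:
            p = np.asarray(pos3d[name], dtype=float) - centre
        except KeyError:
            raise KeyError(
                f"channel {name!r} is not a known 10-20 electrode and not EOG"
            ) from None
        r = np.linalg.norm(p)
        theta = np.arccos(np.clip(p[2] / r, -1.0, 1.0))  # angle from vertex
        rho = theta / (np.pi / 2.0)  # equator ring -> 1
        horiz = np.hypot(p[0], p[1])
        if horiz < 1e-12:
            out[i] = (0.0, 0.0)
        else:
            out[i] = rho * np.array([p[0], p[1]]) / horiz
    return out
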