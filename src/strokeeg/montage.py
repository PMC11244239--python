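"""The 19-channel international 10-20 montage used throughout the package.

Channel order is frozen: every connectivity matrix, entropy vector and
feature image indexes channels in :data:`CHANNELS` order.

Electrode positions are constructed on a unit sphere directly from the
10-20 placement rules (head coordinates: +x right, +y anterior, +z up):

* the circumferential ring (Fp1/2, F7/8, T3/4, T5/6, O1/2) lies on the
  equator at 10%-of-circumference (36 deg) azimuth steps from the midline;
* midline and central electrodes (Fz, Cz, Pz, C3, C4) sit on the
  nasion-inion and preauricular arcs at 20% arc steps (36 deg inclination);
* F3/F4 and P3/P4 are great-circle midpoints of (F7,Fz)/(F8,Fz) and
  (T5,Pz)/(T6,Pz), which is where the 10-20 system places them.
"""

from __future__ import annotations

import numpy as np

#: Frozen channel order for the 19-channel 10-20 montage.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

N_CHANNELS = len(CHANNELS)


def _ring(azimuth_deg: float) -> np.ndarray:
    # Equatorial ring position; azimuth measured from +y (front), positive
    # rotating toward the left hemisphere (-x is not used: left = -x).
    az = np.deg2rad(azimuth_deg)
    return np.array([-np.sin(az), np.cos(az), 0.0])


def _arc(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    # Position at a given inclination from the vertex (Cz), same azimuth
    # convention as _ring.
    inc = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([-np.sin(inc) * np.sin(az), np.sin(inc) * np.cos(az), np.cos(inc)])


def _midpoint(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    w = u + v
    return w / np.linalg.norm(w)


def _build_positions() -> dict[str, np.ndarray]:
    pos = {
        "Fp1": _ring(18), "Fp2": _ring(-18),
        "F7": _ring(54), "F8": _ring(-54),
        "T3": _ring(90), "T4": _ring(-90),
        "T5": _ring(126), "T6": _ring(-126),
        "O1": _ring(162), "O2": _ring(-162),
        "Fz": _arc(36, 0), "Pz": _arc(36, 180), "Cz": _arc(0, 0),
        "C3": _arc(36, 90), "C4": _arc(36, -90),
    }
    pos["F3"] = _midpoint(pos["F7"], pos["Fz"])
    pos["F4"] = _midpoint(pos["F8"], pos["Fz"])
    pos["P3"] = _midpoint(pos["T5"], pos["Pz"])
    pos["P4"] = _midpoint(pos["T6"], pos["Pz"])
    return pos


#: name -> unit-sphere 3-D position
POSITIONS: dict[str, np.ndarray] = _build_positions()

#: [19 x 3] array in CHANNELS order
POSITION_ARRAY: np.ndarray = np.array([POSITIONS[ch] for ch in CHANNELS])


def channel_index(name: str) -> int:
    """Index of an electrode in the frozen channel order."""
    return CHANNELS.index(name)


def positions_2d() -> np.ndarray:
    """Top-view (azimuthal equidistant) 2-D projection, for plotting."""
    xyz = POSITION_ARRAY
    theta = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    r = theta / (np.pi / 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])
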