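"""Catheter channel geometry conventions.

The water-perfused catheter carries 8 radial side-holes spaced 45 degrees
apart.  Angles are measured in degrees from the anterior midline of the anal
canal (0 = anterior, 180 = posterior), stored in [0, 360).

Convention: channel 2 sits on the anterior midline and channels 1 and 8
flank it at -45 and +45 degrees, so the anterior trio (channels 1, 2, 8)
spans a contiguous 135-degree anterior sector.  Channels 3..7 fill the
posterior arc at 90..270 degrees.  The numbering is therefore not sequential
around the circle; every consumer must go through this module rather than
assume channel order equals angular order.
"""

from __future__ import annotations

import numpy as np

N_CHANNELS = 8

#: Angle of each channel (index 0 = channel 1), degrees from anterior midline.
CHANNEL_ANGLES_DEG = np.array([315.0, 0.0, 90.0, 135.0, 180.0, 225.0, 270.0, 45.0])

#: 1-based labels of the channels facing the anterior midline.
ANTERIOR_CHANNELS = (1, 2, 8)

#: 0-based column indices of the anterior channels in a pressure matrix.
ANTERIOR_INDICES = tuple(c - 1 for c in ANTERIOR_CHANNELS)


def wrap_angle(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Map an angle (degrees) to the signed interval [-180, 180)."""
    return (np.asarray(angle_deg) + 180.0) % 360.0 - 180.0


def angles_cover_circle(angles_deg: np.ndarray, tol: float = 1e-6) -> bool:
    """True if the 8 angles form a full 45-degree-spaced ring (any rotation)."""
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    if a.shape != (N_CHANNELS,):
        return False
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return bool(np.allclose(gaps, 45.0, atol=tol))
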