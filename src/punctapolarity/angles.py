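"""Angle conventions shared by every module.

Angles are in degrees, measured in image coordinates: x increases rightward
(columns), y increases downward (rows). ``theta = atan2(dy, dx)`` wrapped to
``(-180, 180]``; 0 deg points along +x. Because y points down, positive angles
turn clockwise on screen; rose plots negate y for display only.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "angle_of", "unit_vector", "circular_mean"]


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # -180.0 can survive the modulo when angle is exactly -180 - 360k
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def angle_of(dx, dy):
    """Angle in degrees of the displacement (dx, dy) under the y-down convention."""
    return wrap_deg(np.degrees(np.arctan2(dy, dx)))


def unit_vector(angle_deg):
    """(dx, dy) unit vector for an angle in degrees."""
    rad = np.radians(angle_deg)
    return np.cos(rad), np.sin(rad)


def circular_mean(angles_deg, weights=None):
    """Mean resultant length R in [0, 1] and mean direction in degrees.

    Returns ``(R, mean_angle_deg)``; the mean angle is ``nan`` when R is 0
    (balanced configurations have no preferred direction).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean requires at least one angle")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights must match angles in shape")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    rad = np.radians(a)
    cx = float(np.sum(w * np.cos(rad)) / total)
    cy = float(np.sum(w * np.sin(rad)) / total)
    r = float(np.hypot(cx, cy))
    mean = angle_of(cx, cy) if r > 1e-12 else float("nan")
    return r, mean
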