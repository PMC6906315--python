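"""Circular statistics on the 180°-periodic orientation domain.

Orientations live on a half-circle: θ and θ + 180° are the same stimulus.
All routines therefore work on the doubled angle 2θ (period 360°) and map
the result back, which is the standard trick for axial data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "orientation_diff",
    "circ_mean_orientation",
    "circ_std_orientation",
    "circ_median_orientation",
]


def wrap_orientation(deg):
    """Wrap orientation(s) in degrees to the canonical interval [-90, 90)."""
    return (np.asarray(deg, dtype=float) + 90.0) % 180.0 - 90.0


def orientation_diff(a_deg, b_deg):
    """Signed angular difference a - b on the orientation circle, in [-90, 90)."""
    return wrap_orientation(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def circ_mean_orientation(deg, weights=None):
    """Circular mean of orientations (degrees), computed on doubled angles."""
    deg = np.asarray(deg, dtype=float)
    if deg.size == 0:
        raise ValueError("circ_mean_orientation requires at least one value")
    phi = np.deg2rad(2.0 * deg)
    if weights is None:
        s, c = np.sin(phi).mean(), np.cos(phi).mean()
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        s, c = (w * np.sin(phi)).sum(), (w * np.cos(phi)).sum()
    return float(wrap_orientation(np.rad2deg(np.arctan2(s, c)) / 2.0))


def circ_resultant(deg):
    """Mean resultant length R in [0, 1] of orientations on the doubled circle."""
    deg = np.asarray(deg, dtype=float)
    phi = np.deg2rad(2.0 * deg)
    return float(np.hypot(np.sin(phi).mean(), np.cos(phi).mean()))


def circ_std_orientation(deg):
    """Circular standard deviation of orientations, in orientation degrees.

    Uses sqrt(-2 ln R) on the doubled circle and halves the result so that for
    tightly concentrated samples it approaches the ordinary linear SD.
    """
    r = circ_resultant(deg)
    if r <= 0.0:
        return float("inf")
    # guard against R marginally above 1 from rounding
    r = min(r, 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))) / 2.0)


def circ_median_orientation(deg):
    """Circular median of orientations (degrees).

    The sample is rotated so its circular mean sits at 0, the ordinary median
    of the wrapped residuals is taken, and the rotation is undone.  This is
    deterministic and invariant to sample order, and reduces to the ordinary
    median whenever the data span less than a half-period, which is the case
    for response-error distributions.
    """
    deg = np.asarray(deg, dtype=float)
    if deg.size == 0:
        raise ValueError("circ_median_orientation requires at least one value")
    center = circ_mean_orientation(deg)
    resid = orientation_diff(deg, center)
    return float(wrap_orientation(center + np.median(resid)))
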