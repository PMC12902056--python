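"""Shared pixel-grid geometry.

All image-like arrays in this package are indexed ``[row, col]`` with row 0
at the top (the y-down convention of image files), while gaze positions and
saccade vectors live in a y-up degree coordinate system (0 deg = rightward,
90 deg = upward).  The conversion between the two happens only through the
helpers below, so the flip is defined in exactly one place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pixel_center_coords",
    "positions_from_pixels",
    "pixels_from_positions",
    "direction_deg",
]


def pixel_center_coords(shape: tuple[int, int], deg_per_px: float):
    """(x, y) degree coordinates of pixel centers for an array of ``shape``.

    Returns ``x`` of length ncols and ``y`` of length nrows, with ``y``
    increasing upward (row 0 has the largest y).
    """
    n_rows, n_cols = shape
    x = (np.arange(n_cols) + 0.5) * deg_per_px
    y = (n_rows - np.arange(n_rows) - 0.5) * deg_per_px
    return x, y


def positions_from_pixels(rows, cols, shape, deg_per_px, jitter_rc=None):
    """Degree positions of pixel indices, with optional sub-pixel offsets.

    ``jitter_rc`` is an optional pair of arrays in [0, 1) giving the
    within-pixel fractional position (row fraction, col fraction); when
    omitted, pixel centers are used.
    """
    n_rows, _ = shape
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if jitter_rc is None:
        fr = fc = 0.5
    else:
        fr, fc = jitter_rc
    x = (cols + fc) * deg_per_px
    y = (n_rows - rows - fr) * deg_per_px
    return x, y


def pixels_from_positions(x, y, shape, deg_per_px):
    """Integer pixel indices containing degree positions (inverse of above)."""
    n_rows, n_cols = shape
    cols = np.clip(np.floor(np.asarray(x) / deg_per_px), 0, n_cols - 1).astype(int)
    rows = np.clip(np.floor(n_rows - np.asarray(y) / deg_per_px), 0, n_rows - 1).astype(int)
    return rows, cols


def direction_deg(dx, dy):
    """Direction of displacement vectors in degrees, y-up, in [0, 360)."""
    return np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
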