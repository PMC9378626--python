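"""Plain-text orientation/defocus tables.

Whitespace-separated columns: tilt1_deg tilt2_deg defocus_nm
[shift_y_px shift_x_px]; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import numpy as np

from ptytomo.phantom import Orientation

_HEADER = "# tilt1_deg tilt2_deg defocus_nm shift_y_px shift_x_px"


def write_angle_table(path, orientations: list[Orientation],
                      defocus_nm: list[float] | None = None,
                      shifts_px: np.ndarray | None = None) -> None:
    n = len(orientations)
    defocus_nm = defocus_nm if defocus_nm is not None else [0.0] * n
    shifts = np.zeros((n, 2)) if shifts_px is None else np.asarray(shifts_px)
    rows = np.column_stack([
        [o.tilt1_deg for o in orientations],
        [o.tilt2_deg for o in orientations],
        defocus_nm, shifts[:, 0], shifts[:, 1]])
    np.savetxt(path, rows, header=_HEADER.lstrip("# "), fmt="%.6f")


def read_angle_table(path) -> tuple[list[Orientation], list[float], np.ndarray]:
    """Returns (orientations, per-tilt defocus in nm, shifts in px)."""
    rows = np.atleast_2d(np.loadtxt(path))
    if rows.shape[1] < 3:
        raise ValueError(
            f"angle table needs >= 3 columns (tilt1, tilt2, defocus), "
            f"got {rows.shape[1]}")
    orientations = [Orientation(float(r[0]), float(r[1])) for r in rows]
    defocus = [float(r[2]) for r in rows]
    shifts = rows[:, 3:5] if rows.shape[1] >= 5 else np.zeros((len(rows), 2))
    return orientations, defocus, shifts
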