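"""Tilt-series alignment and Fourier iterative 3D reconstruction.

Reconstruction follows the GENFIRE scheme: each 2D projection is
oversampled and Fourier-transformed, its frequency samples are gridded
onto the 3D frequency lattice via the Fourier slice theorem with
inverse-distance weighting, and the volume is refined by alternating
real-space constraints (positivity, optional support) with resetting the
measured Fourier samples.

All transforms use the centred convention (origin at the array centre),
matching the projector in :mod:`ptytomo.phantom`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from ptytomo.phantom import Orientation, Phantom3D, rotate_volume


class TomoError(RuntimeError):
    pass


@dataclass
class TiltSeries:
    """Stack of 2D phase projections (radians) on a common grid with one
    orientation and one defocus per projection."""

    projections: np.ndarray                 # (n, rows, cols)
    orientations: list[Orientation]
    pixel_size: float                       # nm
    per_tilt_defocus: list[float] | None = None
    alignment_shifts: np.ndarray | None = None   # (n, 2) pixels (dy, dx)
    alignment_warnings: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=np.float64)
        if self.projections.ndim != 3:
            raise TomoError("projections must be a (n, rows, cols) stack")
        n = self.projections.shape[0]
        if len(self.orientations) != n:
            raise TomoError("one orientation per projection required")
        if self.per_tilt_defocus is None:
            self.per_tilt_defocus = [0.0] * n
        if len(self.per_tilt_defocus) != n:
            raise TomoError("one defocus per projection required")

    @property
    def n_projections(self) -> int:
        return self.projections.shape[0]


@dataclass
class Volume3D:
    """Reconstructed 3D scalar field (normalized phase density)."""

    values: np.ndarray
    voxel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise TomoError("volume contains non-finite values")


def align_projections(series: TiltSeries, reference: str = "previous",
                      upsample_factor: int = 50,
                      min_peak: float = 0.05) -> TiltSeries:
    """Translational alignment by sequential phase correlation.

    Each projection is registered to its aligned neighbour (policy
    ``previous``) or to the running mean (policy ``mean``); shifts are
    applied by Fourier shifting. Projections whose correlation peak is
    below ``min_peak`` are flagged, not rejected.
    """
    if series.n_projections < 2:
        raise TomoError("need at least two projections to align")
    aligned = np.empty_like(series.projections)
    aligned[0] = series.projections[0]
    shifts = np.zeros((series.n_projections, 2))
    warnings: list[int] = []
    for i in range(1, series.n_projections):
        if reference == "previous":
            ref = aligned[i - 1]
        elif reference == "mean":
            ref = aligned[:i].mean(axis=0)
        else:
            raise TomoError(f"unknown reference policy '{reference}'")
        shift, _, _ = phase_cross_correlation(
            ref, series.projections[i], upsample_factor=upsample_factor,
            normalization=None)
        moved = np.real(np.fft.ifft2(ndimage.fourier_shift(
            np.fft.fft2(series.projections[i]), shift)))
        peak = _ncc(ref, moved)
        if peak < min_peak:
            warnings.append(i)
        aligned[i] = moved
        shifts[i] = shift
    return TiltSeries(aligned, series.orientations, series.pixel_size,
                      series.per_tilt_defocus, shifts, warnings)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _centered_fft2(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def _grid_projections(series: TiltSeries, m: int, radius: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Grid all projection Fourier samples onto the m^3 centred lattice.

    Returns (flat constrained indices, measured complex values). Samples
    land at R^T (0, qy, qx); grid points within ``radius`` of a sample
    accumulate it with weight 1/max(d, 1e-3), collisions averaging.
    """
    c = m // 2
    num = np.zeros(m**3, dtype=np.complex128)
    den = np.zeros(m**3, dtype=np.float64)
    n = series.projections.shape[1]
    pad = (m - n) // 2
    q = np.arange(m) - c
    qy, qx = np.meshgrid(q, q, indexing="ij")
    plane = np.stack([np.zeros(m * m), qy.ravel(), qx.ravel()])  # (3, m^2)
    for proj, orient in zip(series.projections, series.orientations):
        big = np.zeros((m, m))
        big[pad:pad + n, pad:pad + n] = proj
        f = _centered_fft2(big).ravel()
        coords = orient.rotation_matrix().T @ plane  # (3, m^2) in index units
        nearest = np.rint(coords)
        d = np.linalg.norm(coords - nearest, axis=0)
        idx3 = nearest.astype(int) + c
        inside = np.all((idx3 >= 0) & (idx3 < m), axis=0) & (d <= radius)
        w = 1.0 / np.maximum(d[inside], 1e-3)
        flat = (idx3[0, inside] * m + idx3[1, inside]) * m + idx3[2, inside]
        np.add.at(num, flat, w * f[inside])
        np.add.at(den, flat, w)
    constrained = np.nonzero(den > 0)[0]
    if constrained.size == 0:
        raise TomoError("empty Fourier constraint set")
    measured = num[constrained] / den[constrained]
    return constrained, measured


def genfire_reconstruct(series: TiltSeries, oversampling: int = 2,
                        interpolation_radius_px: float = 0.7,
                        n_iterations: int = 100, positivity: bool = True,
                        support: np.ndarray | None = None) -> Volume3D:
    """Fourier iterative reconstruction of a tilt series.

    Requires >= 3 projections; warns (via provenance) below 60 degrees of
    total angular range, where missing-wedge artefacts dominate.
    """
    if series.n_projections < 3:
        raise TomoError("need at least three projections")
    n = series.projections.shape[1]
    if series.projections.shape[2] != n:
        raise TomoError("projections must be square")
    m = oversampling * n
    angles = [max(abs(o.tilt1_deg), abs(o.tilt2_deg)) for o in series.orientations]
    angular_range = max(a for a in angles) - min(-a for a in angles)
    provenance = {"oversampling": oversampling,
                  "interpolation_radius_px": interpolation_radius_px,
                  "n_iterations": n_iterations, "positivity": positivity}
    if angular_range < 60:
        provenance["warning"] = (
            f"total angular range {angular_range:.0f} deg < 60 deg; expect "
            "severe missing-wedge artefacts")

    constrained, measured = _grid_projections(series, m,
                                              interpolation_radius_px)
    spectrum = np.zeros(m**3, dtype=np.complex128)
    spectrum[constrained] = measured
    k = spectrum.reshape(m, m, m)
    sup_big = None
    if support is not None:
        sup_big = np.zeros((m, m, m), dtype=bool)
        pad = (m - n) // 2
        sup_big[pad:pad + n, pad:pad + n, pad:pad + n] = support
    for it in range(n_iterations):
        vol = np.real(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k))))
        if not np.all(np.isfinite(vol)):
            raise TomoError(f"numerical failure (NaN) at iteration {it}")
        if positivity:
            vol = np.maximum(vol, 0.0)
        if sup_big is not None:
            vol = vol * sup_big
        k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))
        flat = k.reshape(-1)
        flat[constrained] = measured
        k = flat.reshape(m, m, m)
    vol = np.real(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k))))
    if positivity:
        vol = np.maximum(vol, 0.0)
    if sup_big is not None:
        vol = vol * sup_big
    pad = (m - n) // 2
    out = vol[pad:pad + n, pad:pad + n, pad:pad + n] / series.pixel_size
    # division by pixel size undoes the projector's thickness weighting so
    # the volume is a density (rad/nm) comparable to the phantom
    return Volume3D(np.ascontiguousarray(out), series.pixel_size, provenance)


def reproject(volume: Volume3D, orientation: Orientation) -> np.ndarray:
    """Project an arbitrary volume with the same conventions as
    :func:`ptytomo.phantom.project_phantom`."""
    rotated = rotate_volume(volume.values, orientation)
    return rotated.sum(axis=0) * volume.voxel_size
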