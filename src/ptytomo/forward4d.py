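"""Forward 4D-STEM simulation: defocused probe x projected phase object
-> far-field intensities with Poisson shot noise.

The detector is an ideal counting detector (no MTF, no readout noise).
Each diffraction pattern is computed on a fixed-size real-space window
centred on the probe position (positions are quantized to the pixel
grid), Fourier-transformed, scaled to the per-pattern electron budget
and Poisson-sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ptytomo.optics import (
    ComplexWave2D,
    DoseSpec,
    Grid2D,
    OpticsConfig,
    OpticsError,
    make_probe,
)


class ForwardModelError(ValueError):
    pass


@dataclass(frozen=True)
class ScanPattern:
    """Raster scan: probe centres in nm, (row, col) raster order."""

    positions_nm: tuple[tuple[float, float], ...]
    step_nm: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ForwardModelError("scan step must be positive")
        if len(self.positions_nm) != self.shape[0] * self.shape[1]:
            raise ForwardModelError("position count does not match raster shape")

    @property
    def n_positions(self) -> int:
        return len(self.positions_nm)


def make_raster_scan(shape: tuple[int, int], step_nm: float,
                     center_nm: tuple[float, float],
                     jitter_nm: float = 0.0, seed: int | None = None) -> ScanPattern:
    """Raster scan of ``shape`` = (rows, cols) probe positions centred on
    ``center_nm``; optional seeded sub-step random jitter."""
    rows, cols = shape
    ys = (np.arange(rows) - (rows - 1) / 2.0) * step_nm + center_nm[0]
    xs = (np.arange(cols) - (cols - 1) / 2.0) * step_nm + center_nm[1]
    pos = [(float(y), float(x)) for y in ys for x in xs]
    if jitter_nm > 0:
        rng = np.random.default_rng(seed)
        pos = [(y + float(rng.uniform(-jitter_nm, jitter_nm)),
                x + float(rng.uniform(-jitter_nm, jitter_nm))) for y, x in pos]
    return ScanPattern(tuple(pos), step_nm, shape)


@dataclass
class DiffractionStack4D:
    """Per-tilt 4D dataset: (n_positions, ky, kx) intensities plus the
    metadata needed to reconstruct without side channels."""

    intensities: np.ndarray
    scan: ScanPattern
    optics: OpticsConfig
    dose: DoseSpec
    pixel_size: float          # real-space sampling of the probe window (nm)
    bf_radius_px: float        # bright-field disc radius on the detector
    seed: int | None = None
    noiseless: bool = False
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ForwardModelError("intensities must be (n, ky, kx)")
        if self.intensities.shape[0] != self.scan.n_positions:
            raise ForwardModelError("pattern count does not match scan")
        if np.any(self.intensities < 0):
            raise ForwardModelError("negative intensities")

    @property
    def window_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]

    @property
    def grid(self) -> Grid2D:
        return Grid2D(self.window_shape, self.pixel_size)

    def positions_px(self, canvas_shape: tuple[int, int]) -> np.ndarray:
        """Integer top-left window corners on an object canvas whose centre
        coincides with the scan's bounding-box centre.

        Offsets are quantized relative to the scan centre before the
        canvas origin is added, so the same physical position maps to the
        same object pixel on any canvas of matching parity.
        """
        pos = np.asarray(self.scan.positions_nm)
        center = (pos.min(axis=0) + pos.max(axis=0)) / 2.0
        rel = np.rint((pos - center) / self.pixel_size).astype(int)
        w = np.array(self.window_shape)
        origin = (np.array(canvas_shape) - w) // 2
        return rel + origin[None, :]


def bf_radius_pixels(optics: OpticsConfig, grid: Grid2D) -> float:
    """Bright-field disc radius in detector pixels: (alpha/lambda) / dk."""
    dk = 1.0 / (grid.shape[0] * grid.pixel_size)
    return (optics.alpha_rad / optics.wavelength_nm) / dk


def simulate_4dstem(projection: np.ndarray, optics: OpticsConfig,
                    scan: ScanPattern, dose: DoseSpec, pixel_size: float,
                    window: int = 64, seed: int | None = None,
                    noiseless: bool = False) -> DiffractionStack4D:
    """Simulate far-field diffraction patterns of a phase projection.

    For each probe position p the exit wave is P(r - p) exp(i phi(r));
    the pattern is |FFT|^2 scaled so its total equals the per-pattern
    electron budget, then Poisson-sampled unless ``noiseless``.

    ``projection`` is the 2D phase image (radians) sampled at
    ``pixel_size`` nm/px; ``window`` is the per-position real-space crop
    size in pixels (power of two recommended).
    """
    projection = np.asarray(projection, dtype=np.float64)
    if projection.ndim != 2:
        raise ForwardModelError("projection must be a 2D phase image")
    grid = Grid2D((window, window), pixel_size)
    probe = make_probe(grid, optics)

    stack = DiffractionStack4D(
        np.zeros((scan.n_positions, window, window)), scan, optics, dose,
        pixel_size, bf_radius_pixels(optics, grid), seed=seed,
        noiseless=noiseless)
    corners = stack.positions_px(projection.shape)
    if np.any(corners < 0) or np.any(corners + window > np.array(projection.shape)):
        raise ForwardModelError(
            "probe window exceeds the projection field of view; enlarge the "
            "projection or shrink the scan")

    n_e = dose.electrons_per_pattern
    rng = np.random.default_rng(seed)
    out = np.empty((scan.n_positions, window, window))
    for j, (cy, cx) in enumerate(corners):
        phi = projection[cy:cy + window, cx:cx + window]
        exit_wave = probe.values * np.exp(1j * phi)
        pattern = np.abs(np.fft.fft2(exit_wave)) ** 2
        pattern *= n_e / pattern.sum()
        out[j] = pattern if noiseless else rng.poisson(pattern)
    stack.intensities = out
    return stack


def _detector_radii(shape: tuple[int, int]) -> np.ndarray:
    """Radial distance (pixels) from the zero-frequency pixel, FFT layout."""
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    return np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)


def crop_to_bf(stack: DiffractionStack4D,
               radius_factor: float = 1.0) -> DiffractionStack4D:
    """Zero all detector pixels beyond radius_factor x bf_radius_px.

    Mirrors restricting the reconstruction to the bright-field disc.
    """
    if radius_factor < 1:
        raise ForwardModelError("radius_factor must be >= 1")
    r = _detector_radii(stack.window_shape)
    mask = r <= radius_factor * stack.bf_radius_px
    out = stack.intensities * mask[None, :, :]
    return replace(stack, intensities=out,
                   processing=stack.processing + (f"crop_to_bf:{radius_factor}",))


def threshold_preprocess(stack: DiffractionStack4D,
                         threshold: float = 0.0) -> DiffractionStack4D:
    """Set detector pixels with counts below ``threshold`` to zero
    (dark-noise suppression)."""
    if threshold < 0:
        raise ForwardModelError("threshold must be non-negative")
    out = np.where(stack.intensities < threshold, 0.0, stack.intensities)
    return replace(stack, intensities=out,
                   processing=stack.processing + (f"threshold:{threshold}",))
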