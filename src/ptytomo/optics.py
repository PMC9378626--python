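"""Electron-optical constants, probe formation, propagation, and analytic
resolution / dose / overlap formulas.

Unit conventions used throughout the package: lengths in nanometres,
angles in milliradians at the configuration surface (radians internally),
spatial frequencies in nm^-1, doses in electrons per square angstrom.
Negative defocus means underfocus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

# CODATA 2018
_PLANCK_H = 6.62607015e-34      # J s
_ELECTRON_MASS = 9.1093837015e-31  # kg
_ELEMENTARY_CHARGE = 1.602176634e-19  # C
_SPEED_OF_LIGHT = 299792458.0   # m/s


class OpticsError(ValueError):
    """Invalid optical parameter or sampling condition."""


@dataclass(frozen=True)
class OpticsConfig:
    """Electron-optical configuration of the probe-forming system.

    Parameters
    ----------
    voltage_kv : accelerating potential in kV.
    alpha_mrad : probe convergence semi-angle in mrad.
    beta_mrad : collection semi-angle in mrad; defaults to ``alpha_mrad``
        (bright-field-only operation).
    defocus_nm : signed defocus in nm; negative = underfocus.
    cs_mm : spherical-aberration coefficient in mm (0 for a corrected
        instrument).
    """

    voltage_kv: float
    alpha_mrad: float
    beta_mrad: float | None = None
    defocus_nm: float = 0.0
    cs_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise OpticsError(f"voltage must be positive, got {self.voltage_kv} kV")
        if self.alpha_mrad <= 0:
            raise OpticsError(f"alpha must be positive, got {self.alpha_mrad} mrad")
        if self.beta_mrad is None:
            object.__setattr__(self, "beta_mrad", self.alpha_mrad)
        if self.beta_mrad < self.alpha_mrad:
            raise OpticsError("beta must be >= alpha")
        if self.cs_mm < 0:
            raise OpticsError("cs must be non-negative")

    @property
    def wavelength_nm(self) -> float:
        return electron_wavelength(self.voltage_kv)

    @property
    def alpha_rad(self) -> float:
        return self.alpha_mrad * 1e-3

    @property
    def beta_rad(self) -> float:
        return self.beta_mrad * 1e-3

    @property
    def cs_nm(self) -> float:
        return self.cs_mm * 1e6


@dataclass(frozen=True)
class Grid2D:
    """Real-space sampling grid: ``shape`` = (rows, cols), ``pixel_size``
    in nm/pixel.  Fourier sampling is 1/(N*pixel_size) along each axis."""

    shape: tuple[int, int]
    pixel_size: float

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.shape):
            raise OpticsError(f"grid shape entries must be >= 2, got {self.shape}")
        if self.pixel_size <= 0:
            raise OpticsError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def extent_nm(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in nm^-1."""
        return 1.0 / (2.0 * self.pixel_size)

    def freq_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """FFT-ordered frequency axes (nm^-1) for rows and cols."""
        fy = np.fft.fftfreq(self.shape[0], d=self.pixel_size)
        fx = np.fft.fftfreq(self.shape[1], d=self.pixel_size)
        return fy, fx

    def freq_squared(self) -> np.ndarray:
        fy, fx = self.freq_axes()
        return fy[:, None] ** 2 + fx[None, :] ** 2


@dataclass
class ComplexWave2D:
    """A complex field sampled on a :class:`Grid2D`."""

    values: np.ndarray
    grid: Grid2D

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise OpticsError(
                f"wave shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise OpticsError("wave contains non-finite values")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def total_intensity(self) -> float:
        return float(np.sum(self.intensity))


@dataclass(frozen=True)
class DoseSpec:
    """Electron dose specification: areal dose (e-/A^2) and scan step (nm).

    ``electrons_per_pattern`` is the derived electron budget of a single
    diffraction pattern: dose x step^2 (step converted to angstroms).
    """

    dose_per_area: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.dose_per_area < 0:
            raise OpticsError("dose must be non-negative")
        if self.step_nm <= 0:
            raise OpticsError("scan step must be positive")

    @property
    def electrons_per_pattern(self) -> float:
        return electrons_per_pattern(self.dose_per_area, self.step_nm)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of an electron, in nm.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))
    """
    if voltage_kv <= 0:
        raise OpticsError(f"voltage must be positive, got {voltage_kv} kV")
    v = voltage_kv * 1e3
    ev = _ELEMENTARY_CHARGE * v
    p = np.sqrt(2.0 * _ELECTRON_MASS * ev * (1.0 + ev / (2.0 * _ELECTRON_MASS * _SPEED_OF_LIGHT**2)))
    return float(_PLANCK_H / p * 1e9)


def ptycho_resolution(optics: OpticsConfig) -> float:
    """Diffraction-limited ptychographic resolution lambda/(alpha+beta) in nm.

    With the collection angle defaulted to the convergence angle
    (bright-field disc only) this reduces to lambda/(2 alpha).
    """
    return optics.wavelength_nm / (optics.alpha_rad + optics.beta_rad)


def aberration_phase(optics: OpticsConfig, k: np.ndarray) -> np.ndarray:
    """Aberration phase chi(k) = pi lambda df k^2 + (pi/2) Cs lambda^3 k^4.

    ``k`` in nm^-1. Negative defocus gives chi < 0 at low k, so that a
    weak phase object imaged at underfocus shows positive (bright)
    contrast; this sign convention is pinned by a regression test.
    """
    lam = optics.wavelength_nm
    k2 = np.asarray(k, dtype=float) ** 2
    return (np.pi * lam * optics.defocus_nm * k2
            + 0.5 * np.pi * optics.cs_nm * lam**3 * k2**2)


def ctf_first_zero(optics: OpticsConfig) -> float:
    """Resolution (nm) at the first zero crossing of the phase CTF.

    With Cs = 0 this is the closed form sqrt(lambda |df|). With Cs > 0
    the smallest positive root of sin(chi(k)) is located numerically.
    """
    lam = optics.wavelength_nm
    df = optics.defocus_nm
    if optics.cs_mm == 0.0:
        if df == 0.0:
            raise OpticsError("CTF has no zero crossing with df = 0 and Cs = 0")
        return float(np.sqrt(lam * abs(df)))

    def chi(k: float) -> float:
        return float(aberration_phase(optics, np.array(k)))

    # first k > 0 where chi = +/- pi: scan for a bracket then refine
    k_hi = 1.0 / np.sqrt(lam * abs(df)) if df != 0 else (abs(chi(1.0)) + np.pi)
    ks = np.linspace(1e-9, 10.0 * k_hi, 20000)
    chis = aberration_phase(optics, ks)
    crossing = np.nonzero(np.abs(chis) >= np.pi)[0]
    if crossing.size == 0:
        raise OpticsError("no CTF zero crossing found in search range")
    i = crossing[0]
    sign = np.sign(chis[i])
    root = brentq(lambda k: chi(k) - sign * np.pi, ks[max(i - 1, 0)], ks[i],
                  xtol=1e-12, rtol=1e-10)
    return float(1.0 / root)


def probe_geometric_diameter(optics: OpticsConfig) -> float:
    """Geometric-optics diameter 2 alpha |df| (nm) of the defocused probe.

    Returns 0 at zero defocus; callers must treat the diffraction-limited
    Airy width as the floor.
    """
    return 2.0 * optics.alpha_rad * abs(optics.defocus_nm)


def overlap_ratio(step_nm: float, diameter_nm: float) -> float:
    """Linear probe-overlap fraction max(0, 1 - step/diameter)."""
    if diameter_nm <= 0:
        raise OpticsError("probe diameter must be positive")
    if step_nm < 0:
        raise OpticsError("scan step must be non-negative")
    return max(0.0, 1.0 - step_nm / diameter_nm)


def areal_overlap_ratio(step_nm: float, diameter_nm: float) -> float:
    """Fractional overlap area of two discs with centres ``step_nm`` apart.

    Secondary definition; the linear one is used for reporting.
    """
    if diameter_nm <= 0:
        raise OpticsError("probe diameter must be positive")
    r = diameter_nm / 2.0
    d = step_nm
    if d >= 2 * r:
        return 0.0
    area = 2 * r**2 * np.arccos(d / (2 * r)) - 0.5 * d * np.sqrt(4 * r**2 - d**2)
    return float(area / (np.pi * r**2))


def total_dose(dose_per_tilt: float, n_tilts: int) -> float:
    """Total areal dose of a tilt series: dose_per_tilt x n_tilts."""
    if dose_per_tilt < 0 or n_tilts < 0:
        raise OpticsError("dose and tilt count must be non-negative")
    return dose_per_tilt * n_tilts


def electrons_per_pattern(dose_per_area: float, step_nm: float) -> float:
    """Electron budget of one diffraction pattern: dose x (step in A)^2."""
    if dose_per_area < 0:
        raise OpticsError("dose must be non-negative")
    if step_nm <= 0:
        raise OpticsError("scan step must be positive")
    return dose_per_area * (step_nm * 10.0) ** 2


def make_probe(grid: Grid2D, optics: OpticsConfig) -> ComplexWave2D:
    """Form the probe wave: hard circular aperture of radius alpha/lambda
    in frequency space, aberration phase applied, inverse-transformed to
    real space and normalized to unit total intensity.
    """
    lam = optics.wavelength_nm
    k_ap = optics.alpha_rad / lam
    if k_ap >= grid.nyquist:
        raise OpticsError(
            f"aperture frequency {k_ap:.4f} nm^-1 exceeds grid Nyquist "
            f"{grid.nyquist:.4f} nm^-1; decrease pixel size"
        )
    diameter = probe_geometric_diameter(optics)
    fov = min(grid.extent_nm)
    if diameter > fov:
        raise OpticsError(
            f"geometric probe diameter {diameter:.1f} nm exceeds field of "
            f"view {fov:.1f} nm; enlarge the grid"
        )
    k2 = grid.freq_squared()
    aperture = (np.sqrt(k2) <= k_ap).astype(np.complex128)
    chi = aberration_phase(optics, np.sqrt(k2))
    psi_k = aperture * np.exp(-1j * chi)
    psi = np.fft.ifft2(psi_k)
    psi = np.fft.fftshift(psi)  # centre the probe in the field
    norm = np.sqrt(np.sum(np.abs(psi) ** 2))
    if norm == 0:
        raise OpticsError("empty aperture: no frequencies pass")
    return ComplexWave2D(psi / norm, grid)


def propagate(wave: ComplexWave2D, dz_nm: float, wavelength_nm: float,
              exact: bool = False) -> ComplexWave2D:
    """Free-space propagation by ``dz_nm`` along the beam axis.

    Default kernel is the paraxial (Fresnel) phase
    exp(-i pi lambda dz |k|^2); ``exact=True`` uses the full
    angular-spectrum square-root kernel (differences are negligible at
    the < 3 mrad angles used here). Unitary in either case.
    """
    k2 = wave.grid.freq_squared()
    if exact:
        kz2 = 1.0 / wavelength_nm**2 - k2
        kz = np.sqrt(np.maximum(kz2, 0.0))
        kernel = np.exp(-2j * np.pi * dz_nm * (1.0 / wavelength_nm - kz))
        kernel[kz2 < 0] = 0.0  # evanescent cut-off
    else:
        kernel = np.exp(-1j * np.pi * wavelength_nm * dz_nm * k2)
    out = np.fft.ifft2(np.fft.fft2(wave.values) * kernel)
    return ComplexWave2D(out, wave.grid)


def encircled_energy_diameter(wave: ComplexWave2D, fraction: float = 0.9) -> float:
    """Diameter (nm) of the centred circle enclosing ``fraction`` of the
    wave's total intensity, measured about the intensity centroid."""
    inten = wave.intensity
    total = inten.sum()
    if total <= 0:
        raise OpticsError("wave has zero intensity")
    ny, nx = wave.grid.shape
    ys = np.arange(ny)[:, None]
    xs = np.arange(nx)[None, :]
    cy = float((inten * ys).sum() / total)
    cx = float((inten * xs).sum() / total)
    r = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).ravel()
    order = np.argsort(r)
    cum = np.cumsum(inten.ravel()[order]) / total
    idx = int(np.searchsorted(cum, fraction))
    idx = min(idx, r.size - 1)
    return 2.0 * r[order][idx] * wave.grid.pixel_size
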