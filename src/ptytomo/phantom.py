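"""Ground-truth 3D phase phantoms and their 2D projections.

The phantom emulates an unstained DNA-origami-like specimen: gold
nanoparticles (optionally wrapped in a DNA shell), random-walk DNA
strands, and a lightly textured carbon support slab. Densities are
phase-shift densities in radians per nm of thickness; after the standard
normalization gold sits near 1, DNA near 0.2 and carbon near 0.

Coordinate conventions: volumes are indexed (z, y, x), 0-based, with
physical coordinates at voxel centres and the rotation centre at the
grid centre. Projections integrate along the z (beam) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

LABEL_VACUUM = 0
LABEL_CARBON = 1
LABEL_DNA = 2
LABEL_GOLD = 3


class PhantomError(ValueError):
    pass


@dataclass
class Phantom3D:
    """Voxelized phase-shift density (rad/nm) with per-voxel material labels."""

    density: np.ndarray
    labels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.density.shape != self.labels.shape:
            raise PhantomError("density and label grids differ in shape")
        if self.density.ndim != 3:
            raise PhantomError("phantom must be 3D")
        if np.any(self.density < 0):
            raise PhantomError("density must be non-negative")
        if self.voxel_size <= 0:
            raise PhantomError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape


@dataclass(frozen=True)
class Orientation:
    """Dual-axis orientation: intrinsic rotation by ``tilt1_deg`` about the
    y axis followed by ``tilt2_deg`` about the (rotated) x axis, with the
    beam along z. ``shift_nm`` is an optional in-plane (y, x) offset."""

    tilt1_deg: float = 0.0
    tilt2_deg: float = 0.0
    shift_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tilt1_deg) and np.isfinite(self.tilt2_deg)):
            raise PhantomError("tilt angles must be finite")

    def rotation_matrix(self) -> np.ndarray:
        """3x3 matrix acting on (z, y, x) coordinate vectors."""
        # scipy works in (x, y, z); permute to our (z, y, x) ordering.
        r = Rotation.from_euler("YX", [self.tilt1_deg, self.tilt2_deg],
                                degrees=True).as_matrix()
        perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
        return perm @ r @ perm.T


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry knobs for :func:`build_phantom`. Lengths in nm."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    gold_radius: float = 5.0
    gold_z_gap: float = 5.5          # surface-to-surface gap along z
    n_gold: int = 2
    shell_thickness: float = 2.0     # DNA shell around each gold sphere
    n_strands: int = 3
    strand_radius: float = 1.3
    strand_steps: int = 40
    strand_step_length: float = 2.0
    strand_spawn_fraction: float = 0.15  # start offset, fraction of grid size
    carbon_thickness: float = 4.0    # slab at the bottom (high z)
    carbon_texture: float = 0.05     # relative density fluctuation
    # ratios follow the normalized scale (gold : dna : carbon = 1 : 0.2 :
    # 0.04); absolute values are scaled so projected phases stay below pi
    density_gold: float = 0.12       # rad/nm
    density_dna: float = 0.024
    density_carbon: float = 0.005
    smooth_sigma: float = 0.0        # optional Gaussian edge smoothing (voxels)


def _ball_mask(shape: tuple[int, int, int], center: np.ndarray,
               radius_vox: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    return d2 <= radius_vox**2


def build_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0) -> Phantom3D:
    """Build a reproducible phantom from a geometry spec and a seed.

    Gold spheres are stacked along z about the volume centre, separated
    by ``gold_z_gap`` (surface to surface) and each wrapped in a DNA
    shell of ``shell_thickness``; DNA strands are seeded random-walk
    polylines rasterized as tubes; the carbon slab occupies the bottom
    ``carbon_thickness`` of the volume with mild smoothed-noise texture.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    if min(spec.shape) < 32:
        raise PhantomError("phantom grid must be at least 32 voxels per axis")
    vs = spec.voxel_size
    if spec.n_gold and spec.gold_radius / vs < 2:
        raise PhantomError("gold radius must span at least 2 voxels")
    if spec.n_strands and spec.strand_radius / vs < 0.5:
        raise PhantomError("strand radius must span at least 1 voxel (diameter)")

    density = np.zeros(spec.shape, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    center = (np.array(spec.shape, dtype=float) - 1.0) / 2.0

    # carbon slab with smoothed-noise texture
    if spec.carbon_thickness > 0:
        t_vox = max(1, int(round(spec.carbon_thickness / vs)))
        slab = np.zeros(spec.shape, dtype=bool)
        slab[nz - t_vox:, :, :] = True
        texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 2.0)
        texture /= max(np.abs(texture).max(), 1e-12)
        carbon = spec.density_carbon * (1.0 + spec.carbon_texture * texture)
        density[slab] = np.clip(carbon[slab], 0.0, None)
        labels[slab] = LABEL_CARBON

    # DNA strands: seeded random-walk polylines rasterized as tubes
    strand_r_vox = spec.strand_radius / vs
    for _ in range(spec.n_strands):
        f = spec.strand_spawn_fraction
        pos = center[1:] + rng.uniform(-f, f, size=2) * np.array([ny, nx])
        z = center[0] + rng.uniform(-0.1, 0.1) * nz
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        direction[0] *= 0.2  # strands lie mostly in-plane
        pts = []
        p = np.array([z, pos[0], pos[1]])
        for _ in range(spec.strand_steps):
            pts.append(p.copy())
            direction += 0.4 * rng.standard_normal(3)
            direction[0] *= 0.5
            direction /= max(np.linalg.norm(direction), 1e-12)
            p = p + direction * (spec.strand_step_length / vs)
        _rasterize_tube(density, labels, np.array(pts), strand_r_vox,
                        spec.density_dna, LABEL_DNA)

    # gold spheres with optional DNA shells, stacked along z
    r_vox = spec.gold_radius / vs
    gap_vox = spec.gold_z_gap / vs
    pitch = 2 * r_vox + gap_vox
    z0 = center[0] - pitch * (spec.n_gold - 1) / 2.0
    centers = [np.array([z0 + i * pitch, center[1], center[2]])
               for i in range(spec.n_gold)]
    for c in centers:
        if c[0] - r_vox < 0 or c[0] + r_vox >= nz:
            raise PhantomError("gold sphere placement exceeds grid bounds")
        if spec.shell_thickness > 0:
            shell = _ball_mask(spec.shape, c, r_vox + spec.shell_thickness / vs)
            density[shell] = spec.density_dna
            labels[shell] = LABEL_DNA
    for c in centers:  # gold painted last so shells never overwrite it
        ball = _ball_mask(spec.shape, c, r_vox)
        density[ball] = spec.density_gold
        labels[ball] = LABEL_GOLD

    if spec.smooth_sigma > 0:
        density = ndimage.gaussian_filter(density, spec.smooth_sigma)

    return Phantom3D(density, labels, vs)


def _rasterize_tube(density: np.ndarray, labels: np.ndarray,
                    points_vox: np.ndarray, radius_vox: float,
                    value: float, label: int) -> None:
    """Paint a tube of given radius along a polyline (voxel coordinates),
    skipping any voxels already labelled with a denser material."""
    shape = density.shape
    # densify the polyline so consecutive samples are < 0.5 voxel apart
    segs = []
    for a, b in zip(points_vox[:-1], points_vox[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / 0.5)))
        segs.append(np.linspace(a, b, n))
    samples = np.vstack(segs)
    r_int = int(np.ceil(radius_vox))
    for s in samples:
        lo = np.maximum(np.floor(s - radius_vox).astype(int), 0)
        hi = np.minimum(np.ceil(s + radius_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        mask = ((zz - s[0]) ** 2 + (yy - s[1]) ** 2 + (xx - s[2]) ** 2
                <= radius_vox**2)
        sub_lab = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        paint = mask & (sub_lab < label)
        density[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][paint] = value
        sub_lab[paint] = label


def rotate_volume(values: np.ndarray, orientation: Orientation,
                  order: int = 1) -> np.ndarray:
    """Resample a volume at the orientation's rotation (trilinear by
    default), rotating about the grid centre."""
    r = orientation.rotation_matrix()
    center = (np.array(values.shape, dtype=float) - 1.0) / 2.0
    # affine_transform maps output coords -> input coords: x_in = R^T x_out
    matrix = r.T
    offset = center - matrix @ center
    return ndimage.affine_transform(values, matrix, offset=offset, order=order,
                                    mode="constant", cval=0.0, prefilter=False)


def project_phantom(phantom: Phantom3D, orientation: Orientation) -> np.ndarray:
    """Projected phase image (radians): rotate the density by the
    orientation, integrate along z, multiply by the voxel size. Pure
    phase; no amplitude contrast."""
    rotated = rotate_volume(phantom.density, orientation)
    img = rotated.sum(axis=0) * phantom.voxel_size
    dy, dx = orientation.shift_nm
    if dy or dx:
        img = ndimage.shift(img, (dy / phantom.voxel_size, dx / phantom.voxel_size),
                            order=1, mode="constant")
    return img


def make_tilt_scheme(axis1_range: tuple[float, float] | None = (-49.99, 53.94),
                     axis2_range: tuple[float, float] | None = (-53.42, 46.40),
                     increment: float = 10.0) -> list[Orientation]:
    """Dual-axis tilt scheme about two perpendicular axes.

    Each axis is sampled from its minimum to its maximum inclusive with
    ceil(span/increment)+1 equally spaced angles (spacing approximately
    ``increment``). The default ranges yield 23 orientations total.
    Passing ``None`` for a range skips that axis (single-axis scheme).
    """
    if increment <= 0:
        raise PhantomError("tilt increment must be positive")
    orientations: list[Orientation] = []
    for axis, rng in enumerate((axis1_range, axis2_range)):
        if rng is None:
            continue
        lo, hi = rng
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
            raise PhantomError(f"invalid tilt range ({lo}, {hi})")
        span = hi - lo
        n = 1 if span == 0 else int(np.ceil(span / increment)) + 1
        for angle in np.linspace(lo, hi, n):
            if axis == 0:
                orientations.append(Orientation(tilt1_deg=float(angle)))
            else:
                orientations.append(Orientation(tilt2_deg=float(angle)))
    if not orientations:
        raise PhantomError("empty tilt scheme")
    return orientations
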