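"""Normalization, histogram peak analysis, contrast ratio, dataset
splitting, and FRC/FSC resolution estimation.

The contrast ratio is R = (P_DNA - P_bkgd) / (P_gold - P_bkgd), where
P_bkgd and P_DNA are histogram peak positions of equal-sized background
and DNA regions and P_gold is the mean over the gold region. Data are
first normalised by the affine map sending the background peak to 0 and
the gold mean to 1, so R is affine-invariant.

Resolution is read from the first downward crossing of the ring/shell
correlation below the half-bit information threshold
T(r) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n)); the fixed
0.143 and 0.5 thresholds are available as alternatives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import ndimage

from ptytomo.forward4d import DiffractionStack4D, ScanPattern
from ptytomo.optics import DoseSpec


class MetricsError(ValueError):
    pass


RESOLUTION_NOT_REACHED = float("inf")


@dataclass
class HistogramStats:
    p_bkgd: float
    p_dna: float
    p_gold: float
    r_dna_gold: float
    bin_width: float
    region_voxel_count: int


@dataclass
class FrcResult:
    frequencies: np.ndarray       # shell centre frequencies, nm^-1
    correlation: np.ndarray       # per-shell normalized correlation
    threshold: np.ndarray         # per-shell threshold values
    n_samples: np.ndarray         # Fourier samples per shell
    resolution: float             # nm; RESOLUTION_NOT_REACHED if no crossing
    criterion: str = "halfbit"

    @property
    def crossed(self) -> bool:
        return np.isfinite(self.resolution)


def normalise(data: np.ndarray, bkgd_region: np.ndarray,
              gold_region: np.ndarray, bins: int = 128) -> np.ndarray:
    """Affine normalization x -> (x - P_bkgd)/(P_gold - P_bkgd).

    P_bkgd is the smoothed histogram peak of the background region and
    P_gold the mean of the gold region; regions are boolean masks or
    index arrays and must be non-empty and disjoint.
    """
    data = np.asarray(data, dtype=np.float64)
    bkgd = data[bkgd_region]
    gold = data[gold_region]
    if bkgd.size == 0 or gold.size == 0:
        raise MetricsError("normalization regions must be non-empty")
    p_bkgd = _histogram_peak(bkgd, bins)
    p_gold = float(gold.mean())
    if p_gold == p_bkgd:
        raise MetricsError("degenerate normalization: gold mean equals "
                           "background peak")
    return (data - p_bkgd) / (p_gold - p_bkgd)


def _histogram_peak(values: np.ndarray, bins: int = 128,
                    value_range: tuple[float, float] | None = None,
                    smoothing_bins: float = 3.0) -> float:
    """Peak (mode) of a Gaussian-kernel-smoothed histogram; argmax ties
    break toward the lower intensity."""
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            return lo
        value_range = (lo, hi)
    hist, edges = np.histogram(values, bins=bins, range=value_range)
    smoothed = ndimage.gaussian_filter1d(hist.astype(float), smoothing_bins)
    peak_bin = int(np.argmax(smoothed))  # np.argmax returns the first max
    center = (edges[peak_bin] + edges[peak_bin + 1]) / 2.0
    # parabolic refinement of the argmax to sub-bin precision
    if 0 < peak_bin < bins - 1:
        y0, y1, y2 = smoothed[peak_bin - 1:peak_bin + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            center += 0.5 * (y0 - y2) / denom * (edges[1] - edges[0])
    return float(center)


def histogram_peaks(data: np.ndarray, bkgd_region: np.ndarray,
                    dna_region: np.ndarray, gold_region: np.ndarray,
                    bin_count: int = 128,
                    value_range: tuple[float, float] = (-0.2, 1.2),
                    smoothing_bins: float = 3.0) -> HistogramStats:
    """Per-region histogram peaks on shared bins and the contrast ratio.

    The three regions must contain the same number of voxels (as in the
    equal-voxel extraction used for the published histograms); gold is
    summarized by its mean rather than its peak.
    """
    data = np.asarray(data, dtype=np.float64)
    bkgd = data[bkgd_region]
    dna = data[dna_region]
    gold = data[gold_region]
    if not (bkgd.size == dna.size == gold.size):
        raise MetricsError(
            f"regions must hold equal voxel counts, got {bkgd.size}, "
            f"{dna.size}, {gold.size}")
    if bkgd.size == 0:
        raise MetricsError("empty regions")
    p_bkgd = _histogram_peak(bkgd, bin_count, value_range, smoothing_bins)
    p_dna = _histogram_peak(dna, bin_count, value_range, smoothing_bins)
    p_gold = float(gold.mean())
    r = contrast_ratio(p_dna, p_bkgd, p_gold)
    bin_width = (value_range[1] - value_range[0]) / bin_count
    return HistogramStats(p_bkgd, p_dna, p_gold, r, bin_width, int(bkgd.size))


def contrast_ratio(p_dna: float, p_bkgd: float, p_gold: float) -> float:
    """R = (P_DNA - P_bkgd) / (P_gold - P_bkgd)."""
    denom = p_gold - p_bkgd
    if denom == 0:
        raise MetricsError("contrast ratio undefined: P_gold equals P_bkgd")
    return (p_dna - p_bkgd) / denom


def split_dataset(stack: DiffractionStack4D, scheme: str = "checkerboard"
                  ) -> tuple[DiffractionStack4D, DiffractionStack4D]:
    """Partition scan positions into two disjoint halves.

    ``checkerboard`` alternates positions on the raster so neighbouring
    positions land in different halves; ``interleave`` alternates in
    raster order. Both halves carry halved dose metadata.
    """
    n = stack.scan.n_positions
    if n < 2:
        raise MetricsError("need at least two patterns to split")
    rows, cols = stack.scan.shape
    idx = np.arange(n)
    if scheme == "checkerboard":
        mask_a = ((idx // cols) + (idx % cols)) % 2 == 0
    elif scheme == "interleave":
        mask_a = idx % 2 == 0
    else:
        raise MetricsError(f"unknown split scheme '{scheme}'")

    def subset(mask: np.ndarray) -> DiffractionStack4D:
        pos = tuple(p for p, m in zip(stack.scan.positions_nm, mask) if m)
        scan = ScanPattern(pos, stack.scan.step_nm, (1, len(pos)))
        half_dose = DoseSpec(stack.dose.dose_per_area / 2.0, stack.dose.step_nm)
        return _dc_replace(stack, intensities=stack.intensities[mask],
                           scan=scan, dose=half_dose,
                           processing=stack.processing + (f"split:{scheme}",))

    return subset(mask_a), subset(~mask_a)


def half_bit_threshold(n_samples: np.ndarray) -> np.ndarray:
    """Half-bit information threshold per shell sample count."""
    n = np.maximum(np.asarray(n_samples, dtype=float), 1.0)
    rt = np.sqrt(n)
    return (0.2071 + 1.9102 / rt) / (1.2071 + 0.9102 / rt)


def _soft_circular_mask(shape: tuple[int, ...], edge_fraction: float = 0.1
                        ) -> np.ndarray:
    """Cosine-edged circular (2D) / spherical (3D) mask to suppress
    correlations from the periodic boundary."""
    grids = np.meshgrid(*[np.arange(s) - (s - 1) / 2.0 for s in shape],
                        indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    r_max = min(shape) / 2.0
    r_flat = r_max * (1.0 - edge_fraction)
    mask = np.ones(shape)
    edge = (r > r_flat) & (r < r_max)
    mask[edge] = 0.5 * (1 + np.cos(np.pi * (r[edge] - r_flat) / (r_max - r_flat)))
    mask[r >= r_max] = 0.0
    return mask


def _fourier_correlation(a: np.ndarray, b: np.ndarray, pixel_size: float,
                         shell_width_px: float, criterion: str,
                         apodize: bool) -> FrcResult:
    if a.shape != b.shape:
        raise MetricsError("inputs must share a grid")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a - a.mean()
    b = b - b.mean()
    if apodize:
        mask = _soft_circular_mask(a.shape)
        a = a * mask
        b = b * mask
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    freqs = np.meshgrid(*[np.fft.fftfreq(s, d=pixel_size) for s in a.shape],
                        indexing="ij")
    k = np.sqrt(sum(f**2 for f in freqs))
    dk = shell_width_px / (a.shape[0] * pixel_size)
    nyquist = 1.0 / (2.0 * pixel_size)
    n_shells = int(np.floor(nyquist / dk))
    shell_idx = np.minimum((k / dk).astype(int), n_shells)  # last bin = beyond
    num = np.zeros(n_shells + 1, dtype=np.complex128)
    pa = np.zeros(n_shells + 1)
    pb = np.zeros(n_shells + 1)
    cnt = np.zeros(n_shells + 1)
    np.add.at(num, shell_idx.ravel(), (fa * np.conj(fb)).ravel())
    np.add.at(pa, shell_idx.ravel(), (np.abs(fa) ** 2).ravel())
    np.add.at(pb, shell_idx.ravel(), (np.abs(fb) ** 2).ravel())
    np.add.at(cnt, shell_idx.ravel(), 1.0)
    # drop the DC shell and anything at/beyond Nyquist
    sl = slice(1, n_shells)
    denom = np.sqrt(pa[sl] * pb[sl])
    corr = np.where(denom > 0, np.abs(num[sl]) / np.maximum(denom, 1e-300), 0.0)
    n_samples = cnt[sl]
    centers = (np.arange(1, n_shells) + 0.5) * dk

    if criterion == "halfbit":
        thr = half_bit_threshold(n_samples)
    elif criterion == "0.143":
        thr = np.full_like(corr, 0.143)
    elif criterion == "0.5":
        thr = np.full_like(corr, 0.5)
    else:
        raise MetricsError(f"unknown criterion '{criterion}'")

    resolution = RESOLUTION_NOT_REACHED
    diff = corr - thr
    below = np.nonzero(diff < 0)[0]
    if below.size:
        i = below[0]
        if i == 0:
            k_cross = centers[0]
        else:
            f = diff[i - 1] / (diff[i - 1] - diff[i])  # linear interpolation
            k_cross = centers[i - 1] + f * (centers[i] - centers[i - 1])
        resolution = float(1.0 / k_cross)
    return FrcResult(centers, corr, thr, n_samples, resolution, criterion)


def frc(a: np.ndarray, b: np.ndarray, pixel_size: float = 1.0,
        shell_width_px: float = 1.0, criterion: str = "halfbit",
        apodize: bool = True) -> FrcResult:
    """Fourier ring correlation between two 2D images."""
    if np.asarray(a).ndim != 2:
        raise MetricsError("frc expects 2D images")
    return _fourier_correlation(a, b, pixel_size, shell_width_px, criterion,
                                apodize)


def fsc(a, b, pixel_size: float | None = None, shell_width_px: float = 1.0,
        criterion: str = "halfbit", apodize: bool = True) -> FrcResult:
    """Fourier shell correlation between two 3D volumes (arrays or
    :class:`~ptytomo.tomo.Volume3D`)."""
    from ptytomo.tomo import Volume3D

    if isinstance(a, Volume3D):
        pixel_size = pixel_size or a.voxel_size
        a = a.values
    if isinstance(b, Volume3D):
        b = b.values
    if np.asarray(a).ndim != 3:
        raise MetricsError("fsc expects 3D volumes")
    return _fourier_correlation(a, b, pixel_size or 1.0, shell_width_px,
                                criterion, apodize)


def dose_series_report(entries, bkgd_region, dna_region, gold_region,
                       pixel_size: float = 1.0, csv_path=None, plot_path=None):
    """Contrast ratio and half-data FRC resolution per dose.

    ``entries`` is a list of (dose_per_area, image) or
    (dose_per_area, image, half_a, half_b); when halves are present the
    FRC resolution between them is reported, otherwise NaN.

    Returns a list of dict rows; optionally writes CSV and a plot.
    """
    entries = list(entries)
    if len(entries) < 2:
        raise MetricsError("need at least two dose entries")
    rows = []
    for entry in entries:
        if len(entry) == 2:
            dose, image = entry
            halves = None
        else:
            dose, image, *halves = entry
        norm = normalise(image, bkgd_region, gold_region)
        stats = histogram_peaks(norm, bkgd_region, dna_region, gold_region)
        res = float("nan")
        if halves:
            res = frc(halves[0], halves[1], pixel_size).resolution
        rows.append({"dose_e_per_A2": float(dose),
                     "contrast_ratio": stats.r_dna_gold,
                     "frc_resolution_nm": res})
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot([r["dose_e_per_A2"] for r in rows],
                [r["contrast_ratio"] for r in rows], "o-")
        ax.set_xlabel("dose (e-/A^2)")
        ax.set_ylabel("contrast ratio R")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return rows
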