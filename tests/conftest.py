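import numpy as np
import pytest
from scipy import ndimage

import ptytomo as pt
from ptytomo.optics import DoseSpec


@pytest.fixture(scope="session")
def smooth_phase_object():
    """128x128 band-limited random phase object, max |phi| = 1 rad."""
    rng = np.random.default_rng(0)
    phi = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 2.0)
    phi *= 1.0 / np.abs(phi).max()
    return phi


@pytest.fixture(scope="session")
def noiseless_stack(smooth_phase_object):
    """Noiseless 4D stack: 5x5 scan at 70% linear overlap of a 12 nm
    defocused probe over the session phase object."""
    optics = pt.OpticsConfig(60.0, 1.5, defocus_nm=-4000.0)
    scan = pt.make_raster_scan((5, 5), 3.6, (0.0, 0.0))
    return pt.simulate_4dstem(smooth_phase_object, optics, scan,
                              DoseSpec(88.0, 3.6), pixel_size=1.0,
                              window=64, noiseless=True)


@pytest.fixture(scope="session")
def two_sphere_phantom():
    """32^3 band-limited two-gold-sphere phantom (z-gap parameter 5.5 nm)."""
    spec = pt.PhantomSpec(shape=(32, 32, 32), voxel_size=1.0, gold_radius=4.0,
                          gold_z_gap=5.5, n_strands=0, shell_thickness=0.0,
                          carbon_thickness=0.0, smooth_sigma=1.0)
    return pt.build_phantom(spec, seed=0)


@pytest.fixture(scope="session")
def single_axis_series(two_sphere_phantom):
    angles = np.arange(-69.0, 70.0, 3.0)
    orients = [pt.Orientation(tilt1_deg=a) for a in angles]
    projs = np.array([pt.project_phantom(two_sphere_phantom, o)
                      for o in orients])
    return pt.TiltSeries(projs, orients, two_sphere_phantom.voxel_size)


def illumination_mask(stack, canvas_shape, threshold=0.3):
    """Mask of the probe-illuminated part of a reconstruction canvas."""
    probe = pt.make_probe(pt.Grid2D(stack.window_shape, stack.pixel_size),
                          stack.optics)
    illum = np.zeros(canvas_shape)
    w = stack.window_shape[0]
    for cy, cx in stack.positions_px(canvas_shape):
        illum[cy:cy + w, cx:cx + w] += probe.intensity
    return illum > threshold * illum.max()


def crop_to_canvas(image, canvas_shape):
    """Central crop of a full image to a reconstruction canvas."""
    cy = (image.shape[0] - canvas_shape[0]) // 2
    cx = (image.shape[1] - canvas_shape[1]) // 2
    return image[cy:cy + canvas_shape[0], cx:cx + canvas_shape[1]]
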