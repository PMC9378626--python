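"""Shared synthetic instance for post-acquisition focus tests: a 3 mrad
probe (short depth of field) scanned 5x5 over a structured phantom
projection, simulated noiselessly at a chosen true defocus."""

import numpy as np
from skimage.transform import resize

import ptytomo as pt
from ptytomo.optics import DoseSpec


def focus_instance(true_defocus_nm, seed=3):
    spec = pt.PhantomSpec(shape=(64, 64, 64), voxel_size=4.0,
                          gold_radius=10.0, gold_z_gap=8.0, n_strands=4,
                          strand_radius=2.0, carbon_thickness=8.0,
                          density_gold=0.03, density_dna=0.006,
                          density_carbon=0.00125)
    ph = pt.build_phantom(spec, seed=seed)
    proj = pt.project_phantom(ph, pt.Orientation())
    phi = resize(proj, (320, 320), order=1)
    phi *= 1.0 / phi.max()
    optics = pt.OpticsConfig(60.0, 3.0, defocus_nm=true_defocus_nm)
    scan = pt.make_raster_scan((5, 5), 12.0, (0.0, 0.0))
    return pt.simulate_4dstem(phi, optics, scan, DoseSpec(88.0, 12.0),
                              pixel_size=0.75, window=256, noiseless=True)
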