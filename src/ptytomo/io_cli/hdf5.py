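"""HDF5 layout for 4D diffraction stacks.

One file per tilt: dataset ``/data`` (n, ky, kx), ``/scan/positions_nm``
(n, 2), with optics / dose / provenance attributes on the root group.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from ptytomo.forward4d import DiffractionStack4D, ScanPattern
from ptytomo.optics import DoseSpec, OpticsConfig


def write_stack_hdf5(path, stack: DiffractionStack4D) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=stack.intensities)
        scan = fh.create_group("scan")
        scan.create_dataset("positions_nm",
                            data=np.asarray(stack.scan.positions_nm))
        scan.attrs["step_nm"] = stack.scan.step_nm
        scan.attrs["shape"] = stack.scan.shape
        o = stack.optics
        fh.attrs.update({
            "voltage_kv": o.voltage_kv, "alpha_mrad": o.alpha_mrad,
            "beta_mrad": o.beta_mrad, "defocus_nm": o.defocus_nm,
            "cs_mm": o.cs_mm,
            "dose_per_area": stack.dose.dose_per_area,
            "dose_step_nm": stack.dose.step_nm,
            "pixel_size_nm": stack.pixel_size,
            "bf_radius_px": stack.bf_radius_px,
            "noiseless": stack.noiseless,
            "processing": json.dumps(list(stack.processing)),
        })
        if stack.seed is not None:
            fh.attrs["seed"] = stack.seed


def read_stack_hdf5(path) -> DiffractionStack4D:
    with h5py.File(path, "r") as fh:
        data = fh["data"][...]
        pos = fh["scan/positions_nm"][...]
        scan = ScanPattern(tuple(map(tuple, pos)),
                           float(fh["scan"].attrs["step_nm"]),
                           tuple(int(v) for v in fh["scan"].attrs["shape"]))
        optics = OpticsConfig(
            voltage_kv=float(fh.attrs["voltage_kv"]),
            alpha_mrad=float(fh.attrs["alpha_mrad"]),
            beta_mrad=float(fh.attrs["beta_mrad"]),
            defocus_nm=float(fh.attrs["defocus_nm"]),
            cs_mm=float(fh.attrs["cs_mm"]))
        dose = DoseSpec(float(fh.attrs["dose_per_area"]),
                        float(fh.attrs["dose_step_nm"]))
        seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
        return DiffractionStack4D(
            data, scan, optics, dose,
            pixel_size=float(fh.attrs["pixel_size_nm"]),
            bf_radius_px=float(fh.attrs["bf_radius_px"]),
            seed=seed, noiseless=bool(fh.attrs["noiseless"]),
            processing=tuple(json.loads(fh.attrs["processing"])))
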