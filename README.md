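# ptytomo

Synthetic electron ptychographic tomography, end to end: simulate
defocused-probe 4D-STEM tilt series of a weak-phase phantom (DNA-like
strands and shells, gold nanoparticles, carbon support), recover 2D
phase maps with the extended ptychographic iterative engine (ePIE)
including post-acquisition defocus refinement, reconstruct 3D volumes
with a GENFIRE-style Fourier iterative algorithm, and quantify contrast
ratios and FRC/FSC resolution with the half-bit criterion.

## Layout

| module | contents |
| --- | --- |
| `ptytomo.optics` | electron wavelength, probe formation, Fresnel/angular-spectrum propagation, CTF first zero, λ/(α+β) resolution, overlap and dose accounting |
| `ptytomo.phantom` | 3D phase phantoms (gold spheres + DNA shells, random-walk strands, carbon slab), projection at dual-axis orientations, tilt schemes |
| `ptytomo.forward4d` | 4D-STEM forward model: exit wave → far-field intensities, Poisson noise, bright-field cropping, threshold preprocessing |
| `ptytomo.epie` | ePIE reconstruction, band-limited random object initialization, sharpness-scored post-acquisition defocus search |
| `ptytomo.tomo` | translational tilt-series alignment, Fourier-slice gridding + positivity-constrained iterative 3D reconstruction, reprojection |
| `ptytomo.metrics` | gold/background normalization, equal-voxel histogram peaks, contrast ratio R, checkerboard dataset splitting, FRC/FSC with half-bit / 0.143 / 0.5 thresholds |
| `ptytomo.io_cli` | MRC + HDF5 + angle-table I/O, pipeline configuration, end-to-end pipeline |

## CLI

```bash
ptytomo simulate --outdir sim/ --seed 1            # phantom → tilt HDF5 files
ptytomo ptycho --input sim/tilt_000.h5 --output phase.mrc --iterations 100 --alpha 0.5 --seed 7
ptytomo postfocus --input sim/tilt_000.h5 --output refocused.mrc --center-um -40
ptytomo align --projections projs.mrc --angles sim/angles.txt --output aligned.mrc
ptytomo tomo --projections aligned.mrc --angles sim/angles.txt --output vol.mrc --iterations 100 --positivity
ptytomo metrics --a halfA.mrc --b halfB.mrc --criterion halfbit
ptytomo pipeline --outdir run/ --seed 0            # full desk-scale pipeline + JSON report
```

`ptytomo pipeline` accepts a YAML configuration via `--config`; every
randomized stage derives its seed from the master seed, so reports are
bitwise reproducible.

## Conventions

Lengths in nm, angles in mrad/degrees, doses in e⁻/Å²; negative defocus
is underfocus; arrays are indexed (z, y, x) / (row, col), 0-based, with
physical coordinates at pixel centres and rotation about the grid
centre. Volumes are written as MRC2014 (float32, little-endian), 4D
stacks as one HDF5 file per tilt, and orientation/defocus tables as
plain text.
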