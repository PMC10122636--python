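# boneibr

Inverse bone (re)modeling (IBR) with voxel micro-FE and homogenized FE
models, in pure scientific Python (numpy/scipy).

IBR infers the physiological loading of a bone from its microstructure: a
set of unit load cases is applied to a finite element model, and
non-negative scale factors are found such that the combined strain energy
density (SED) field matches a target stimulus as closely as possible.
`boneibr` implements the full chain at two scales:

- **Tissue level (micro-FE).** Binary voxel images are converted one
  element per voxel into 8-node hexahedral meshes and solved under
  displacement boundary conditions; the target stimulus is a constant
  tissue SED (0.02 MPa by default).
- **Continuum level (homogenized FE).** A coarse regular hex grid is built
  over the image; per-element relative density is sampled with spheres and
  mapped to power-law materials (density-only isotropic, or
  density+fabric orthotropic with MIL fabric). The target stimulus is
  density dependent, `U0 * rho^d`, with `U0` the tissue stimulus and the
  exponent `d` calibrated from KUBC-homogenized microstructure cubes
  (default `d = 1.19`).

Everything is testable without external data: `boneibr.synth` generates
seeded Gaussian-random-field trabecular cubes and cortex-shelled section
phantoms with controllable density and anisotropy.

## Package layout

| module | contents |
| --- | --- |
| `boneibr.image` | `VoxelImage` container, MetaImage (`.mhd`/`.raw`) and NRRD I/O |
| `boneibr.synth` | GRF cubes and section phantoms (`PhantomSpec`) |
| `boneibr.fesolver` | hex meshes, materials, element stiffness, sparse solves, SED/reactions |
| `boneibr.homogenize` | six canonical KUBC load cases, apparent stress/stiffness, optimized continuum stimulus |
| `boneibr.ibr` | NNLS optimization core, targets, CV, force scaling, exponent calibration |
| `boneibr.matmap` | sphere density sampling, density / density+fabric materials, MIL fabric |
| `boneibr.metrics` | off-axis angle, angle/magnitude scores, regression + Lin's CCC |
| `boneibr.pipeline` | end-to-end cube calibration and section comparison studies |
| `boneibr.export` | VTK / Abaqus-INP / CSV / JSON writers |

## CLI

```sh
# generate a synthetic microstructure
boneibr synth --kind cube --density 0.3 --shape 40 40 40 --spacing 0.13 --seed 1 -o cube.mhd

# KUBC homogenization + tissue-level IBR of one cube
boneibr homogenize cube.mhd --E 12000 --nu 0.3 --disp -0.001 -o cube_result.json

# calibrate the continuum stimulus exponent from per-cube results
boneibr calibrate results_dir/ --ustar 0.02 -o stimulus.json

# IBR on a JSON problem file (tissue or continuum target)
boneibr ibr solutions.json --model continuum --ustar 0.02 --d 1.19 -o ibr.json

# compare two force predictions
boneibr compare a.json b.json -o comparison.csv

# end-to-end desk-scale studies
boneibr run-cube-study --n-cubes 10 --shape 32 --density-range 0.1 0.6 -o cube_study.json
boneibr run-section-study --shape 32 32 48 --density 0.3 --cortex 0.3 -o section_study.json
```

## Conventions

- Units are mm-N-MPa; SED is in MPa (= mJ/mm^3).
- Voigt order (11, 22, 33, 23, 13, 12) with engineering shear strain.
- KUBC shear load cases use tensor shear `E_kl = d/(2L)` (face tangential
  displacement magnitude `|d|`); apparent stress is averaged over the total
  cube volume with pores contributing zero.
- Fabric eigenvalues are normalized to determinant one; the
  density+fabric material is the standard compliance-based
  Zysset-Curnier parameterization.
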