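# meshct

Synthetic DICOM CT series from density-tagged triangle meshes.

Medical-physics research regularly needs CT data with *known* ground
truth — QA phantoms, displacement phantoms for validating image
registration, lesion phantoms for planning studies, breathing 4D series
for motion management — but real patient CTs come with ethics overhead
and unknown truth. `meshct` generates such data synthetically: it
converts watertight STL/OBJ meshes, each tagged with a Hounsfield
density and an overlap priority, into DICOM CT series that planning
systems can import directly.

## Method in brief

A scene of closed triangle surfaces S₁…Sₙ with densities ρᵢ (HU) and
priorities pᵢ is rasterised onto a grid covering its bounding box with
user-chosen spacing. Membership of a sample point x in Sᵢ uses the
even–odd parity rule: x ∈ Sᵢ iff a ray from x crosses ∂Sᵢ an odd number
of times. The sample's HU is

    HU(x) = ρ_argmax{pᵢ : x ∈ Sᵢ}        (background −1000 HU if none;
                                          equal priority → higher ρ)

Voxelisation is adaptive and two-pass: pass one classifies each voxel
centre; voxels whose value differs from a 6-connected neighbour are
boundary voxels and are re-sampled on a k×k×k sub-lattice (default
k = 3), the voxel HU becoming the mean of its samples — a partial-volume
value. Degenerate casts (edge/vertex grazing) are re-cast along a
perturbed direction. Optional image-domain artefact simulators add
Gaussian noise, metal streaks (`I·e^{−μr}` radial deposits), partial
volume blur and sinusoidal ring artefacts. Slices are exported as CT
Image Storage objects (unsigned 16-bit, slope 1 / intercept −1024, HU in
[−1024, 3071]); 4D series tag each phase with TemporalPositionIndex /
NumberOfTemporalPositions.

See `docs/methods.md` for the full model, parameter meanings and
numerical choices.

## Worked example

Generate the three-cylinder lung phantom (water body at 0 HU, −200 HU
lungs, 2000 HU metal sphere) and export it at 2.5 mm:

```sh
$ meshct phantom lung-metal demo --lung-offset-mm 10 --spacing-mm 2.5
wrote 4 meshes and scene.yaml to demo
$ meshct voxelise demo/scene.yaml
... INFO meshct: scene: 4 structures
... INFO meshct: voxelised: dims (135, 96, 80)
... INFO meshct: wrote 80 files to demo/dicom
```

The phantom spans 336 × 240 × 200 mm, so at 2.5 mm the grid is
135 × 96 × 80 voxels and the series holds one file per axial slice
(80). Reading the series back:

```python
>>> from meshct.dicom_io import read_series
>>> vol, meta = read_series("demo/dicom")
>>> vol.hu.max()            # the metal insert survives end-to-end
2000.0
>>> # modal HU of the phantom interior is the assigned water density
>>> import numpy as np
>>> np.bincount((vol.hu.ravel() + 1024).astype(int)).argmax() - 1024
0
```

Lung-interior voxels read −200 HU, background −1000 HU, and boundary
voxels take intermediate partial-volume values. A `phases:` block in the
config (count, SI/AP amplitudes) switches the same pipeline to a cyclic
breathing 4D export; `meshct validate` checks a config without running,
and `meshct artefact` degrades an existing series.

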