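# nirsmap

Channel-placement design for functional near-infrared spectroscopy
(fNIRS) from photon-transport simulation.

fNIRS measures cortical hemodynamics through source–detector optode
pairs ("channels") placed on the scalp, but an optode montage does not by
itself say *which* brain region each channel samples. `nirsmap` answers
that question quantitatively: it simulates photon migration through a
segmented head volume, computes each channel's spatial sensitivity map,
expresses it as a percent **specificity** to the regions of a brain
atlas, and turns the resulting look-up tables into ranked channel
selections for a target region of interest (ROI). It is aimed at
researchers planning fNIRS montages — in particular with developmental
populations, where head geometry (and hence channel-to-ROI
correspondence) differs strongly from adult heads.

## The computation

For each optode position a voxel Monte Carlo simulation yields the
photon fluence `Φ(i)` per voxel, normalized by the total weight absorbed
in the head. A channel formed by source *s* and detector *d* has the
voxelwise normalized sensitivity

    normSens(ch, i) = Φ_s(i) · Φ_d(i) / Σ_j Φ_s(j) · Φ_d(j),

which sums to 1 over the volume (the channel's photon measurement
density function). Its brain sensitivity and ROI specificity are

    brainSens(ch)      = Σ_{j ∈ brain} normSens(ch, j)
    Specificity_R (ch) = 100 · Σ_{k ∈ R} normSens(ch, k) / brainSens(ch),

with brain voxels outside every atlas ROI collected in a
`Brain_Outside` compartment, so each channel's specificities sum to
100. Uncorrected (volume-relative) sensitivities per compartment (ROIs,
`Brain_Outside`, scalp, skull, CSF) sum to 1. Each channel also gets a
sensitivity-weighted coordinate, `Σ_j coord(j) · normSens(ch, j) /
brainSens(ch)` over brain voxels, and its source–detector separation.

Group-level tables average the *uncorrected* sensitivities per ROI
across members and renormalize to 100; member channel coordinates are
carried into a common template space by a least-squares affine fitted on
label-paired 10–10 electrode positions.

The montage is the standard 81-position 10–10 system, constructed on
any closed scalp surface by iterative vertex placement and proportional
geodesic subdivision of the fiducial-defined reference curves. Seven
positions (Nz, N1, N2, AF9, AF10, T9, T10) are excluded, the remaining
74 are split into 38 sources and 36 detectors, and neighboring pairs
form 130 channels (packaged design table).

Everything runs on self-contained synthetic phantoms — concentric
ellipsoidal shells (scalp, skull, CSF, gray-matter shell, white-matter
core) with a sectorized, mirror-symmetric gray-matter parcellation — or
on user-supplied NIfTI segmentations and atlas label volumes.

## Worked example

```python
from nirsmap.pipeline import run_pipeline

config = {
    "phantom": {"preset": "adult-like", "grid_shape": [64, 64, 64],
                "voxel_size_mm": 2.5, "outer_radii_mm": [65, 75, 60],
                "n_sectors": 8},
    "simulation": {"n_photons": 100_000, "seed": 7},
    "montage": {"channels": ["C3-C1", "C4-C2", "C3-C5", "C4-C6",
                             "T7-C5", "T8-C6"]},
    "selection": {"roi": "Sector_4_L", "cutoff_percent": 30.0,
                  "force_symmetry": True},
}
art = run_pipeline(config, out_dir="example_out")
print(art["table"].data[["source", "detector", "separation_mm",
                         "Sector_3_L", "Sector_4_L",
                         "Brain_Outside"]].round(2).to_string())
```

prints

```
        source detector  separation_mm  Sector_3_L  Sector_4_L  Brain_Outside
channel
T7-C5       T7       C5          19.65       36.52       49.43          13.83
C3-C5       C3       C5          19.54       37.28       47.53          15.19
C3-C1       C3       C1          19.61       36.66       48.63          14.55
C4-C2       C4       C2          19.61        0.09        0.10          14.57
C4-C6       C4       C6          19.54        0.00        0.00          14.88
T8-C6       T8       C6          19.65        0.00        0.00          13.74
```

The three left-hemisphere channels over the target sector reach 48–49%
specificity to `Sector_4_L` (the left parieto-central sector of the
synthetic atlas), with the remainder of their brain sensitivity split
between the neighboring sector and `Brain_Outside`; their right-side
homologues see essentially none of it. At the default 30% cut-off the
selection keeps `T7-C5`, `C3-C1` and `C3-C5`, and because
`force_symmetry` is on, their mirror channels `T8-C6`, `C4-C2` and
`C4-C6` are added so the montage stays hemispherically symmetric —
`art["selection"].channel_ids` lists all six. Every row of the exported
look-up table sums to 100 across ROI columns plus `Brain_Outside`.

The same pipeline is available from the shell:

```sh
nirsmap phantom --preset adult-like --voxel 2.5 --sectors 8 --out head/
nirsmap montage --head head/four_class.nii.gz --out montage.json
nirsmap run --config pipeline.yaml
nirsmap select --table lookup_group.csv --atlas-roi Sector_4_L \
    --cutoff 10 --force-symmetry --out selection.json
```

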