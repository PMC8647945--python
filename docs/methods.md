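# Methods

This note documents the models, numerical choices and limitations behind
`nirsmap`, in the order the pipeline runs them.

## Synthetic head phantoms

`make_layered_phantom` builds a head as concentric ellipsoids: an outer
scalp surface with semi-axes `outer_radii_mm`, then scalp, skull and CSF
shells of configurable thickness, a gray-matter (GM) shell
(`gm_thickness_mm`, default 4 mm) and a white-matter (WM) core. Two
presets set layer thicknesses: `adult-like` (scalp 6 mm, skull 6.5 mm,
CSF 2.5 mm) and `infant-like` (3 / 2 / 2.5 mm), reflecting the thinner
extracerebral tissue of infant heads. Defaults are in the range used for
layered slab/head models in diffuse optics; they are geometry
parameters, not fits.

The synthetic atlas partitions GM voxels into `n_sectors` angular
sectors. For even `n` the sectors are hemisphere × angular bins of
`atan2(z, y)` — an angle *independent of x* — so left/right sector pairs
(`Sector_k_L` / `Sector_k_R`) are exact voxelwise mirror images about
the mid-sagittal plane. Odd `n > 1` gives bilateral (self-mirror)
sectors; `n = 1` labels all GM as one ROI, leaving the WM core as
`Brain_Outside`. Grids with even dimensions put the mirror plane between
voxel columns, which makes all symmetry properties exact at voxel level;
with odd grids, voxels exactly on the midline are left in
`Brain_Outside`. Phantom generation is deterministic.

What the phantoms emulate: layered tissue geometry, a brain parcellation
with exact hemispheric symmetry, and realistic layer thickness / head
size scaling. What they do not: cortical folding, anatomical asymmetry,
partial-volume effects of real segmentations, eyes/neck tissue, and
inter-individual anatomical variability (synthetic "group members"
share one geometry and differ only in Monte Carlo noise). Passing tests
therefore validate the *computational contracts* — normalization,
symmetry, selection logic — not anatomical accuracy on real heads.

## 10–10 montage construction

The scalp surface is extracted as the 0.5 isosurface of the lightly
smoothed (σ = 1 voxel) head mask and triangulated. All reference curves
are plane sections of this mesh:

* mid-sagittal: plane through nasion (Nz), inion (Iz) and the current
  vertex estimate; the coronal curve analogously through the
  preauricular points (LPA, RPA). The vertex Cz is iterated (up to 25
  rounds, 0.05 mm tolerance) until it bisects both curves.
* midline positions at 10% arc fractions Nz→Iz; central coronal
  positions (T7 … T8) at 10% fractions LPA→RPA.
* a lower ring at fiducial level through Nz, LPA/RPA, Iz (N1, AF9, F9,
  FT9, T9, TP9, P9, PO9, I1 and right homologues at 10% fractions of
  each half), and an upper ring through Fpz, T7/T8, Oz (Fp1, AF7, F7,
  FT7 at 20% fractions of the Fpz→T7 arc, and so on).
* intermediate coronal rows (e.g. F7–Fz–F8) subdivided at 25/50/75%
  (or 50% for the AF and PO rows).

This yields the 81 labeled positions. On a spherical phantom the
construction is tested against an independent closed-form circle-section
oracle; agreement is required within one voxel. The approach assumes a
closed, star-convex scalp — true for phantoms and whole-head
segmentations, not for clipped or open surfaces (rejected with an
error).

Roles and channels are a fixed montage design shipped as packaged CSVs:
7 positions excluded, a 38-source/36-detector split and 130
source–detector channels that join neighboring optodes (separation below
0.4386 × head radius on a spherical reference, i.e. the first two
neighbor shells of the 10–10 layout). Optode roles named in published
channel examples are honored; the remainder follow a left-right
symmetric, row-alternating assignment. The channel table is closed under
left-right mirroring, and every retained optode carries at least one
channel. `build_channels` accepts user pairings for other designs.

## Photon Monte Carlo

Weighted-packet voxel Monte Carlo with the standard estimator set:

* step sampling: optical depth `-ln(ξ)` consumed voxel-by-voxel
  (`μ_t = μ_a + μ_s` per tissue), with voxel indices tracked
  incrementally along the ray;
* absorption: weight fraction `μ_a/μ_t` deposited at each interaction;
  fluence per voxel is `deposited / (μ_a · V)` where `μ_a > 0` and the
  track-length estimate `Σ w·ℓ / V` in non-absorbing media (CSF-like),
  both unbiased for the same quantity;
* scattering: Henyey–Greenstein with per-tissue anisotropy `g`
  (isotropic sampling when `g = 0`);
* termination: Russian roulette below weight 10⁻⁴ (survival factor 10),
  and hard termination on leaving the head or grid. No refractive
  boundary reflections are modeled; the refractive index is carried for
  the optional maximum-path cutoff only (continuous-wave accumulation is
  the default, since all downstream quantities use total fluence).

Randomness comes from an xorshift128+ stream seeded through splitmix64,
one independent stream per (member, optode) run derived with
`numpy.random.SeedSequence`, making runs bit-reproducible and
order-independent. Validation: Beer–Lambert attenuation in a pure
absorber within 3σ binomial error; shell-averaged fluence around an
isotropic source in a homogeneous medium within 10% of the diffusion
approximation `(4πDr)⁻¹ e^{-μ_eff r}` at 10–25 mm; energy conservation
(absorbed + escaped = launched) to better than 0.1% at 10⁶ photons.

The packaged optical-property table holds representative near-infrared
(~690–800 nm) values for scalp, skull, CSF, GM and WM, expressed in
similarity-reduced form: `g = 0` with `μ_s` set to the reduced
scattering coefficient `μ_s′ = μ_s (1 − g)`. Continuous-wave fluence in
the diffusive regime depends on tissue only through `(μ_a, μ_s′)`, so
this choice preserves the sensitivity distributions while keeping
desk-scale runs fast; the kernel fully supports `g ≠ 0` for users who
supply anisotropic tables. All specificity quantities are ratios and are
additionally invariant to the fluence normalization constant, so
moderate changes to the optical table shift sensitivity profiles but
never break the normalization contracts.

Fluence normalization divides by the total absorbed weight (rather than
the launched photon count); the two conventions differ by the escape
fraction, which cancels in every specificity and is recorded in the
`FluenceVolume` metadata either way.

Optode launch geometry: the source is placed at the head-surface voxel
nearest the electrode (error if none lies within one voxel diagonal),
directed along the inward surface normal estimated from the gradient of
the smoothed head mask. Transport requires an axis-aligned RAS affine;
rotated acquisitions must be resampled first.

## Sensitivity, specificity and tables

The channel equations are implemented exactly as stated in the README;
the product-field denominator is the grid-wide sum of the
source × detector fluence product. Design points worth recording:

* voxel *centers* define coordinates in the sensitivity-weighted channel
  coordinate (the plausible alternative — corners — would shift results
  by half a voxel).
* compartments not reported in the look-up tables (eyes, other
  inside-skull tissue) are tracked in a residual `other` compartment so
  the global sum-to-1 invariant is exact rather than approximate.
* exports round specificities to 4 decimals; all comparisons (including
  the selection cut-off) use full precision, so the cut-off cannot flap
  on rounded ties.
* specificity requires `brainSens > 0`; a channel blind to the brain is
  an error, not a zero row.

Group tables re-derive specificity from member-averaged uncorrected
sensitivities (unweighted across members), rather than averaging member
specificities; the two differ when members' brain sensitivities differ,
and the re-derivation keeps rows summing to 100 by construction.
Electrode coregistration uses the closed-form least-squares affine on
label-paired electrodes — labels give exact correspondences, so no
probabilistic point matching is needed; degenerate (coplanar)
configurations are rejected via the singular values of the centered
coordinate matrix. Separation statistics use the sample (n−1) standard
deviation.

## Channel selection

Selection keeps channels whose specificity to the target ROI *strictly
exceeds* the cut-off (default 30%), sorted by specificity with ties
broken by channel id. Three views are derived: landmarks (channels for
the ROI), channels (all ROIs above the cut-off per selected channel) and
the distinct sources/detectors. `force_symmetry` adds each selected
channel's mirror channel when present *regardless of its own
specificity* (union semantics — the alternative, intersection, would
drop asymmetric findings rather than complete them); mirror-less
channels are reported as unpairable with a warning. The operation is
idempotent and its output closed under mirroring. Raising the cut-off
can only shrink a selection.

## Problem sizes

Default desk-scale conditions used throughout the tests and the
acceptance script: 64³ grids at 2.5 mm voxels, 8-sector atlases, 10⁵
photons per optode for montage-level runs (10⁶ for the physics
oracles), and 2–3 member groups. The per-channel normalization
invariants hold to 10⁻⁶ regardless of photon count; photon counts only
set the Monte Carlo noise on the specificity values themselves.
Production-quality specificity estimates on real segmentations warrant
10⁷–10⁸ photons per optode and the subject's own anatomical atlas.

## Known limitations

* No refractive-index mismatch at boundaries (no internal reflection);
  fluence near the surface is therefore slightly underestimated
  relative to Fresnel-aware codes.
* Voxel transport only; no tetrahedral meshes, no GPU, no time-resolved
  output beyond the optional path-length cutoff.
* The packaged 130-channel pairing is a reconstruction of the canonical
  neighbor-pairing design from its published structural constraints, not
  a transcription of a distributed table; custom pairings can be passed
  to `build_channels`.
* Synthetic group members share one head geometry; group machinery is
  exercised end-to-end, but anatomical between-subject variance is out
  of scope for the phantom generator.
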