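"""Segmented head volumes, atlas parcellations, and synthetic layered phantoms.

The forward model operates on voxelized head representations:

* :class:`TissueLabelVolume` — the multi-class tissue segmentation that
  drives photon transport (gray matter, white matter, CSF, scalp, skull, ...).
* :class:`FourClassVolume` — the coarse scalp/skull/CSF/brain segmentation
  used for the brain-sensitivity bookkeeping.
* :class:`AtlasVolume` — an ROI parcellation of the brain; brain voxels
  carrying no ROI label form the implicit ``Brain_Outside`` compartment.

Real studies derive these from segmented MRIs.  For self-contained use and
testing, :func:`make_layered_phantom` builds concentric ellipsoidal shells
(scalp, skull, CSF, a gray-matter shell and a white-matter core) with a
sectorized gray-matter parcellation whose left/right ROIs are exact mirror
images about the mid-sagittal plane.

All volumes are written/read as NIfTI-1 with a JSON sidecar holding the
label-name maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "TissueLabelVolume",
    "FourClassVolume",
    "AtlasVolume",
    "PhantomSpec",
    "make_layered_phantom",
    "derive_four_class",
    "read_label_volume",
    "write_label_volume",
    "DEFAULT_FOUR_CLASS_MAPPING",
]

# Canonical coarse classes.  "other" is the residual, non-reported class:
# tissue that absorbs light (eyes, neck muscle, spinal bone) but is not
# tabulated as scalp/skull/CSF/brain in the sensitivity tables.
FOUR_CLASS_LABELS = {"outside": 0, "scalp": 1, "skull": 2, "CSF": 3,
                     "brain": 4, "other": 5}
FOUR_CLASS_NAMES = {v: k for k, v in FOUR_CLASS_LABELS.items()}

#: Default tissue-name -> coarse-class mapping.
DEFAULT_FOUR_CLASS_MAPPING: dict[str, str] = {
    "air": "outside",
    "skin": "scalp",
    "skull": "skull",
    "CSF": "CSF",
    "GM": "brain",
    "WM": "brain",
    "NMA": "brain",
    "other-brain": "brain",
    "eyes": "other",
    "other-inside-skull": "other",
}


def _as_voxel_size(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths (mm) from the affine's column norms."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class _LabelGrid:
    """Shared behaviour of integer label grids with NIfTI-style geometry."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("label grid must be a nonempty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label grid must hold integer data")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(_as_voxel_size(self.affine) <= 0):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return _as_voxel_size(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (…,3) 0-based voxel-center indices to world mm (RAS)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "_LabelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class TissueLabelVolume(_LabelGrid):
    """Multi-class tissue segmentation (0 = outside/air)."""

    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_names) - {0}
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        self.label_names.setdefault(0, "air")

    def head_mask(self) -> np.ndarray:
        """Boolean mask of voxels belonging to the head (any tissue)."""
        return self.labels > 0


@dataclass
class FourClassVolume(_LabelGrid):
    """Coarse scalp/skull/CSF/brain segmentation on the same grid."""

    @property
    def class_names(self) -> dict[int, str]:
        return dict(FOUR_CLASS_NAMES)

    def brain_mask(self) -> np.ndarray:
        return self.labels == FOUR_CLASS_LABELS["brain"]

    def head_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class AtlasVolume(_LabelGrid):
    """ROI parcellation; nonzero labels only on brain voxels.

    Brain voxels with ``roi_labels == 0`` form the implicit
    ``Brain_Outside`` region.
    """

    roi_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        names = list(self.roi_names.values())
        if len(names) != len(set(names)):
            raise ValueError("duplicate ROI names")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.roi_names)
        if missing:
            raise ValueError(f"ROI labels without names: {sorted(missing)}")

    @property
    def roi_labels(self) -> np.ndarray:
        return self.labels

    def validate_on_brain(self, four: FourClassVolume) -> None:
        if not self.same_grid(four):
            raise ValueError("atlas and four-class volume are on different grids")
        off_brain = (self.labels > 0) & ~four.brain_mask()
        if off_brain.any():
            raise ValueError("atlas assigns ROI labels to non-brain voxels")


# ---------------------------------------------------------------------------
# Synthetic phantom generation
# ---------------------------------------------------------------------------

_PRESET_THICKNESS = {
    # Approximate layer thicknesses (mm).  Infant heads have thinner
    # extracerebral layers and relatively thicker CSF than adult heads.
    "infant-like": {"scalp": 3.0, "skull": 2.0, "CSF": 2.5},
    "adult-like": {"scalp": 6.0, "skull": 6.5, "CSF": 2.5},
}

TISSUE_LABELS = {"GM": 1, "WM": 2, "CSF": 3, "skin": 4, "skull": 5}
TISSUE_NAMES = {v: k for k, v in TISSUE_LABELS.items()}


@dataclass
class PhantomSpec:
    """Geometry of a synthetic layered-ellipsoid head phantom.

    Parameters
    ----------
    outer_radii_mm
        Semi-axes (x, y, z) of the outer scalp ellipsoid.
    layer_thickness_mm
        Thickness of the scalp, skull and CSF shells.
    grid_shape
        Voxel grid dimensions.
    voxel_size_mm
        Isotropic voxel edge length, or a 3-vector.
    n_sectors
        Number of atlas ROIs carved out of the gray-matter shell.
    gm_thickness_mm
        Thickness of the gray-matter shell; the remaining brain core is
        white matter.
    preset
        ``"infant-like"`` or ``"adult-like"``; sets default layer
        thicknesses when ``layer_thickness_mm`` is not given.
    """

    outer_radii_mm: tuple[float, float, float] = (70.0, 85.0, 65.0)
    layer_thickness_mm: dict[str, float] | None = None
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float | tuple[float, float, float] = 3.0
    n_sectors: int = 8
    gm_thickness_mm: float = 4.0
    preset: str = "adult-like"

    def __post_init__(self) -> None:
        if self.preset not in _PRESET_THICKNESS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.layer_thickness_mm is None:
            self.layer_thickness_mm = dict(_PRESET_THICKNESS[self.preset])
        missing = {"scalp", "skull", "CSF"} - set(self.layer_thickness_mm)
        if missing:
            raise ValueError(f"missing layer thicknesses: {sorted(missing)}")
        if any(t <= 0 for t in self.layer_thickness_mm.values()):
            raise ValueError("layer thicknesses must be positive")
        total = sum(self.layer_thickness_mm.values()) + self.gm_thickness_mm
        if total >= min(self.outer_radii_mm):
            raise ValueError(
                "layer thicknesses exceed the smallest outer semi-axis"
            )
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")
        half_span = np.asarray(self.grid_shape) * self.voxel_size / 2.0
        if np.any(np.asarray(self.outer_radii_mm) >= half_span - self.voxel_size):
            raise ValueError(
                "outer radii do not fit the grid (head would be clipped); "
                "enlarge grid_shape or voxel_size_mm")

    @property
    def voxel_size(self) -> np.ndarray:
        v = np.broadcast_to(np.asarray(self.voxel_size_mm, dtype=float), (3,))
        if np.any(v <= 0):
            raise ValueError("voxel size must be positive")
        return v.copy()


def _phantom_affine(spec: PhantomSpec) -> np.ndarray:
    """RAS affine placing the world origin at the grid center."""
    v = spec.voxel_size
    shape = np.asarray(spec.grid_shape, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(v)
    affine[:3, 3] = -(shape - 1) / 2.0 * v
    return affine


def _ellipsoid_field(coords: list[np.ndarray], radii: np.ndarray) -> np.ndarray:
    """Scaled squared radius: <=1 inside the ellipsoid with given semi-axes."""
    x, y, z = coords
    return (x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2


def make_layered_phantom(
    spec: PhantomSpec,
) -> tuple[TissueLabelVolume, FourClassVolume, AtlasVolume]:
    """Generate concentric ellipsoidal shells and a sectorized GM atlas.

    Shell order, outermost first: scalp, skull, CSF, gray-matter shell,
    white-matter core.  The atlas partitions gray-matter voxels into
    ``n_sectors`` angular sectors, arranged so that left/right sector pairs
    are exact voxelwise mirror images about the mid-sagittal plane (x = 0).
    Generation is fully deterministic.
    """
    affine = _phantom_affine(spec)
    v = spec.voxel_size
    shape = spec.grid_shape
    ctr = (np.asarray(shape, dtype=float) - 1) / 2.0
    axes = [
        (np.arange(shape[d]) - ctr[d]) * v[d] for d in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)

    outer = np.asarray(spec.outer_radii_mm, dtype=float)
    t = spec.layer_thickness_mm
    assert t is not None
    r_skull = outer - t["scalp"]
    r_csf = r_skull - t["skull"]
    r_brain = r_csf - t["CSF"]
    r_wm = r_brain - spec.gm_thickness_mm

    labels = np.zeros(shape, dtype=np.int16)
    # Paint from the outside in; later assignments overwrite inner regions.
    for radii, lab in (
        (outer, TISSUE_LABELS["skin"]),
        (r_skull, TISSUE_LABELS["skull"]),
        (r_csf, TISSUE_LABELS["CSF"]),
        (r_brain, TISSUE_LABELS["GM"]),
        (r_wm, TISSUE_LABELS["WM"]),
    ):
        labels[_ellipsoid_field(coords, radii) <= 1.0] = lab

    tissue = TissueLabelVolume(labels=labels, affine=affine,
                               label_names=dict(TISSUE_NAMES))
    four = derive_four_class(tissue, DEFAULT_FOUR_CLASS_MAPPING)

    roi = np.zeros(shape, dtype=np.int16)
    gm = labels == TISSUE_LABELS["GM"]
    n = spec.n_sectors
    roi_names: dict[int, str] = {}
    if n == 1:
        roi[gm] = 1
        roi_names[1] = "Sector_1"
    else:
        x, y, z = np.meshgrid(*axes, indexing="ij")
        # Angle in the sagittal (y, z) plane is invariant under x -> -x,
        # so sectors built from it mirror exactly.
        alpha = np.arctan2(z, y)  # (-pi, pi]
        if n % 2 == 0:
            m = n // 2
            bins = np.clip(((alpha + np.pi) / (2 * np.pi) * m).astype(int), 0, m - 1)
            left = x < 0
            # Left hemisphere sectors get odd labels, right get even labels,
            # so ROI 2k-1 and 2k are mirror pairs.
            roi[gm & left] = 2 * bins[gm & left] + 1
            roi[gm & (x > 0)] = 2 * bins[gm & (x > 0)] + 2
            # Voxels exactly on x = 0 (odd grids) stay in Brain_Outside.
            for k in range(m):
                roi_names[2 * k + 1] = f"Sector_{k + 1}_L"
                roi_names[2 * k + 2] = f"Sector_{k + 1}_R"
        else:
            bins = np.clip(((alpha + np.pi) / (2 * np.pi) * n).astype(int), 0, n - 1)
            roi[gm] = bins[gm] + 1
            for k in range(n):
                roi_names[k + 1] = f"Sector_{k + 1}"
    atlas = AtlasVolume(labels=roi, affine=affine, roi_names=roi_names)
    atlas.validate_on_brain(four)
    return tissue, four, atlas


def derive_four_class(
    vol: TissueLabelVolume, mapping: Mapping[str, str]
) -> FourClassVolume:
    """Collapse a tissue segmentation into scalp/skull/CSF/brain classes.

    ``mapping`` maps tissue names (as in ``vol.label_names``) to one of
    ``outside``, ``scalp``, ``skull``, ``CSF``, ``brain``.  Every tissue
    label present in the volume must be covered.
    """
    present = [int(l) for l in np.unique(vol.labels) if l != 0]
    lut_size = max(present, default=0) + 1
    lut = np.zeros(lut_size, dtype=np.int16)
    for lab in present:
        name = vol.label_names[lab]
        if name not in mapping:
            raise ValueError(f"tissue label {lab} ({name!r}) has no class mapping")
        cls = mapping[name]
        if cls not in FOUR_CLASS_LABELS:
            raise ValueError(f"unknown four-class target {cls!r} for {name!r}")
        lut[lab] = FOUR_CLASS_LABELS[cls]
    out = lut[vol.labels]
    return FourClassVolume(labels=out, affine=vol.affine.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_label_volume(vol: _LabelGrid, path: str | Path) -> None:
    """Write a label volume as NIfTI-1 plus a JSON label-name sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))
    meta: dict = {}
    if isinstance(vol, TissueLabelVolume):
        meta = {"kind": "tissue",
                "label_names": {str(k): v for k, v in vol.label_names.items()}}
    elif isinstance(vol, AtlasVolume):
        meta = {"kind": "atlas",
                "roi_names": {str(k): v for k, v in vol.roi_names.items()}}
    elif isinstance(vol, FourClassVolume):
        meta = {"kind": "four_class"}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_label_volume(
    path: str | Path,
) -> TissueLabelVolume | FourClassVolume | AtlasVolume:
    """Read a NIfTI label volume written by :func:`write_label_volume`.

    Files lacking a sidecar are read as :class:`TissueLabelVolume` when
    integer-valued; float-valued data are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path} holds non-integer data; not a label volume")
        raise ValueError(f"{path} stores labels as float; expected integer dtype")
    affine = img.affine
    side = _sidecar_path(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    kind = meta.get("kind", "tissue")
    data = data.astype(np.int16)
    if kind == "atlas":
        names = {int(k): v for k, v in meta.get("roi_names", {}).items()}
        return AtlasVolume(labels=data, affine=affine, roi_names=names)
    if kind == "four_class":
        return FourClassVolume(labels=data, affine=affine)
    names = {int(k): v for k, v in meta.get("label_names", {}).items()}
    if not names:
        names = {int(l): f"tissue_{int(l)}" for l in np.unique(data) if l != 0}
    return TissueLabelVolume(labels=data, affine=affine, label_names=names)
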