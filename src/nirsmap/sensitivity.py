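"""Per-channel sensitivity, specificity and channel geometry.

The core quantities, per source-detector channel:

* ``normSens`` — the voxelwise product of the normalized source and
  detector fluence, divided by its grid-wide sum, so the field sums to 1
  over the volume.  This is the channel's spatial sensitivity map (the
  photon measurement density function).
* ``brainSens`` — the fraction of ``normSens`` lying in brain-class
  voxels.
* specificity — the percentage of ``brainSens`` falling in each atlas
  ROI; brain voxels outside every ROI form the ``Brain_Outside``
  compartment, so specificities sum to 100 per channel.
* uncorrected sensitivity — plain ``normSens`` sums per compartment
  (ROIs, Brain_Outside, scalp, skull, CSF, residual classes), summing to 1.
* the sensitivity-weighted channel coordinate and the source-detector
  separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mc import FluenceVolume
from .volumes import FOUR_CLASS_LABELS, AtlasVolume, FourClassVolume

__all__ = [
    "ChannelSensitivityField",
    "ChannelRecord",
    "SpecificityTable",
    "channel_norm_sens",
    "brain_sens",
    "specificity",
    "uncorrected_sensitivity",
    "channel_coordinate",
    "separation",
    "compute_channel_record",
]

BRAIN_OUTSIDE = "Brain_Outside"
_TISSUE_COMPARTMENTS = ("scalp", "skull", "CSF")
_RESIDUAL = "other"


@dataclass
class ChannelSensitivityField:
    """Voxelwise normalized sensitivity of one channel; sums to 1."""

    values: np.ndarray
    affine: np.ndarray
    channel_id: str = ""
    source: str = ""
    detector: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=float)
        if (self.values < 0).any():
            raise ValueError("sensitivity must be non-negative")
        total = self.values.sum()
        if not np.isclose(total, 1.0, rtol=1e-9, atol=0):
            raise ValueError(f"normSens must sum to 1, got {total!r}")

    def same_grid(self, other) -> bool:
        shape = other.values.shape if hasattr(other, "values") else other.labels.shape
        aff = other.affine
        return self.values.shape == shape and np.allclose(self.affine, aff)


def channel_norm_sens(
    fl_s: FluenceVolume, fl_d: FluenceVolume, channel_id: str = "",
    source: str = "", detector: str = "",
) -> ChannelSensitivityField:
    """Normalized channel sensitivity from two normalized fluence volumes.

    The voxelwise source x detector fluence product is divided by its sum
    over the whole grid.  The operation is symmetric in its arguments and
    invariant to positive rescaling of either input.
    """
    for fl, role in ((fl_s, "source"), (fl_d, "detector")):
        if fl.normalization != "normalized":
            raise ValueError(f"{role} fluence volume is not normalized")
    if not fl_s.same_grid(fl_d):
        raise ValueError("source and detector fluence grids differ")
    prod = fl_s.values * fl_d.values
    total = prod.sum()
    if total <= 0:
        raise ValueError("all-zero sensitivity product; channel is disconnected")
    return ChannelSensitivityField(
        values=prod / total, affine=fl_s.affine.copy(),
        channel_id=channel_id, source=source, detector=detector)


def brain_sens(field: ChannelSensitivityField, four: FourClassVolume) -> float:
    """Channel sensitivity to the brain: normSens summed over brain voxels."""
    if not field.same_grid(four):
        raise ValueError("sensitivity field and segmentation grids differ")
    return float(field.values[four.brain_mask()].sum())


def specificity(
    field: ChannelSensitivityField,
    atlas: AtlasVolume,
    four: FourClassVolume,
) -> dict[str, float]:
    """Percent of a channel's brain sensitivity in each ROI (plus
    ``Brain_Outside``); the values sum to 100."""
    if not field.same_grid(atlas):
        raise ValueError("sensitivity field and atlas grids differ")
    bs = brain_sens(field, four)
    if bs <= 0:
        raise ValueError("channel has zero brain sensitivity")
    brain = four.brain_mask()
    out: dict[str, float] = {}
    for lab, name in atlas.roi_names.items():
        out[name] = 100.0 * float(field.values[atlas.labels == lab].sum()) / bs
    outside = brain & (atlas.labels == 0)
    out[BRAIN_OUTSIDE] = 100.0 * float(field.values[outside].sum()) / bs
    return out


def uncorrected_sensitivity(
    field: ChannelSensitivityField,
    atlas: AtlasVolume,
    four: FourClassVolume,
) -> dict[str, float]:
    """normSens sums per compartment; all compartments together sum to 1.

    Compartments: each atlas ROI, ``Brain_Outside``, scalp, skull, CSF and
    a residual ``other`` class for head tissue outside those categories
    (eyes, neck, ...).
    """
    if not field.same_grid(atlas) or not field.same_grid(four):
        raise ValueError("grids differ")
    brain = four.brain_mask()
    out: dict[str, float] = {}
    for lab, name in atlas.roi_names.items():
        out[name] = float(field.values[atlas.labels == lab].sum())
    out[BRAIN_OUTSIDE] = float(field.values[brain & (atlas.labels == 0)].sum())
    for comp in _TISSUE_COMPARTMENTS:
        out[comp] = float(field.values[four.labels == FOUR_CLASS_LABELS[comp]].sum())
    out[_RESIDUAL] = float(
        field.values[four.labels == FOUR_CLASS_LABELS["other"]].sum())
    return out


def specificity_from_uncorrected(uncorrected: dict[str, float]) -> dict[str, float]:
    """Recompute percent specificity from uncorrected brain compartments."""
    brain_keys = [k for k in uncorrected
                  if k not in _TISSUE_COMPARTMENTS and k != _RESIDUAL]
    total = sum(uncorrected[k] for k in brain_keys)
    if total <= 0:
        raise ValueError("zero summed brain sensitivity")
    return {k: 100.0 * uncorrected[k] / total for k in brain_keys}


def channel_coordinate(
    field: ChannelSensitivityField, four: FourClassVolume
) -> np.ndarray:
    """Sensitivity-weighted mean world coordinate over brain voxels."""
    if not field.same_grid(four):
        raise ValueError("grids differ")
    bs = brain_sens(field, four)
    if bs <= 0:
        raise ValueError("channel has zero brain sensitivity")
    ijk = np.argwhere(four.brain_mask())
    w = field.values[four.brain_mask()]
    world = four.voxel_to_world(ijk)
    return (world * w[:, None]).sum(axis=0) / bs


def separation(source_pos: np.ndarray, detector_pos: np.ndarray) -> float:
    """Euclidean source-detector distance in mm."""
    return float(np.linalg.norm(np.asarray(source_pos, float)
                                - np.asarray(detector_pos, float)))


@dataclass
class ChannelRecord:
    """All per-channel quantities for one head model."""

    channel_id: str
    source: str
    detector: str
    brain_sens: float
    uncorrected: dict[str, float]
    specificity: dict[str, float]
    coordinate: np.ndarray
    separation_mm: float


def compute_channel_record(
    field: ChannelSensitivityField,
    atlas: AtlasVolume,
    four: FourClassVolume,
    source_pos: np.ndarray,
    detector_pos: np.ndarray,
) -> ChannelRecord:
    return ChannelRecord(
        channel_id=field.channel_id or f"{field.source}-{field.detector}",
        source=field.source,
        detector=field.detector,
        brain_sens=brain_sens(field, four),
        uncorrected=uncorrected_sensitivity(field, atlas, four),
        specificity=specificity(field, atlas, four),
        coordinate=channel_coordinate(field, four),
        separation_mm=separation(source_pos, detector_pos),
    )


@dataclass
class SpecificityTable:
    """Channels x ROI specificity matrix plus channel geometry.

    Thin wrapper around a DataFrame indexed by channel id with columns
    ``source``, ``detector``, ``separation_mm``, ``x``, ``y``, ``z``, one
    column per ROI, and ``Brain_Outside``.
    """

    data: pd.DataFrame
    roi_columns: list[str]
    level: str = "individual"
    atlas_name: str = "atlas"
    extra: dict = field(default_factory=dict)

    META_COLUMNS = ("source", "detector", "separation_mm", "x", "y", "z")

    def __post_init__(self) -> None:
        missing = [c for c in self.META_COLUMNS + tuple(self.roi_columns)
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        if self.level not in ("individual", "template", "group"):
            raise ValueError(f"unknown level {self.level!r}")

    @classmethod
    def from_records(
        cls, records: list[ChannelRecord], level: str = "individual",
        atlas_name: str = "atlas",
    ) -> "SpecificityTable":
        if not records:
            raise ValueError("no channel records")
        roi_cols = list(records[0].specificity)
        rows = {}
        for r in records:
            row = {
                "source": r.source, "detector": r.detector,
                "separation_mm": r.separation_mm,
                "x": r.coordinate[0], "y": r.coordinate[1],
                "z": r.coordinate[2],
            }
            row.update({k: r.specificity[k] for k in roi_cols})
            rows[r.channel_id] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "channel"
        return cls(data=df, roi_columns=roi_cols, level=level,
                   atlas_name=atlas_name)

    def row_sums(self) -> pd.Series:
        return self.data[self.roi_columns].sum(axis=1)

    def channel_specificity(self, channel: str) -> dict[str, float]:
        return self.data.loc[channel, self.roi_columns].to_dict()

    def to_csv(self, path: str | Path, decimals: int = 4) -> None:
        """Export the look-up table; specificities rounded to 4 decimals."""
        out = self.data.copy()
        out[self.roi_columns] = out[self.roi_columns].round(decimals)
        out.to_csv(path)
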