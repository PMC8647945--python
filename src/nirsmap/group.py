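"""Group-level specificity, electrode coregistration and channel properties.

Group specificity for a channel is *not* the mean of member specificities:
the uncorrected (volume-relative) sensitivities are averaged per ROI
across group members first, and the averages are then renormalized over
all ROIs (including ``Brain_Outside``) to percentages.  This weights each
member by its absolute brain sensitivity and reduces to the individual
specificity when members are identical.

Channel coordinates are carried into a common template space through an
affine fitted by least squares on label-paired 10-10 electrode positions
(labels give exact correspondences, so probabilistic point matching is
unnecessary), then averaged across members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import ElectrodeSet
from .sensitivity import SpecificityTable, _RESIDUAL, _TISSUE_COMPARTMENTS

__all__ = [
    "group_specificity",
    "AffineFit",
    "fit_electrode_affine",
    "apply_affine",
    "group_coordinates",
    "group_separation",
    "build_group_table",
]

_NON_BRAIN = set(_TISSUE_COMPARTMENTS) | {_RESIDUAL}


def _brain_keys(uncorrected: Mapping[str, float]) -> list[str]:
    return [k for k in uncorrected if k not in _NON_BRAIN]


def group_specificity(
    members: Sequence[Mapping[str, Mapping[str, float]]],
) -> dict[str, dict[str, float]]:
    """Group specificity per channel from member uncorrected sensitivities.

    Parameters
    ----------
    members
        One mapping per group member: ``{channel_id: {ROI: uncorrected}}``.
        Non-brain compartments (scalp/skull/CSF/other), if present, are
        ignored; ROI sets must agree across members.

    Returns ``{channel_id: {ROI: percent}}`` with rows summing to 100.
    """
    if not members:
        raise ValueError("need at least one group member")
    channels = list(members[0])
    rois = _brain_keys(members[0][channels[0]])
    for m in members[1:]:
        if list(m) != channels:
            raise ValueError("members have mismatched channel sets")
        for ch in channels:
            if _brain_keys(m[ch]) != rois:
                raise ValueError("members have mismatched ROI lists")
    out: dict[str, dict[str, float]] = {}
    for ch in channels:
        means = {roi: float(np.mean([m[ch][roi] for m in members]))
                 for roi in rois}
        total = sum(means.values())
        if total <= 0:
            raise ValueError(f"channel {ch}: zero summed group sensitivity")
        out[ch] = {roi: 100.0 * v / total for roi, v in means.items()}
    return out


@dataclass
class AffineFit:
    """Least-squares affine individual -> template, with residuals."""

    affine: np.ndarray
    rms_mm: float
    residuals: dict[str, float]


def fit_electrode_affine(
    individual: ElectrodeSet, template: ElectrodeSet
) -> AffineFit:
    """Affine mapping individual electrode space into template space.

    Solves ``min_A sum_l ||A x_l - y_l||^2`` over the shared electrode
    labels.  Requires at least 4 non-coplanar points.
    """
    labels = [l for l in individual.labels if l in template]
    if set(labels) != set(individual.labels) or len(labels) != len(template):
        raise ValueError("electrode sets must share the same labels")
    if len(labels) < 4:
        raise ValueError("need at least 4 paired electrodes")
    X = np.array([individual[l] for l in labels])
    Y = np.array([template[l] for l in labels])
    centered = X - X.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[2] < 1e-6 * max(svals[0], 1.0):
        raise ValueError("electrode configuration is degenerate (coplanar)")
    Xh = np.hstack([X, np.ones((len(X), 1))])
    coef, *_ = np.linalg.lstsq(Xh, Y, rcond=None)  # (4, 3)
    affine = np.eye(4)
    affine[:3, :4] = coef.T
    pred = Xh @ coef
    res = np.linalg.norm(pred - Y, axis=1)
    return AffineFit(
        affine=affine,
        rms_mm=float(np.sqrt(np.mean(res**2))),
        residuals=dict(zip(labels, res.tolist())),
    )


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return out[0] if np.asarray(points).ndim == 1 else out


def group_coordinates(
    member_coords: Sequence[Mapping[str, np.ndarray]],
    affines: Sequence[np.ndarray],
) -> dict[str, np.ndarray]:
    """Mean channel coordinate in template space across members."""
    if len(member_coords) != len(affines):
        raise ValueError("one affine per member is required")
    channels = list(member_coords[0])
    out = {}
    for ch in channels:
        mapped = [apply_affine(A, m[ch])
                  for m, A in zip(member_coords, affines)]
        out[ch] = np.mean(mapped, axis=0)
    return out


def group_separation(
    member_seps: Sequence[Mapping[str, float]],
) -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    """Per-channel and overall mean +/- sample SD of separation distances."""
    if not member_seps:
        raise ValueError("need at least one member")
    channels = list(member_seps[0])
    per_channel = {}
    for ch in channels:
        vals = np.array([m[ch] for m in member_seps], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        per_channel[ch] = (float(vals.mean()), sd)
    means = np.array([v[0] for v in per_channel.values()])
    overall = (float(means.mean()),
               float(means.std(ddof=1)) if len(means) > 1 else 0.0)
    return per_channel, overall


def build_group_table(
    member_uncorrected: Sequence[Mapping[str, Mapping[str, float]]],
    member_coords: Sequence[Mapping[str, np.ndarray]],
    member_seps: Sequence[Mapping[str, float]],
    affines: Sequence[np.ndarray],
    channel_meta: Mapping[str, tuple[str, str]],
    atlas_name: str = "atlas",
) -> SpecificityTable:
    """Assemble the group-level specificity table.

    ``channel_meta`` maps channel id -> (source label, detector label).
    The schema matches the individual table plus ``n_members`` and
    ``separation_sd_mm`` columns.
    """
    spec = group_specificity(member_uncorrected)
    coords = group_coordinates(member_coords, affines)
    seps, _ = group_separation(member_seps)
    rois = list(next(iter(spec.values())))
    rows = {}
    for ch, sp in spec.items():
        s, d = channel_meta[ch]
        row = {"source": s, "detector": d,
               "separation_mm": seps[ch][0],
               "separation_sd_mm": seps[ch][1],
               "x": coords[ch][0], "y": coords[ch][1], "z": coords[ch][2],
               "n_members": len(member_uncorrected)}
        row.update(sp)
        rows[ch] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "channel"
    return SpecificityTable(data=df, roi_columns=rois, level="group",
                            atlas_name=atlas_name)
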