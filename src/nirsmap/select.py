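"""Channel selection: cut-off filtering, forced symmetry, summary views.

A :class:`SpecificityTable` is turned into actionable channel choices for
a target ROI: channels whose specificity to the ROI *exceeds* a cut-off
(default 30%) are ranked, and three mutually consistent views are built —
the channels sensitive to the ROI ("landmarks"), every ROI each selected
channel can measure above the cut-off ("channels"), and the distinct
optodes involved ("sources and detectors").  The force-symmetry option
adds each selected channel's left-right homologue regardless of its own
specificity, making the selection closed under mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .montage import mirror_label
from .sensitivity import SpecificityTable

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "select_channels",
    "force_symmetry",
    "export_lookup",
]


@dataclass
class SelectionConfig:
    """Selection parameters; the default specificity cut-off is 30%."""

    roi: str
    cutoff_percent: float = 30.0
    force_symmetry: bool = False
    level: str = "individual"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff_percent <= 100.0:
            raise ValueError("cutoff_percent must lie in [0, 100]")


@dataclass
class SelectionResult:
    """Ranked selection with landmarks / channels / optodes views."""

    config: SelectionConfig
    landmarks: pd.DataFrame
    channels: dict[str, dict[str, float]]
    sources: list[str]
    detectors: list[str]
    unpairable: list[str] = field(default_factory=list)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.landmarks.index)


def _build_views(
    table: SpecificityTable, config: SelectionConfig, selected: list[str]
) -> SelectionResult:
    df = table.data
    roi = config.roi
    sub = df.loc[selected, ["source", "detector", "separation_mm", roi]]
    sub = sub.rename(columns={roi: "specificity"})
    # Rank by specificity, ties broken by channel id for stable output.
    order = sorted(selected, key=lambda ch: (-df.loc[ch, roi], ch))
    sub = sub.loc[order]
    channels_view = {
        ch: {
            r: float(df.loc[ch, r])
            for r in table.roi_columns
            if float(df.loc[ch, r]) > config.cutoff_percent
        }
        for ch in order
    }
    sources = sorted({df.loc[ch, "source"] for ch in order})
    detectors = sorted({df.loc[ch, "detector"] for ch in order})
    return SelectionResult(config=config, landmarks=sub,
                           channels=channels_view,
                           sources=sources, detectors=detectors)


def select_channels(
    table: SpecificityTable, config: SelectionConfig
) -> SelectionResult:
    """Channels whose specificity to the target ROI exceeds the cut-off.

    Ties exactly at the cut-off are excluded (strict inequality).  When
    ``config.force_symmetry`` is set the result is symmetrized.
    """
    if config.roi not in table.roi_columns:
        raise KeyError(
            f"unknown ROI {config.roi!r}; available: {table.roi_columns}")
    df = table.data
    selected = [ch for ch in df.index
                if float(df.loc[ch, config.roi]) > config.cutoff_percent]
    result = _build_views(table, config, selected)
    if config.force_symmetry:
        result = force_symmetry(result, table)
    return result


def force_symmetry(
    result: SelectionResult, table: SpecificityTable
) -> SelectionResult:
    """Close a selection under left-right mirroring.

    For every selected channel the mirror channel (mirror source, mirror
    detector) is added when it exists in the table, regardless of its own
    specificity.  Channels whose mirror is absent are reported as
    unpairable.  The operation is idempotent.
    """
    df = table.data
    by_pair = {(df.loc[ch, "source"], df.loc[ch, "detector"]): ch
               for ch in df.index}
    selected = set(result.channel_ids)
    unpairable = []
    for ch in result.channel_ids:
        s, d = df.loc[ch, "source"], df.loc[ch, "detector"]
        mirror = (mirror_label(s), mirror_label(d))
        if mirror in by_pair:
            selected.add(by_pair[mirror])
        elif (mirror[1], mirror[0]) in by_pair:
            # mirrored roles flip on some montages
            selected.add(by_pair[(mirror[1], mirror[0])])
        else:
            unpairable.append(ch)
            warnings.warn(
                f"mirror channel {mirror[0]}-{mirror[1]} of {ch} is not in "
                "the channel set", stacklevel=2)
    cfg = replace(result.config, force_symmetry=True)
    out = _build_views(table, cfg, sorted(selected))
    out.unpairable = unpairable
    return out


def export_lookup(table: SpecificityTable, path, decimals: int = 4) -> None:
    """Write the look-up table CSV (channel, optodes, geometry, ROI %)."""
    table.to_csv(path, decimals=decimals)
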