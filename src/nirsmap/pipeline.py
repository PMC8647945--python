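"""End-to-end pipeline: head model -> montage -> fluence -> tables -> selection.

Drives the full computation from a single YAML/JSON config and writes the
look-up tables, selection results and a manifest (seeds, parameters,
version) to an output directory.  Per-optode Monte Carlo seeds are derived
deterministically from the base seed with ``numpy.random.SeedSequence``,
so runs are reproducible and optode simulations are order-independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .group import build_group_table, fit_electrode_affine
from .mc import OpticalProperties, SimConfig, launch_geometry, normalize_fluence, simulate_fluence
from .montage import (
    ChannelSet,
    ElectrodeSet,
    assign_roles,
    build_channels,
    construct_10_10,
    default_fiducials,
    scalp_mesh,
)
from .select import SelectionConfig, export_lookup, select_channels
from .sensitivity import (
    SpecificityTable,
    channel_norm_sens,
    compute_channel_record,
)
from .volumes import (
    AtlasVolume,
    FourClassVolume,
    PhantomSpec,
    TissueLabelVolume,
    make_layered_phantom,
    read_label_volume,
)

__all__ = ["PipelineError", "run_pipeline", "simulate_member_records",
           "member_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def member_seed(base_seed: int, member: int, optode_index: int) -> int:
    """Deterministic sub-seed for one (member, optode) simulation."""
    ss = np.random.SeedSequence([int(base_seed), int(member), int(optode_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@_stage("head-model")
def _load_head(config: dict) -> tuple[TissueLabelVolume, FourClassVolume, AtlasVolume]:
    if "phantom" in config:
        spec = PhantomSpec(**config["phantom"])
        return make_layered_phantom(spec)
    head = config["head"]
    tissue = read_label_volume(head["tissue"])
    four = read_label_volume(head["four_class"])
    atlas = read_label_volume(head["atlas"])
    atlas.validate_on_brain(four)
    return tissue, four, atlas


@_stage("montage")
def _build_montage(four: FourClassVolume, config: dict):
    mcfg = config.get("montage", {})
    mesh = scalp_mesh(four)
    fiducials = default_fiducials(four)
    electrodes = construct_10_10(mesh, fiducials)
    roles = assign_roles(electrodes, mcfg.get("exclusions"))
    channels = build_channels(roles)
    subset = mcfg.get("channels")
    if subset:
        keep = set(subset)
        pairs = [p for p, cid in zip(channels.pairs, channels.ids)
                 if cid in keep]
        if len(pairs) != len(keep):
            missing = keep - set(channels.ids)
            raise ValueError(f"unknown channel ids in subset: {sorted(missing)}")
        channels = ChannelSet(pairs=pairs)
    return electrodes, roles, channels


def simulate_member_records(
    tissue: TissueLabelVolume,
    four: FourClassVolume,
    atlas: AtlasVolume,
    electrodes: ElectrodeSet,
    channels: ChannelSet,
    optics: OpticalProperties,
    n_photons: int,
    base_seed: int,
    member: int = 0,
    max_path_mm: float | None = None,
):
    """Simulate fluence for every optode a channel set needs and build
    the per-channel records for one head model."""
    optodes = sorted(channels.optodes())
    fluence = {}
    for idx, lab in enumerate(optodes):
        pos, direction = launch_geometry(electrodes[lab], tissue)
        cfg = SimConfig(n_photons=n_photons,
                        seed=member_seed(base_seed, member, idx),
                        max_path_mm=max_path_mm)
        fluence[lab] = normalize_fluence(
            simulate_fluence(tissue, optics, pos, direction, cfg))
    records = []
    for s, d in channels:
        field = channel_norm_sens(fluence[s], fluence[d],
                                  channel_id=f"{s}-{d}", source=s, detector=d)
        records.append(compute_channel_record(
            field, atlas, four, electrodes[s], electrodes[d]))
    return records, fluence


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text)
    return dict(config)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> dict[str, Any]:
    """Run the full pipeline from a config mapping or YAML path.

    Config sections: ``phantom`` (or ``head``), ``optics``, ``montage``,
    ``simulation``, ``group``, ``selection``, ``output``.  Returns a dict
    with the produced tables, selection and artifact paths.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("output", "nirsmap_out"))
    out.mkdir(parents=True, exist_ok=True)

    tissue, four, atlas = _load_head(cfg)
    electrodes, roles, channels = _build_montage(four, cfg)

    opt_path = cfg.get("optics")
    optics = (OpticalProperties.from_yaml(opt_path) if opt_path
              else OpticalProperties.default())

    sim = cfg.get("simulation", {})
    n_photons = int(sim.get("n_photons", 100_000))
    seed = int(sim.get("seed", 0))
    max_path = sim.get("max_path_mm")

    group_cfg = cfg.get("group", {})
    n_members = int(group_cfg.get("n_members", 1))

    try:
        member_tables = []
        member_unc, member_coords, member_seps = [], [], []
        for member in range(n_members):
            records, _ = simulate_member_records(
                tissue, four, atlas, electrodes, channels, optics,
                n_photons, seed, member=member, max_path_mm=max_path)
            member_unc.append({r.channel_id: r.uncorrected for r in records})
            member_coords.append({r.channel_id: r.coordinate for r in records})
            member_seps.append({r.channel_id: r.separation_mm for r in records})
            member_tables.append(SpecificityTable.from_records(
                records, level="individual", atlas_name=atlas.__class__.__name__))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'simulation' failed: {exc}") from exc

    try:
        if n_members > 1:
            # Synthetic members share one head model, so member->template
            # affines come out as identity; the machinery is exercised
            # end-to-end regardless.
            fit = fit_electrode_affine(electrodes, electrodes)
            affines = [fit.affine] * n_members
            meta = {f"{s}-{d}": (s, d) for s, d in channels}
            table = build_group_table(member_unc, member_coords, member_seps,
                                      affines, meta)
        else:
            table = member_tables[0]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'group' failed: {exc}") from exc

    lookup_path = out / f"lookup_{table.level}.csv"
    export_lookup(table, lookup_path)

    result = None
    sel_cfg = cfg.get("selection")
    selection_path = None
    if sel_cfg:
        try:
            sc = SelectionConfig(
                roi=sel_cfg["roi"],
                cutoff_percent=float(sel_cfg.get("cutoff_percent", 30.0)),
                force_symmetry=bool(sel_cfg.get("force_symmetry", False)),
                level=table.level,
            )
            result = select_channels(table, sc)
            selection_path = out / "selection.json"
            selection_path.write_text(json.dumps({
                "config": asdict(sc),
                "landmarks": result.landmarks.reset_index().to_dict("records"),
                "channels": result.channels,
                "sources": result.sources,
                "detectors": result.detectors,
                "unpairable": result.unpairable,
            }, indent=1, default=float))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'selection' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": _jsonable(cfg),
        "seed": seed,
        "n_photons": n_photons,
        "n_members": n_members,
        "n_electrodes": len(electrodes),
        "n_sources": len(roles.sources),
        "n_detectors": len(roles.detectors),
        "n_channels": len(channels),
        "outputs": {
            "lookup": str(lookup_path),
            "selection": str(selection_path) if selection_path else None,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "tissue": tissue, "four": four, "atlas": atlas,
        "electrodes": electrodes, "roles": roles, "channels": channels,
        "member_tables": member_tables, "table": table,
        "selection": result, "out_dir": out, "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
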