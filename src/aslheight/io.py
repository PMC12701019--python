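"""TIFF stack readers/writers, run configuration and the end-to-end pipeline.

Stacks are plain multi-channel TIFFs with shape (channel, x, z); channel
roles and the z pixel spacing travel in a JSON blob in the TIFF description
tag, so phantom-written stacks round-trip without sidecar files.  A config
override of the spacing always wins over metadata (and is logged).

``run_pipeline`` ties the whole method together: simulate or load wells,
measure every position, summarise wells, compare groups, and write tidy
CSVs plus a JSON manifest carrying the seed and a config hash.  All outputs
are deterministic for a fixed seed (no timestamps), so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .aggregate import serpentine_positions, summarize_well
from .errors import ConfigurationError, InsufficientDataError
from .heights import ASLMeasurement, ChannelStack, measure_well
from .phantom import PhantomConfig, render_well
from .stats import bky_adjust, compare_groups

__all__ = ["load_stack", "save_scan", "save_well", "run_pipeline"]

logger = logging.getLogger("aslheight")

_CHANNEL_ORDER = ("reflection", "calcein", "rhodamine")


def save_scan(scan, path: str | Path) -> Path:
    """Write one scan's channels to a multi-channel TIFF with JSON metadata."""
    path = Path(path)
    channels = scan.channels
    names = [c for c in _CHANNEL_ORDER if c in channels]
    data = np.stack([channels[c] for c in names]).astype(np.float64)
    meta = {"channels": names, "z_spacing_um": scan.z_spacing}
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))
    return path


def load_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    z_spacing: float | None = None,
) -> ChannelStack:
    """Load a multi-channel XZ TIFF as role-keyed images.

    Channel roles come from the TIFF description metadata when present, or
    from ``channel_map`` ({role: channel index}), which takes precedence.
    ``z_spacing`` (µm/pixel) overrides any metadata value — a mismatch is
    logged as a warning; with neither source available a
    :class:`ConfigurationError` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ConfigurationError(f"{path}: expected a (channel, x, z) stack, got shape {data.shape}")

    if channel_map is None:
        names = meta.get("channels")
        if not names:
            raise ConfigurationError(f"{path}: no channel metadata and no channel_map given")
        channel_map = {name: i for i, name in enumerate(names)}
    channels = {role: data[i] for role, i in channel_map.items() if i < data.shape[0]}
    if len(channels) < len(channel_map):
        missing = set(channel_map) - set(channels)
        raise ConfigurationError(f"{path}: channel indices out of range for {sorted(missing)}")

    meta_spacing = meta.get("z_spacing_um")
    if z_spacing is not None:
        if meta_spacing is not None and not np.isclose(meta_spacing, z_spacing):
            logger.warning(
                "%s: config z_spacing %.4g µm overrides metadata %.4g µm",
                path, z_spacing, meta_spacing,
            )
        spacing = z_spacing
    elif meta_spacing is not None:
        spacing = float(meta_spacing)
    else:
        raise ConfigurationError(f"{path}: z_spacing not in metadata; pass it explicitly")
    return ChannelStack(channels=channels, z_spacing=spacing)


def save_well(scans, outdir: str | Path, prefix: str = "pos") -> Path:
    """Write a simulated well: one TIFF per position, truth CSV, config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scan in enumerate(scans):
        save_scan(scan, outdir / f"{prefix}{i:02d}.tif")
        t = scan.truth
        rows.append(
            {"position": i, "z1_um": t.z1, "z2_um": t.z2, "z3_um": t.z3,
             "cell_um": t.true_cell_height, "asl_um": t.true_asl_height}
        )
    pd.DataFrame(rows).to_csv(outdir / "truth.csv", index=False)
    cfg = dataclasses.asdict(scans[0].config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return outdir


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _measurements_frame(measurements: list[ASLMeasurement], group: str, source: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well_id": [m.well_id for m in measurements],
            "group": group,
            "source": source,
            "position": [m.position_index for m in measurements],
            "time_min": [m.time_min for m in measurements],
            "method": [m.method for m in measurements],
            "asl_um": [m.asl_height for m in measurements],
            "cell_um": [m.cell_height for m in measurements],
            "z2_offset_um": [m.z2_calcein_offset for m in measurements],
            "flags": [";".join(sorted(m.qc_flags)) for m in measurements],
        }
    )


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run simulate/load → measure → aggregate → compare from one config.

    Config keys: ``seed``; ``method`` ("reflection", "fluorescence" or
    "both"); ``wells`` — a list of {id, group, simulate: {phantom fields} |
    stacks: [tiff paths]}; optional ``sampling`` {rows, cols,
    central_fraction}, ``z_spacing`` override, ``qc`` {r2_threshold,
    min_prominence}, ``profile_width``, ``compare`` — list of [group_a,
    group_b] pairs, ``output_dir``.

    Returns {"positions", "summaries", "comparisons"} DataFrames and the
    manifest dict; when an output directory is set, writes positions.csv,
    summaries.csv, comparisons.csv, manifest.json and run.log.  A well with
    no usable positions is a hard error before anything is written.
    """
    if not config.get("wells"):
        raise ConfigurationError("config lists no wells")
    seed = int(config.get("seed", 0))
    method = config.get("method", "reflection")
    methods = ("reflection", "fluorescence") if method == "both" else (method,)
    if any(m not in ("reflection", "fluorescence") for m in methods):
        raise ConfigurationError(f"unknown method {method!r}")
    sampling = config.get("sampling", {})
    plan = serpentine_positions(
        rows=int(sampling.get("rows", 3)),
        cols=int(sampling.get("cols", 5)),
        central_fraction=float(sampling.get("central_fraction", 0.6)),
    )
    qc = config.get("qc", {})
    measure_kwargs = {
        "width": int(config.get("profile_width", 5)),
        "min_prominence": float(qc.get("min_prominence", 0.1)),
        "r2_threshold": float(qc.get("r2_threshold", 0.9)),
    }

    log_lines: list[str] = []
    ss = np.random.SeedSequence(seed)
    well_seeds = {w["id"]: int(s.generate_state(1)[0] % (2**31))
                  for w, s in zip(config["wells"], ss.spawn(len(config["wells"])))}

    pos_frames, summaries = [], []
    for well in config["wells"]:
        well_id = str(well["id"])
        group = str(well.get("group", well_id))
        time_min = float(well.get("time_min", 0.0))
        if "simulate" in well:
            pcfg = PhantomConfig(
                **{**well["simulate"], "n_positions": plan.n_positions}
            )
            scans = render_well(pcfg, seed=well_seeds[well_id])
            source = "simulated"
        elif "stacks" in well:
            scans = [
                load_stack(p, channel_map=well.get("channel_map"),
                           z_spacing=config.get("z_spacing"))
                for p in well["stacks"]
            ]
            source = "loaded"
        else:
            raise ConfigurationError(f"well {well_id!r} has neither 'simulate' nor 'stacks'")
        for m in methods:
            measurements = measure_well(
                scans, method=m, well_id=well_id, time_min=time_min, **measure_kwargs
            )
            try:
                summary = summarize_well(measurements)
            except InsufficientDataError as exc:
                flags = sorted({f for meas in measurements for f in meas.qc_flags})
                raise ConfigurationError(
                    f"well {well_id!r} ({m}) has no usable positions; flags seen: {flags}"
                ) from exc
            pos_frames.append(_measurements_frame(measurements, group, source))
            summaries.append({"group": group, **dataclasses.asdict(summary)})
            log_lines.append(
                f"well={well_id} method={m} n={summary.n_positions} "
                f"flagged={summary.n_flagged} mean={summary.mean:.3f} cv={summary.cv:.2f}"
            )

    positions = pd.concat(pos_frames, ignore_index=True)
    summary_df = pd.DataFrame(summaries)

    comparisons = []
    usable = positions[positions["flags"].str.split(";").apply(
        lambda fs: not any(f in ("insufficient_peaks", "fit_failure",
                                 "fit_quality", "boundary_failure") for f in fs)
    )]
    for pair in config.get("compare", []):
        ga, gb = pair
        for m in methods:
            sel = usable[usable["method"] == m]
            a = sel.loc[sel["group"] == ga, "asl_um"].to_numpy()
            b = sel.loc[sel["group"] == gb, "asl_um"].to_numpy()
            test = config.get("test", "unpaired_t")
            cmp_res = compare_groups(a, b, test=test, labels=(str(ga), str(gb)))
            comparisons.append({**dataclasses.asdict(cmp_res), "method": m})
    cmp_df = pd.DataFrame(comparisons)
    if len(cmp_df) > 1:
        cmp_df["adjusted_p"] = bky_adjust(cmp_df["p_value"].to_numpy())
    elif len(cmp_df) == 1:
        cmp_df["adjusted_p"] = cmp_df["p_value"]

    manifest = {
        "package": "aslheight",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "method": method,
        "n_wells": len(config["wells"]),
        "n_positions_per_well": plan.n_positions,
    }

    outdir = output_dir or config.get("output_dir")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        positions.to_csv(outdir / "positions.csv", index=False)
        summary_df.to_csv(outdir / "summaries.csv", index=False)
        cmp_df.to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "positions": positions,
        "summaries": summary_df,
        "comparisons": cmp_df,
        "manifest": manifest,
    }
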