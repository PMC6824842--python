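"""File formats, configuration and the end-to-end pipeline.

Channels travel as one 16-bit grayscale TIFF per channel, named
``<field_id>_{bf,green,red,blue}.tif``; tables as UTF-8 CSV with a header
row; configuration as YAML.  ``run_pipeline`` chains
simulate/segment/quantify/stats per field and pools fields, writing
droplet and aggregate tables in the source-data schema plus the binned
curves and fits, and a machine-readable run log (config hash + seed).
Logging goes to standard error so stdout stays clean for piping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import quantify as q
from . import scene as sc
from . import stats as st
from .segment import SegmentationConfig, segment_cells, segment_droplets

__all__ = [
    "PipelineConfig",
    "read_channel_stack",
    "write_channel_stack",
    "run_pipeline",
    "read_source_droplets",
]

log = logging.getLogger("microwet")

CHANNEL_NAMES = ("bf", "green", "red", "blue")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    output_dir: str = "microwet_out"
    seed: int = 0
    n_fields: int = 5
    pixel_size_um: float = 0.1625
    scene: Optional[dict] = None          # SceneSpec overrides (simulate mode)
    channels: Optional[dict[str, dict[str, str]]] = None  # field_id -> channel paths
    segmentation: dict = field(default_factory=dict)      # SegmentationConfig overrides
    log_level: str = "INFO"

    def scene_spec(self, seed: int) -> sc.SceneSpec:
        kw = dict(self.scene or {})
        kw.setdefault("pixel_size_um", self.pixel_size_um)
        if kw.get("aggregate_area_params") is not None:
            kw["aggregate_area_params"] = tuple(kw["aggregate_area_params"])
        kw["seed"] = seed
        return sc.SceneSpec(**kw)

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.segmentation)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        if cfg.channels:
            for fid, chans in cfg.channels.items():
                for name in CHANNEL_NAMES:
                    p = chans.get(name)
                    if p is None or not Path(p).exists():
                        raise FileNotFoundError(
                            f"field {fid}: channel {name!r} file missing: {p}"
                        )
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# channel I/O
# ---------------------------------------------------------------------------

def write_channel_stack(stack: sc.ChannelStack, directory) -> dict[str, Path]:
    """One 16-bit grayscale TIFF per channel, named <field_id>_<channel>.tif."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in CHANNEL_NAMES:
        arr = getattr(stack, name)
        p = directory / f"{stack.field_id}_{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.uint16))
        paths[name] = p
    return paths


def read_channel_stack(
    paths: dict[str, str | Path], pixel_size_um: float, field_id: str
) -> sc.ChannelStack:
    """Lossless load of the four 16-bit channels.

    Raises on a missing channel, mismatched dimensions, or non-16-bit data
    (8-bit inputs get a conversion hint).
    """
    arrays = {}
    for name in CHANNEL_NAMES:
        if name not in paths:
            raise FileNotFoundError(f"missing channel {name!r}")
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(f"channel {name!r} file not found: {p}")
        arr = tifffile.imread(p)
        if arr.dtype != np.uint16:
            hint = (
                " (convert with e.g. skimage.util.img_as_uint)"
                if arr.dtype == np.uint8 else ""
            )
            raise ValueError(
                f"channel {name!r} is {arr.dtype}, expected 16-bit grayscale{hint}"
            )
        arrays[name] = arr
    shapes = {n: a.shape for n, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channel dimensions differ: {shapes}")
    return sc.ChannelStack(
        bf=arrays["bf"], green=arrays["green"], red=arrays["red"],
        blue=arrays["blue"], pixel_size_um=pixel_size_um, field_id=field_id,
    )


# ---------------------------------------------------------------------------
# source-data ingestion
# ---------------------------------------------------------------------------

_AREA_ALIASES = {
    "droplet_area_um2": ("droplet_area_um2", "droplet_area", "droplet area", "area"),
    "cell_area_um2": ("cell_area_um2", "cell_area", "area covered by cells", "cells_area"),
    "live_area_um2": ("live_area_um2", "live_area", "total live cell area", "live"),
    "dead_area_um2": ("dead_area_um2", "dead_area", "total dead cell area", "dead"),
    "aggregate_area_um2": ("aggregate_area_um2", "aggregate_area", "aggregate area"),
    "survival_rate": ("survival_rate", "survival rate", "survival"),
    "repeat": ("repeat", "field", "field_id"),
}


def read_source_droplets(path) -> pd.DataFrame:
    """Read a published-schema droplet table (CSV): per-droplet areas in µm²,
    optional live/dead areas and 'repeat' field identifiers.

    Column names are matched case-insensitively against the published
    descriptions, so both this package's outputs and the paper-style raw
    tables load.
    """
    df = pd.read_csv(path)
    lower = {c.lower().strip(): c for c in df.columns}
    out = {}
    for canon, aliases in _AREA_ALIASES.items():
        for al in aliases:
            if al in lower:
                out[canon] = df[lower[al]]
                break
    if "droplet_area_um2" not in out:
        raise ValueError(
            f"{path}: no droplet-area column found among {list(df.columns)}"
        )
    res = pd.DataFrame(out)
    if {"live_area_um2", "dead_area_um2"} <= set(res.columns) and \
            "cell_area_um2" not in res.columns:
        res["cell_area_um2"] = res["live_area_um2"] + res["dead_area_um2"]
    if "repeat" not in res.columns:
        res["repeat"] = "0"
    return res


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def process_field(
    stack: sc.ChannelStack, seg_cfg: SegmentationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """segment → quantify for one field of view."""
    droplets = segment_droplets(stack.blue, seg_cfg, stack.pixel_size_um)
    live, dead = segment_cells(stack.green, stack.red, seg_cfg, stack.pixel_size_um)
    objects = q.label_aggregates(live, dead, stack.pixel_size_um)
    assignment = q.assign_to_droplets(objects, droplets)
    return q.build_tables(
        droplets, objects, live, dead, assignment,
        stack.pixel_size_um, stack.field_id,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all outputs.

    Simulate (or load) each field, segment, quantify, then pool fields and
    compute the statistical summaries.  Rerunning with the same config and
    seed reproduces the outputs byte for byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stacks: list[sc.ChannelStack] = []
    if config.channels:
        for fid, chans in sorted(config.channels.items()):
            try:
                stacks.append(read_channel_stack(chans, config.pixel_size_um, fid))
            except Exception as e:
                raise RuntimeError(f"stage=load field={fid}: {e}") from e
    else:
        for i in range(config.n_fields):
            fid_seed = config.seed * 1000 + i
            try:
                spec = config.scene_spec(seed=fid_seed)
                scn = sc.sample_scene(spec)
                stack = sc.render_channels(scn, spec)
                stack.field_id = str(i)
                stacks.append(stack)
                sc.write_ground_truth(scn, out / f"ground_truth_field{i}.csv")
            except Exception as e:
                raise RuntimeError(f"stage=simulate field={i}: {e}") from e

    seg_cfg = config.segmentation_config()
    droplet_tables, aggregate_tables = [], []
    for stack in stacks:
        try:
            dtab, atab = process_field(stack, seg_cfg)
        except Exception as e:
            raise RuntimeError(
                f"stage=segment/quantify field={stack.field_id}: {e}"
            ) from e
        dtab.to_csv(out / f"droplets_field{stack.field_id}.csv", index=False)
        atab.to_csv(out / f"aggregates_field{stack.field_id}.csv", index=False)
        droplet_tables.append(dtab)
        aggregate_tables.append(atab)
        log.info("field %s: %d droplets, %d objects",
                 stack.field_id, len(dtab), len(atab))

    droplets = pd.concat(droplet_tables, ignore_index=True) if droplet_tables \
        else pd.DataFrame(columns=q.DROPLET_COLUMNS)
    aggregates = pd.concat(aggregate_tables, ignore_index=True) if aggregate_tables \
        else pd.DataFrame(columns=q.AGGREGATE_COLUMNS)
    droplets.to_csv(out / "droplets.csv", index=False)
    aggregates.to_csv(out / "aggregates.csv", index=False)

    try:
        _write_stats(droplets, aggregates, stacks, out)
    except Exception as e:
        raise RuntimeError(f"stage=stats: {e}") from e

    run_log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_fields": len(stacks),
        "n_droplets": int(len(droplets)),
        "n_objects": int(len(aggregates)),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return out


def _write_stats(droplets, aggregates, stacks, out: Path) -> None:
    bins = st.BinSpec.default_droplet_bins()
    field_area_mm2 = (
        stacks[0].shape[0] * stacks[0].shape[1] * stacks[0].pixel_size_um**2 / 1e6
        if stacks else 1.0
    )
    st.size_distribution(droplets, field_area_mm2, bins).to_csv(
        out / "size_distribution.csv", index=False)
    with_cells = droplets[droplets["cell_area_um2"] > 0]
    if len(with_cells):
        st.survival_vs_droplet_size(droplets, bins).to_frame().to_csv(
            out / "survival_vs_droplet_size.csv", index=False)
        st.binned_mean_curve(
            with_cells["cell_area_um2"], with_cells["droplet_area_um2"], bins
        ).to_frame().to_csv(out / "droplet_size_vs_cell_area.csv", index=False)
        st.population_above_size(droplets).to_csv(
            out / "population_above_size.csv", index=False)
        surv = st.overall_survival(droplets)
        (out / "overall_survival.json").write_text(
            json.dumps({"overall_survival": surv}))
    areas = droplets["droplet_area_um2"].to_numpy(dtype=float)
    if (areas >= 10).sum() >= 2 and np.ptp(areas[areas >= 10]) > 0:
        for method in ("logbin_ls", "truncated_mle"):
            fit = st.fit_power_law(areas, method=method, xmin=10.0,
                                   xmax=float(areas.max()))
            fit.to_frame().to_csv(out / f"power_law_{method}.csv", index=False)
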