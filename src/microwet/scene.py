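"""Synthetic drying-surface scenes.

On a surface drying under moderate relative humidity, residual microdroplets
of concentrated solution persist around bacterial cells and aggregates.  The
generator in this module produces ground-truth scenes with the statistical
structure observed in such experiments:

* droplet areas follow a truncated power law, p(A) ∝ A**gamma on
  [area_min, area_max] with gamma < 0;
* the area covered by cells inside a droplet grows, on average, linearly
  with droplet area (multiplicative log-normal noise, clipped so cells never
  exceed their droplet);
* the probability that a cell is alive is a logistic function of
  log10(host droplet area), rising from ``survival_s_min`` in the smallest
  droplets to ``survival_s_max`` in the largest.

Scenes can be rendered into four 16-bit channels (bright-field, green=live,
red=dead, blue=droplet outline) so that the full segmentation and
quantification pipeline can be exercised against a known truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "Droplet",
    "Cell",
    "Aggregate",
    "GroundTruthScene",
    "ChannelStack",
    "sample_truncated_power_law",
    "truncated_power_law_cdf",
    "sample_scene",
    "render_channels",
    "write_ground_truth",
    "read_ground_truth",
]

#: projected footprint of a single cell, µm² (rod-shaped bacterium, 2D projection)
CELL_FOOTPRINT_UM2 = 1.0


class SceneValidationError(ValueError):
    """A SceneSpec violates one of its invariants."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic drying-surface scene.

    Lengths are in µm, areas in µm², intensities on the 16-bit camera scale.
    ``aggregate_area_params`` optionally switches generation to
    aggregate-first mode: aggregate areas are drawn from a log10-normal
    distribution ``(mean_log10, sd_log10)`` and droplet areas derived through
    the inverse coupling, which is how scenes mimicking solitary-cell vs.
    aggregated experiments are produced.  The default (None) is
    droplet-first: droplet areas are drawn from the truncated power law.
    """

    field_width_um: float = 332.8
    field_height_um: float = 332.8
    pixel_size_um: float = 0.1625
    n_aggregates: int = 25
    aggregate_area_params: Optional[tuple[float, float]] = None
    droplet_exponent_gamma: float = -1.2
    droplet_area_min_um2: float = 10.0
    droplet_area_max_um2: float = 1.0e4
    coupling_coeff: float = 0.2
    coupling_noise_sd: float = 0.3
    survival_s_min: float = 0.02
    survival_s_max: float = 0.8
    survival_log_midpoint: float = 3.0
    survival_slope: float = 3.5
    background_level: float = 500.0
    signal_level: float = 5000.0
    noise_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.droplet_exponent_gamma < 0:
            raise SceneValidationError(
                f"droplet_exponent_gamma must be < 0, got {self.droplet_exponent_gamma}"
            )
        if not 0 < self.droplet_area_min_um2 < self.droplet_area_max_um2:
            raise SceneValidationError(
                "need 0 < droplet_area_min_um2 < droplet_area_max_um2, got "
                f"[{self.droplet_area_min_um2}, {self.droplet_area_max_um2}]"
            )
        if not 0 <= self.survival_s_min <= self.survival_s_max <= 1:
            raise SceneValidationError(
                "need 0 <= survival_s_min <= survival_s_max <= 1, got "
                f"({self.survival_s_min}, {self.survival_s_max})"
            )
        if self.survival_slope < 0:
            raise SceneValidationError(
                f"survival_slope must be >= 0, got {self.survival_slope}"
            )
        if self.pixel_size_um <= 0:
            raise SceneValidationError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )
        for name in ("field_width_um", "field_height_um"):
            v = getattr(self, name)
            n = v / self.pixel_size_um
            if v <= 0 or abs(n - round(n)) > 1e-6:
                raise SceneValidationError(
                    f"{name}={v} must be a positive multiple of pixel_size_um="
                    f"{self.pixel_size_um}"
                )
        if self.n_aggregates < 0:
            raise SceneValidationError(
                f"n_aggregates must be >= 0, got {self.n_aggregates}"
            )
        if self.coupling_coeff <= 0 or self.coupling_coeff > 1:
            raise SceneValidationError(
                f"coupling_coeff must be in (0, 1], got {self.coupling_coeff}"
            )

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) of the rendered rasters."""
        return (
            int(round(self.field_height_um / self.pixel_size_um)),
            int(round(self.field_width_um / self.pixel_size_um)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("aggregate_area_params") is not None:
            d["aggregate_area_params"] = tuple(d["aggregate_area_params"])
        return cls(**d)


@dataclass(frozen=True)
class Droplet:
    id: int
    x_um: float
    y_um: float
    area_um2: float

    @property
    def radius_um(self) -> float:
        return math.sqrt(self.area_um2 / math.pi)


@dataclass(frozen=True)
class Cell:
    id: int
    x_um: float
    y_um: float
    footprint_um2: float
    viability: str  # "live" | "dead"
    host_droplet_id: Optional[int]
    aggregate_id: int


@dataclass(frozen=True)
class Aggregate:
    id: int
    cell_ids: tuple[int, ...]
    area_um2: float


@dataclass(frozen=True)
class GroundTruthScene:
    droplets: tuple[Droplet, ...]
    cells: tuple[Cell, ...]
    aggregates: tuple[Aggregate, ...]
    spec: SceneSpec

    def __post_init__(self) -> None:
        ids = {d.id for d in self.droplets}
        for c in self.cells:
            if c.host_droplet_id is not None and c.host_droplet_id not in ids:
                raise SceneValidationError(
                    f"cell {c.id} references missing droplet {c.host_droplet_id}"
                )
            if c.viability not in ("live", "dead"):
                raise SceneValidationError(
                    f"cell {c.id} has viability {c.viability!r}"
                )

    def droplet_areas(self) -> np.ndarray:
        return np.array([d.area_um2 for d in self.droplets], dtype=float)


@dataclass
class ChannelStack:
    """Four registered 2D rasters sharing one grid, 16-bit dynamic range."""

    bf: np.ndarray
    green: np.ndarray
    red: np.ndarray
    blue: np.ndarray
    pixel_size_um: float
    field_id: str = "0"

    def __post_init__(self) -> None:
        shapes = {self.bf.shape, self.green.shape, self.red.shape, self.blue.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        for name in ("bf", "green", "red", "blue"):
            a = getattr(self, name)
            if a.min() < 0 or a.max() > 65535:
                raise ValueError(f"channel {name} outside [0, 65535]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bf.shape


# ---------------------------------------------------------------------------
# truncated power law
# ---------------------------------------------------------------------------

def truncated_power_law_cdf(
    a: np.ndarray, gamma: float, amin: float, amax: float
) -> np.ndarray:
    """CDF of the density p(A) ∝ A**gamma truncated to [amin, amax]."""
    a = np.asarray(a, dtype=float)
    g1 = gamma + 1.0
    if abs(g1) < 1e-12:
        out = np.log(a / amin) / np.log(amax / amin)
    else:
        out = (a**g1 - amin**g1) / (amax**g1 - amin**g1)
    return np.clip(out, 0.0, 1.0)


def sample_truncated_power_law(
    n: int, gamma: float, amin: float, amax: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF sampling of the truncated continuous power law."""
    if not 0 < amin < amax:
        raise ValueError(f"need 0 < amin < amax, got [{amin}, {amax}]")
    u = rng.random(n)
    g1 = gamma + 1.0
    if abs(g1) < 1e-12:
        return amin * (amax / amin) ** u
    return (amin**g1 + u * (amax**g1 - amin**g1)) ** (1.0 / g1)


def survival_probability(area_um2: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Logistic live probability as a function of host droplet area."""
    z = spec.survival_slope * (np.log10(area_um2) - spec.survival_log_midpoint)
    return spec.survival_s_min + (spec.survival_s_max - spec.survival_s_min) / (
        1.0 + np.exp(-z)
    )


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------

def _place_disks(
    radii: np.ndarray,
    width: float,
    height: float,
    margin: float,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Greedy random sequential placement of non-overlapping disks.

    Disks are placed largest-first; a disk must lie fully inside the field
    (with ``margin``) and not overlap previously placed disks.
    """
    order = np.argsort(-radii)
    centers = np.full((len(radii), 2), np.nan)
    placed: list[tuple[float, float, float]] = []
    for idx in order:
        r = radii[idx]
        lo_x, hi_x = r + margin, width - r - margin
        lo_y, hi_y = r + margin, height - r - margin
        if hi_x <= lo_x or hi_y <= lo_y:
            raise ValueError(
                f"droplet of radius {r:.1f} µm does not fit a "
                f"{width:.0f}×{height:.0f} µm field"
            )
        for _ in range(max_tries):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            # 2 µm clearance keeps neighbouring droplets separable after blur
            if all((x - px) ** 2 + (y - py) ** 2 > (r + pr + 2.0) ** 2
                   for px, py, pr in placed):
                placed.append((x, y, r))
                centers[idx] = (x, y)
                break
        else:
            raise ValueError(
                f"could not place disk of radius {r:.1f} µm after {max_tries} tries; "
                "reduce n_aggregates or droplet_area_max_um2"
            )
    return centers


def _sunflower(n: int, spacing: float) -> np.ndarray:
    """n points in a golden-angle (sunflower) disk layout, ~uniform density."""
    k = np.arange(n, dtype=float)
    r = spacing * np.sqrt(k)
    th = k * (math.pi * (3.0 - math.sqrt(5.0)))
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def sample_scene(spec: SceneSpec) -> GroundTruthScene:
    """Draw a ground-truth scene from the generative model.

    Droplet areas are i.i.d. truncated-power-law draws (or derived from
    aggregate areas when ``aggregate_area_params`` is given); the cell-covered
    area inside each droplet is ``coupling_coeff`` × droplet area under
    multiplicative log-normal noise, clipped to the droplet; each cell is
    independently live with the logistic probability of its host droplet
    area.  Deterministic for a given spec (all randomness flows from
    ``spec.seed``).
    """
    rng = np.random.default_rng([spec.seed, 0xD20])
    n = spec.n_aggregates
    if n == 0:
        return GroundTruthScene((), (), (), spec)

    if spec.aggregate_area_params is None:
        droplet_areas = sample_truncated_power_law(
            n,
            spec.droplet_exponent_gamma,
            spec.droplet_area_min_um2,
            spec.droplet_area_max_um2,
            rng,
        )
        noise = np.exp(rng.normal(0.0, spec.coupling_noise_sd, n))
        target_cell_area = np.minimum(
            spec.coupling_coeff * droplet_areas * noise, droplet_areas
        )
    else:
        mu, sd = spec.aggregate_area_params
        target_cell_area = 10.0 ** rng.normal(mu, sd, n)
        noise = np.exp(rng.normal(0.0, spec.coupling_noise_sd, n))
        droplet_areas = np.clip(
            target_cell_area / spec.coupling_coeff * noise,
            spec.droplet_area_min_um2,
            spec.droplet_area_max_um2,
        )
        target_cell_area = np.minimum(target_cell_area, droplet_areas)

    radii = np.sqrt(droplet_areas / math.pi)
    centers = _place_disks(
        radii,
        spec.field_width_um,
        spec.field_height_um,
        margin=2.0 * spec.pixel_size_um,
        rng=rng,
    )

    p_live = survival_probability(droplet_areas, spec)

    droplets: list[Droplet] = []
    cells: list[Cell] = []
    aggregates: list[Aggregate] = []
    cell_id = 0
    for i in range(n):
        did = i + 1
        x, y = centers[i]
        droplets.append(Droplet(did, x, y, droplet_areas[i]))
        n_cells = max(
            1,
            min(
                int(round(target_cell_area[i] / CELL_FOOTPRINT_UM2)),
                int(droplet_areas[i] / CELL_FOOTPRINT_UM2),
            ),
        )
        # single-layer packing around the aggregate centroid; spacing ≈ one
        # cell diameter keeps footprints essentially disjoint, so the union
        # of rendered cells matches the summed footprint areas
        cell_r0 = math.sqrt(CELL_FOOTPRINT_UM2 / math.pi)
        offsets = _sunflower(n_cells, 2.0 * cell_r0)
        agg_radius = float(np.hypot(offsets[:, 0], offsets[:, 1]).max()) if n_cells > 1 else 0.0
        cell_r = math.sqrt(CELL_FOOTPRINT_UM2 / math.pi)
        max_r = radii[i] - cell_r - spec.pixel_size_um
        if agg_radius > max_r > 0:
            offsets *= max_r / agg_radius
        live = rng.random(n_cells) < p_live[i]
        member_ids = []
        for j in range(n_cells):
            cell_id += 1
            member_ids.append(cell_id)
            cells.append(
                Cell(
                    id=cell_id,
                    x_um=x + offsets[j, 0],
                    y_um=y + offsets[j, 1],
                    footprint_um2=CELL_FOOTPRINT_UM2,
                    viability="live" if live[j] else "dead",
                    host_droplet_id=did,
                    aggregate_id=did,
                )
            )
        aggregates.append(
            Aggregate(did, tuple(member_ids), n_cells * CELL_FOOTPRINT_UM2)
        )

    return GroundTruthScene(tuple(droplets), tuple(cells), tuple(aggregates), spec)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _pixel_grid(shape: tuple[int, int], px: float) -> tuple[np.ndarray, np.ndarray]:
    ys = (np.arange(shape[0]) + 0.5) * px
    xs = (np.arange(shape[1]) + 0.5) * px
    return ys, xs


def _paint_disk(img: np.ndarray, x: float, y: float, r: float, px: float,
                value: np.ndarray | float) -> None:
    """Add ``value`` (scalar or radial profile callable output) on the disk."""
    h, w = img.shape
    i0 = max(0, int((y - r) / px) - 1)
    i1 = min(h, int((y + r) / px) + 2)
    j0 = max(0, int((x - r) / px) - 1)
    j1 = min(w, int((x + r) / px) + 2)
    if i0 >= i1 or j0 >= j1:
        return
    ys = (np.arange(i0, i1) + 0.5) * px
    xs = (np.arange(j0, j1) + 0.5) * px
    d2 = (ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2
    inside = d2 <= r * r
    if np.isscalar(value):
        img[i0:i1, j0:j1][inside] += value
    else:
        img[i0:i1, j0:j1][inside] += value(np.sqrt(d2[inside]))


def render_channels(scene: GroundTruthScene, spec: SceneSpec | None = None) -> ChannelStack:
    """Rasterize a scene into the four 16-bit channels.

    The blue channel shows each droplet as a bright interior whose intensity
    decays mildly toward the rim (centers brighter than periphery); a 1-px
    Gaussian blur produces the smooth falloff and the strong gradient at the
    boundary, so droplets are recoverable by both an intensity and a gradient
    threshold.  Green and red show live and dead cell footprints at
    ``signal_level`` over background.  Additive Gaussian noise with sd
    ``noise_sd`` is applied to every channel.  Deterministic given the spec
    seed.
    """
    if spec is None:
        spec = scene.spec
    shape = spec.shape_px
    px = spec.pixel_size_um

    out_of_field = []
    for d in scene.droplets:
        if not (d.radius_um <= d.x_um <= spec.field_width_um - d.radius_um
                and d.radius_um <= d.y_um <= spec.field_height_um - d.radius_um):
            out_of_field.append(f"droplet {d.id}")
    for c in scene.cells:
        if not (0 <= c.x_um <= spec.field_width_um and 0 <= c.y_um <= spec.field_height_um):
            out_of_field.append(f"cell {c.id}")
    if out_of_field:
        raise ValueError("objects outside the field: " + ", ".join(out_of_field))

    bg = spec.background_level
    blue = np.zeros(shape, dtype=float)
    green = np.zeros(shape, dtype=float)
    red = np.zeros(shape, dtype=float)
    bf = np.zeros(shape, dtype=float)

    for d in scene.droplets:
        r = d.radius_um
        # center at full signal, rim at 70% — brighter center, dimmer periphery
        profile = lambda rr, r=r: spec.signal_level * (1.0 - 0.3 * (rr / r) ** 2)
        _paint_disk(blue, d.x_um, d.y_um, r, px, profile)

    cell_r = math.sqrt(CELL_FOOTPRINT_UM2 / math.pi)
    for c in scene.cells:
        target = green if c.viability == "live" else red
        _paint_disk(target, c.x_um, c.y_um, cell_r, px, spec.signal_level)
        # cells are visible in bright field as dark footprints
        _paint_disk(bf, c.x_um, c.y_um, cell_r, px, -0.3 * bg)

    # smooth falloff at boundaries; cells get a lighter blur to stay compact
    blue = ndimage.gaussian_filter(blue, sigma=1.0)
    green = np.clip(ndimage.gaussian_filter(green, sigma=0.5), 0, None)
    red = np.clip(ndimage.gaussian_filter(red, sigma=0.5), 0, None)

    rng = np.random.default_rng([spec.seed, 0x4E0])
    chans = {}
    for name, img in (("bf", bg + bf), ("green", bg + green),
                      ("red", bg + red), ("blue", bg + blue)):
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, shape)
        chans[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return ChannelStack(
        bf=chans["bf"], green=chans["green"], red=chans["red"], blue=chans["blue"],
        pixel_size_um=px, field_id=str(spec.seed),
    )


def scene_tables(scene: GroundTruthScene, field_id: str = "0") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth droplet and aggregate record tables for a scene.

    Same schema as the measured tables from the quantification stage, so
    statistics can be computed directly on the latent truth (no rendering or
    segmentation involved).
    """
    live_per_droplet: dict[int, float] = {}
    dead_per_droplet: dict[int, float] = {}
    for c in scene.cells:
        if c.host_droplet_id is None:
            continue
        tgt = live_per_droplet if c.viability == "live" else dead_per_droplet
        tgt[c.host_droplet_id] = tgt.get(c.host_droplet_id, 0.0) + c.footprint_um2
    drop_rows = []
    for d in scene.droplets:
        la = live_per_droplet.get(d.id, 0.0)
        da = dead_per_droplet.get(d.id, 0.0)
        drop_rows.append({
            "droplet_id": d.id, "repeat": field_id, "droplet_area_um2": d.area_um2,
            "centroid_x_um": d.x_um, "centroid_y_um": d.y_um,
            "cell_area_um2": la + da, "live_area_um2": la, "dead_area_um2": da,
        })
    cell_by_id = {c.id: c for c in scene.cells}
    droplet_by_id = {d.id: d for d in scene.droplets}
    agg_rows = []
    for a in scene.aggregates:
        members = [cell_by_id[i] for i in a.cell_ids]
        la = sum(c.footprint_um2 for c in members if c.viability == "live")
        da = sum(c.footprint_um2 for c in members if c.viability == "dead")
        host = members[0].host_droplet_id if members else None
        agg_rows.append({
            "aggregate_id": a.id, "repeat": field_id, "aggregate_area_um2": a.area_um2,
            "host_droplet_id": host,
            "droplet_area_um2": droplet_by_id[host].area_um2 if host is not None else np.nan,
            "live_area_um2": la, "dead_area_um2": da,
            "survival_rate": la / (la + da) if la + da > 0 else np.nan,
        })
    drop_cols = ["droplet_id", "repeat", "droplet_area_um2", "centroid_x_um",
                 "centroid_y_um", "cell_area_um2", "live_area_um2", "dead_area_um2"]
    agg_cols = ["aggregate_id", "repeat", "aggregate_area_um2", "host_droplet_id",
                "droplet_area_um2", "live_area_um2", "dead_area_um2", "survival_rate"]
    return (pd.DataFrame(drop_rows, columns=drop_cols),
            pd.DataFrame(agg_rows, columns=agg_cols))


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------

_GT_COLUMNS = [
    "kind", "id", "x_um", "y_um", "area_um2",
    "viability", "host_droplet_id", "aggregate_id",
]


def ground_truth_frame(scene: GroundTruthScene) -> pd.DataFrame:
    rows = []
    for d in scene.droplets:
        rows.append(("droplet", d.id, d.x_um, d.y_um, d.area_um2, "", "", ""))
    for c in scene.cells:
        rows.append((
            "cell", c.id, c.x_um, c.y_um, c.footprint_um2,
            c.viability, c.host_droplet_id if c.host_droplet_id is not None else "",
            c.aggregate_id,
        ))
    return pd.DataFrame(rows, columns=_GT_COLUMNS)


def write_ground_truth(scene: GroundTruthScene, path) -> None:
    """Write a flat CSV table, one row per droplet and one per cell."""
    ground_truth_frame(scene).to_csv(path, index=False)


def read_ground_truth(path, spec: SceneSpec) -> GroundTruthScene:
    """Inverse of :func:`write_ground_truth` (the spec is supplied separately)."""
    df = pd.read_csv(path, keep_default_na=False)
    droplets = tuple(
        Droplet(int(r.id), float(r.x_um), float(r.y_um), float(r.area_um2))
        for r in df[df.kind == "droplet"].itertuples()
    )
    cells = tuple(
        Cell(
            int(r.id), float(r.x_um), float(r.y_um), float(r.area_um2),
            str(r.viability),
            int(r.host_droplet_id) if str(r.host_droplet_id) != "" else None,
            int(r.aggregate_id),
        )
        for r in df[df.kind == "cell"].itertuples()
    )
    agg_members: dict[int, list[int]] = {}
    for c in cells:
        agg_members.setdefault(c.aggregate_id, []).append(c.id)
    aggregates = tuple(
        Aggregate(aid, tuple(members), len(members) * CELL_FOOTPRINT_UM2)
        for aid, members in sorted(agg_members.items())
    )
    return GroundTruthScene(droplets, cells, aggregates, spec)
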