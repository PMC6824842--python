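"""Per-droplet and per-aggregate quantification.

Turns label images and live/dead masks into tidy record tables that mirror
the published source-data schemas: per-droplet rows carry the droplet area
and the live/dead cell-covered areas inside it; per-aggregate rows carry the
aggregate area, its host droplet, and its survival rate.  Areas are pixel
counts × pixel_size_um²; cell area is the standard proxy for cell number in
this kind of 2D-projected analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

from .segment import LabelImage

__all__ = [
    "label_aggregates",
    "assign_to_droplets",
    "build_tables",
    "DROPLET_COLUMNS",
    "AGGREGATE_COLUMNS",
]

DROPLET_COLUMNS = [
    "droplet_id", "repeat", "droplet_area_um2", "centroid_x_um", "centroid_y_um",
    "cell_area_um2", "live_area_um2", "dead_area_um2",
]
AGGREGATE_COLUMNS = [
    "aggregate_id", "repeat", "aggregate_area_um2", "host_droplet_id",
    "droplet_area_um2", "live_area_um2", "dead_area_um2", "survival_rate",
]


def label_aggregates(
    live_mask: np.ndarray, dead_mask: np.ndarray, pixel_size_um: float
) -> LabelImage:
    """8-connected components of (live ∪ dead): one label per cellular object
    (solitary cell or aggregate)."""
    if live_mask.shape != dead_mask.shape:
        raise ValueError(
            f"mask shapes differ: {live_mask.shape} vs {dead_mask.shape}"
        )
    union = live_mask.astype(bool) | dead_mask.astype(bool)
    labels = measure.label(union, connectivity=2)
    return LabelImage(labels=labels.astype(np.int32), pixel_size_um=pixel_size_um)


def assign_to_droplets(
    objects: LabelImage, droplets: LabelImage
) -> dict[int, int | None]:
    """Map each cellular object to its host droplet.

    An object is assigned to the droplet with which it shares the most
    pixels; ties break to the smaller droplet id; objects overlapping no
    droplet map to ``None`` ("dry").
    """
    obj = objects.labels
    dro = droplets.labels
    if obj.shape != dro.shape:
        raise ValueError(f"grid mismatch: {obj.shape} vs {dro.shape}")

    n_obj = int(obj.max())
    n_dro = int(dro.max())
    out: dict[int, int | None] = {i: None for i in range(1, n_obj + 1)}
    if n_obj == 0:
        return out

    sel = obj > 0
    pairs = obj[sel].astype(np.int64) * (n_dro + 1) + dro[sel].astype(np.int64)
    counts = np.bincount(pairs, minlength=(n_obj + 1) * (n_dro + 1))
    counts = counts.reshape(n_obj + 1, n_dro + 1)
    # column 0 is background (no droplet); argmax over droplets 1..n_dro,
    # ties resolved to the smaller droplet id by argmax's first-hit rule
    overlap = counts[1:, 1:]
    if n_dro > 0:
        best = overlap.argmax(axis=1)
        best_count = overlap[np.arange(n_obj), best]
        for i in range(n_obj):
            if best_count[i] > 0:
                out[i + 1] = int(best[i]) + 1
    return out


def build_tables(
    droplet_labels: LabelImage,
    object_labels: LabelImage,
    live_mask: np.ndarray,
    dead_mask: np.ndarray,
    assignment: dict[int, int | None],
    pixel_size_um: float,
    field_id: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-droplet and per-aggregate record tables.

    A droplet's live/dead areas sum the live/dead pixels of objects assigned
    to it that fall inside the droplet mask (pixels of an object protruding
    past the droplet rim are not counted toward the droplet, preserving
    cell_area ≤ droplet area).  Dry objects (host None) are retained in the
    aggregate table so population totals are conserved.
    """
    dro = droplet_labels.labels
    obj = object_labels.labels
    if dro.shape != obj.shape or dro.shape != live_mask.shape or dro.shape != dead_mask.shape:
        raise ValueError(
            "inconsistent grids: droplets %s, objects %s, live %s, dead %s"
            % (dro.shape, obj.shape, live_mask.shape, dead_mask.shape)
        )
    n_obj = int(obj.max())
    missing = [i for i in range(1, n_obj + 1) if i not in assignment]
    if missing:
        raise ValueError(f"assignment missing object ids: {missing}")

    px_area = pixel_size_um**2
    n_dro = int(dro.max())

    # map each object id to its assigned droplet id (0 = dry)
    assigned = np.zeros(n_obj + 1, dtype=np.int64)
    for oid, did in assignment.items():
        assigned[oid] = 0 if did is None else did
    # droplet id credited at each cell pixel: the object's host droplet, but
    # only where the pixel actually lies inside that droplet's mask
    host_at_pixel = assigned[obj]
    inside_host = host_at_pixel == dro
    credited = np.where(inside_host, host_at_pixel, 0)

    live = live_mask.astype(bool)
    dead = dead_mask.astype(bool)
    live_per_dro = np.bincount(credited[live], minlength=n_dro + 1)[1:]
    dead_per_dro = np.bincount(credited[dead], minlength=n_dro + 1)[1:]

    droplet_areas = np.bincount(dro.ravel(), minlength=n_dro + 1)[1:] * px_area
    props = {p.label: p for p in measure.regionprops(dro)} if n_dro else {}

    drop_rows = []
    for d in range(1, n_dro + 1):
        cy, cx = props[d].centroid
        drop_rows.append({
            "droplet_id": d,
            "repeat": field_id,
            "droplet_area_um2": droplet_areas[d - 1],
            "centroid_x_um": (cx + 0.5) * pixel_size_um,
            "centroid_y_um": (cy + 0.5) * pixel_size_um,
            "cell_area_um2": (live_per_dro[d - 1] + dead_per_dro[d - 1]) * px_area,
            "live_area_um2": live_per_dro[d - 1] * px_area,
            "dead_area_um2": dead_per_dro[d - 1] * px_area,
        })
    droplet_df = pd.DataFrame(drop_rows, columns=DROPLET_COLUMNS)

    live_per_obj = np.bincount(obj[live], minlength=n_obj + 1)[1:]
    dead_per_obj = np.bincount(obj[dead], minlength=n_obj + 1)[1:]
    agg_rows = []
    for o in range(1, n_obj + 1):
        did = assignment[o]
        la = live_per_obj[o - 1] * px_area
        da = dead_per_obj[o - 1] * px_area
        agg_rows.append({
            "aggregate_id": o,
            "repeat": field_id,
            "aggregate_area_um2": la + da,
            "host_droplet_id": did if did is not None else pd.NA,
            "droplet_area_um2": droplet_areas[did - 1] if did is not None else np.nan,
            "live_area_um2": la,
            "dead_area_um2": da,
            "survival_rate": la / (la + da) if la + da > 0 else np.nan,
        })
    aggregate_df = pd.DataFrame(agg_rows, columns=AGGREGATE_COLUMNS)
    return droplet_df, aggregate_df
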