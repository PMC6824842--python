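import numpy as np
import pytest

from microwet import scene as sc
from microwet.segment import SegmentationConfig


@pytest.fixture(scope="session")
def small_spec() -> sc.SceneSpec:
    """A fast-to-render field: 83.2 µm (512 px) across, modest droplets."""
    return sc.SceneSpec(
        field_width_um=83.2,
        field_height_um=83.2,
        n_aggregates=5,
        droplet_area_min_um2=10.0,
        droplet_area_max_um2=300.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return sc.sample_scene(small_spec)


@pytest.fixture(scope="session")
def small_stack(small_scene):
    return sc.render_channels(small_scene)


@pytest.fixture(scope="session")
def default_cfg() -> SegmentationConfig:
    return SegmentationConfig()


def match_droplets(scene: sc.GroundTruthScene, droplet_df, max_dist_factor=1.0):
    """Greedy centroid matching of detected droplets to ground truth.

    Returns (f1, per-matched-droplet |relative area error| array).
    """
    det = droplet_df[
        ["centroid_x_um", "centroid_y_um", "droplet_area_um2"]
    ].to_numpy(dtype=float)
    used: set[int] = set()
    tp = 0
    errs = []
    for d in scene.droplets:
        best, bd = None, np.inf
        for j in range(len(det)):
            if j in used:
                continue
            dist = np.hypot(det[j, 0] - d.x_um, det[j, 1] - d.y_um)
            if dist < bd:
                bd, best = dist, j
        if best is not None and bd < max_dist_factor * d.radius_um:
            used.add(best)
            tp += 1
            errs.append(abs(det[best, 2] - d.area_um2) / d.area_um2)
    fp = len(det) - tp
    fn = len(scene.droplets) - tp
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return f1, np.asarray(errs)
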