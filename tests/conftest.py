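import numpy as np
import pytest
from scipy.spatial import cKDTree

from spheroquant import SimConfig, analyze_well


@pytest.fixture(scope="session")
def default_result():
    """Fully analysed default well: 150 spheroids, log-normal diameters
    (median 250 µm), no fusion, no roughness, 7×7 jittered noisy tiles."""
    return analyze_well(SimConfig(seed=1))


@pytest.fixture
def small_cfg():
    """A small 3×3-tile well that keeps stitching tests fast."""
    return SimConfig(
        seed=11, tile_rows=3, tile_cols=3, n_spheroids=25,
        well_width_um=3000.0, well_height_um=3000.0,
    )


def match_rois_to_truth(rois, truth, max_center_frac=0.5, max_radius_frac=0.25):
    """Greedy nearest-center matching of detections to true spheroids.

    Returns (matched_pairs, false_positives) where matched_pairs is a list of
    (roi, true_object) with center distance below ``max_center_frac`` of the
    true radius and radius agreement within ``max_radius_frac``.
    """
    objs = truth.spheroids()
    if not objs:
        return [], list(rois)
    tree = cKDTree([(o.center_x_um, o.center_y_um) for o in objs])
    pairs, fps = [], []
    for r in rois:
        d, i = tree.query((r.center_x_um, r.center_y_um))
        o = objs[i]
        if d < max_center_frac * o.radius_um and \
                abs(r.radius_um - o.radius_um) / o.radius_um < max_radius_frac:
            pairs.append((r, o))
        else:
            fps.append(r)
    return pairs, fps
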