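import numpy as np
import pytest

from chiptaxis import DeviceGeometry, generate_vessel_image, quantify_image


@pytest.fixture(scope="session")
def geometry() -> DeviceGeometry:
    """Default migration-channel geometry (L = 1300 um)."""
    return DeviceGeometry()


@pytest.fixture(scope="session")
def bundle100():
    """One synthetic vascular-well field with 30/40/30 labelled cells."""
    return generate_vessel_image(
        n_luminal=30, n_extravasated=40, n_recruited=30, snr=10.0, seed=7
    )


@pytest.fixture(scope="session")
def quantified100(bundle100):
    """The full pipeline run once on the shared bundle."""
    counts, spots, lumens, well = quantify_image(
        bundle100.image, bundle100.pixel_size_um
    )
    return counts, spots, lumens, well


def match_to_truth(spots, truth_cells, tol_px=3.0):
    """Nearest-neighbour assignment of detections to truth cells.

    Returns (matched_indices, truth_labels) for detections within tol_px.
    """
    from scipy.spatial import cKDTree

    truth_xy = np.array([(x, y) for x, y, _ in truth_cells], dtype=float)
    labels = [lab for _, _, lab in truth_cells]
    det_xy = np.array([(x, y) for x, y, _ in spots.points], dtype=float)
    if det_xy.size == 0 or truth_xy.size == 0:
        return [], labels
    dist, idx = cKDTree(truth_xy).query(det_xy)
    return [(d_i, t_i) for d_i, (d, t_i) in enumerate(zip(dist, idx)) if d <= tol_px], labels
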