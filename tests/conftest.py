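import numpy as np
import pytest
from hypothesis import settings

from beanbolus import imaging, synth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def oracle_plate():
    """One rendered plate with ground truth, shared across imaging tests.

    35 particles (20 cotyledon, 15 seed coat) of at least 2 mm^2 with
    well-separated class colours, plus 3 specular reflections.
    """
    spec = synth.PlateSpec(
        n_white=20, n_black=15, n_reflections=3, min_area_mm2=2.0, seed=4
    )
    image, truth = synth.render_plate(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def oracle_calibration(oracle_plate):
    _, _, truth = oracle_plate
    return imaging.calibrate(truth.marker_length_mm, truth.marker_length_px)


@pytest.fixture(scope="session")
def oracle_segmentation(oracle_plate, oracle_calibration):
    _, image, _ = oracle_plate
    return imaging.segment_image(image, oracle_calibration)


def match_by_centroid(truth_df, recovered_df):
    """Pair ground-truth and recovered particles by nearest centroid."""
    t = truth_df[["centroid_y_px", "centroid_x_px"]].to_numpy()
    r = recovered_df[["centroid_y_px", "centroid_x_px"]].to_numpy()
    d = np.linalg.norm(t[:, None, :] - r[None, :, :], axis=-1)
    idx = d.argmin(axis=1)
    assert len(set(idx)) == len(idx), "centroid matching is not one-to-one"
    return truth_df.reset_index(drop=True), recovered_df.iloc[idx].reset_index(drop=True)
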