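import numpy as np
import pytest

from cochleaquant.imaging import RowGeometry, classify_cells, segment_nuclei
from cochleaquant.synthgen import gen_cochlea_stack, study_params


@pytest.fixture(scope="session")
def wt_noiseless():
    """Small noiseless WT stack: truth is exact by construction."""
    params = study_params("WT", seed=11, n_cells_per_row=10, noise_sd=0.0,
                          offset_jitter_um=0.0)
    stack, truth, polyline = gen_cochlea_stack(params)
    return params, stack, truth, polyline


@pytest.fixture(scope="session")
def wt_noiseless_detections(wt_noiseless):
    params, stack, truth, polyline = wt_noiseless
    segments = segment_nuclei(stack)
    detections = classify_cells(
        segments, stack,
        RowGeometry(polyline=polyline, row_spacing_um=params.row_spacing_um))
    return detections


@pytest.fixture(scope="session")
def treated_noisy():
    """KO_treated stack with noise, plus a WT control for GFP scoring."""
    params = study_params("KO_treated", seed=21, n_cells_per_row=10, noise_sd=3.0)
    stack, truth, polyline = gen_cochlea_stack(params)
    ctrl_params = study_params("WT", seed=22, n_cells_per_row=10, noise_sd=3.0)
    ctrl_stack, ctrl_truth, ctrl_poly = gen_cochlea_stack(ctrl_params)
    return (params, stack, truth, polyline), (ctrl_params, ctrl_stack, ctrl_poly)


def match_to_truth(detection, truth_alive):
    """Index of the truth cell whose nucleus is nearest a detection."""
    pos = truth_alive[["nx", "ny", "nz"]].to_numpy()
    return int(np.argmin(np.linalg.norm(pos - detection.centroid_um, axis=1)))
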