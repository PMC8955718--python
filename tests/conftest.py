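import numpy as np
import pytest

from speedkin import analyze_run
from speedkin.core import load_anthropometric_table, load_route_map
from speedkin.synthetic import SynthConfig, generate_run


@pytest.fixture(scope="session")
def table():
    return load_anthropometric_table()


@pytest.fixture(scope="session")
def route_map():
    return load_route_map()


@pytest.fixture(scope="session")
def run_noisy():
    """Default study conditions: sigma=2 px, 5% dropout, 20% match outliers."""
    return generate_run(SynthConfig(), seed=1)


@pytest.fixture(scope="session")
def res_noisy(run_noisy):
    return analyze_run(run_noisy.pose_frames, run_noisy.matches,
                       run_noisy.detections)


@pytest.fixture(scope="session")
def run_clean():
    """Noise-free run: every stage should recover ground truth exactly."""
    cfg = SynthConfig(sigma_px=0.0, dropout=0.0, outlier_frac=0.0)
    return generate_run(cfg, seed=3)


@pytest.fixture(scope="session")
def res_clean(run_clean):
    return analyze_run(run_clean.pose_frames, run_clean.matches,
                       run_clean.detections)


@pytest.fixture(scope="session")
def run_constant():
    """Constant 1.5 m/s ascent over 7 s (covers holds 1-12)."""
    cfg = SynthConfig(duration_s=7.0, speed_modulation=0.0)
    return generate_run(cfg, seed=3)


@pytest.fixture(scope="session")
def res_constant(run_constant):
    return analyze_run(run_constant.pose_frames, run_constant.matches,
                       run_constant.detections)


@pytest.fixture(scope="session")
def run_static():
    """World-static climber under an alternating (constant-scale) camera pan."""
    n = int(4.0 * 24)
    alpha = np.empty(n)
    alpha[::2], alpha[1::2] = 0.15, -0.15
    cfg = SynthConfig(mode="static", duration_s=4.0, start_y_m=7.0,
                      sigma_px=0.0, dropout=0.0, outlier_frac=0.0,
                      prescribed_alpha=alpha)
    return generate_run(cfg, seed=2)


@pytest.fixture(scope="session")
def res_static(run_static):
    return analyze_run(run_static.pose_frames, run_static.matches,
                       run_static.detections)
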