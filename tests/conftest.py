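import numpy as np
import pytest

from waterflea import CohortConfig, Detection, Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(positions, track_id=0, start_frame=0, area=100.0, perimeter=40.0,
               major=12.0, minor=6.0, circularity=0.8):
    """Build a Track from an (n, 2) array of pixel positions."""
    tr = Track(track_id=track_id)
    for i, (x, y) in enumerate(np.asarray(positions, dtype=float)):
        tr.append(Detection(frame=start_frame + i, x=float(x), y=float(y), area=area,
                            perimeter=perimeter, major=major, minor=minor, circularity=circularity))
    return tr


@pytest.fixture
def straight_track():
    """Constant-velocity straight track: (3, 4) px/frame for 12 frames."""
    pos = np.column_stack([3.0 * np.arange(12), 4.0 * np.arange(12)])
    return make_track(pos + 50.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small rendered cohort shared by segmentation/linking tests."""
    import waterflea as wf

    cfg = CohortConfig(n_animals=3, duration_s=8.0, arena_w_px=320, arena_h_px=240,
                       seed=7, min_separation_px=40.0, noise_sd=4.0, n_debris=3)
    truth = wf.simulate_trajectories(cfg, age_days=10.0)
    video = wf.render_video(truth)
    return cfg, truth, video
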