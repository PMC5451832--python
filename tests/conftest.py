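import numpy as np
import pytest

from rodtrack import fixtures, tracking
from rodtrack.config import DrlseParams, SegConfig, TrackConfig


@pytest.fixture(scope="session")
def default_params():
    return DrlseParams()


@pytest.fixture(scope="session")
def seg_cfg():
    return SegConfig()


@pytest.fixture(scope="session")
def track_cfg():
    return TrackConfig()


@pytest.fixture(scope="session")
def bench_scene():
    """The 20-frame low-crowding benchmark scene (seed 42)."""
    return fixtures.simulate_colony(20, seed=42)


@pytest.fixture(scope="session")
def bench_stack(bench_scene):
    noise = 0.03 * (fixtures.BACKGROUND - fixtures.INTERIOR)
    return fixtures.render_stack(bench_scene, noise_sd=noise)


@pytest.fixture(scope="session")
def bench_run(bench_scene, bench_stack, seg_cfg, track_cfg, default_params):
    """Full pipeline output on the benchmark; shared across tests."""
    images, _ = bench_stack
    per_frame, state, lineage = tracking.track_stack(
        images, seg_cfg, track_cfg, default_params,
        calibration=bench_scene.calibration,
    )
    return per_frame, state, lineage


def single_capsule_scene(
    length=4.0, width=1.0, orientation=0.6, center=(19.2, 19.2), cell_id=1
):
    """A one-frame scene holding a single capsule at a fixed pose."""
    cell = fixtures.CapsuleCell(
        id=cell_id,
        center=np.array(center, dtype=float),
        orientation=orientation,
        length=length,
        width=width,
    )
    return fixtures.SyntheticScene(
        frames=[[cell]],
        lineage={},
        calibration=0.15,
        frame_interval=69.0,
        image_size=(256, 256),
        seed=0,
        births={cell_id: 0},
    )


@pytest.fixture
def capsule_scene():
    return single_capsule_scene()


def make_division_scene(seed):
    """Single-cell scene guaranteed to divide once within 18 frames."""
    return fixtures.simulate_colony(
        18, seed=seed, growth_rate=0.06, n_initial=1, motion_sd=0.01
    )
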