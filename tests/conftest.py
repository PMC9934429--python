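import numpy as np
import pytest

from helixdimer.synthetic import (
    DimerPose,
    HelixSpec,
    TrajectoryScript,
    assemble_dimer,
    build_ideal_helix,
    generate_trajectory,
)

#: Pose in the pivot-open regime where helix rotations occur and the
#: cross-product rotation reference is far from its degeneracy threshold.
PIVOT_POSE = dict(separation=1.0, crossing=-50.0)


@pytest.fixture(scope="session")
def helix():
    """Ideal 28-residue coarse-grained backbone helix along +z."""
    return build_ideal_helix(HelixSpec())


@pytest.fixture
def dimer_frame(helix):
    """Noise-free left-handed dimer frame at the inactive-like pose."""
    return assemble_dimer(helix, helix, DimerPose(separation=1.0, crossing=-25.0))


def spin_ramp(helix_label: str, spin: float, *, crossing: float = -50.0,
              n_frames: int = 21, noise_sd: float = 0.0,
              bend_amplitude: float = 0.0, seed: int = 0):
    """Scripted trajectory spinning one helix by ``spin`` degrees."""
    start = DimerPose(separation=1.0, crossing=crossing)
    end = DimerPose(separation=1.0, crossing=crossing, **{helix_label: float(spin)})
    script = TrajectoryScript(
        waypoints=((0.0, start), (10.0, end)),
        noise_sd=noise_sd,
        bend_amplitude=bend_amplitude,
        seed=seed,
    )
    return generate_trajectory(script, dt=10.0 / (n_frames - 1))


def rigid_transform(frame, R: np.ndarray, t: np.ndarray):
    """Apply a rigid rotation + translation to every bead of a frame."""
    from helixdimer.core import BeadFrame

    return BeadFrame(
        time=frame.time,
        chains={
            cid: (resids.copy(), (R @ xyz.T).T + t)
            for cid, (resids, xyz) in frame.chains.items()
        },
    )
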