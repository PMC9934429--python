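"""Scripted synthetic helix-dimer trajectories with known ground truth.

This module builds ideal coarse-grained backbone helices (one bead per
residue) and assembles them into dimers whose crossing angle, lateral
separation, per-helix spin and axial slide are set exactly by construction.
Scripted trajectories interpolate those pose parameters between waypoints
and optionally add smooth axis bending and Gaussian positional noise, which
lets every downstream descriptor be validated by parameter recovery: the
analysis must read back what the script wrote.

It is purely kinematic: no force field, no lipids, no dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BeadFrame, FIRST_RESIDUE, rotation_about_axis


@dataclass(frozen=True)
class HelixSpec:
    """Ideal helix parameters (canonical alpha-helix backbone by default).

    Attributes
    ----------
    n_res : int
        Number of residues (one backbone bead each).
    rise : float
        Axial translation per residue in nm (1.5 A for an alpha helix).
    twist : float
        Azimuthal rotation per residue in degrees (100 deg for an
        alpha helix: 3.6 residues per turn).
    radius : float
        Distance of the backbone bead from the helical axis in nm.
    """

    n_res: int = 28
    rise: float = 0.15
    twist: float = 100.0
    radius: float = 0.23

    def __post_init__(self):
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not (0.0 < self.twist < 360.0):
            raise ValueError("twist must be in (0, 360) degrees")


@dataclass(frozen=True)
class DimerPose:
    """Target geometry of an assembled dimer.

    ``crossing`` is the signed crossing angle in degrees (negative =
    left-handed packing), realised as symmetric tilts of +/- crossing/2 so
    that neither helix is privileged. ``spinA``/``spinB`` rotate each helix
    about its own axis; ``slide`` shifts helix B axially relative to A.
    """

    separation: float = 1.0
    crossing: float = 0.0
    spinA: float = 0.0
    spinB: float = 0.0
    slide: float = 0.0

    def __post_init__(self):
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if abs(self.crossing) >= 90.0:
            raise ValueError("|crossing| must be < 90 degrees")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.separation, self.crossing, self.spinA, self.spinB, self.slide]
        )

    @staticmethod
    def from_array(a) -> "DimerPose":
        return DimerPose(*(float(x) for x in a))


@dataclass(frozen=True)
class TrajectoryScript:
    """Ordered pose waypoints plus noise/bending settings.

    Pose parameters are interpolated linearly between waypoints; angles are
    interpolated without wrapping, so scripts are authored unwrapped (a spin
    ramp 0 -> 300 means five sixths of a counterclockwise turn, not -60).
    """

    waypoints: tuple[tuple[float, DimerPose], ...]
    noise_sd: float = 0.0
    bend_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "waypoints", tuple(self.waypoints))
        if len(self.waypoints) == 0:
            raise ValueError("script needs at least one waypoint")
        times = [t for t, _ in self.waypoints]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("waypoint times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def pose_at(self, t: float) -> DimerPose:
        """Linear interpolation of the pose at time ``t`` (clamped ends)."""
        times = np.array([w[0] for w in self.waypoints])
        poses = np.stack([w[1].as_array() for w in self.waypoints])
        vals = [np.interp(t, times, poses[:, k]) for k in range(poses.shape[1])]
        return DimerPose.from_array(vals)


def build_ideal_helix(spec: HelixSpec) -> np.ndarray:
    """Backbone bead coordinates (n_res, 3) of an ideal helix along +z.

    Bead i sits at axial position i*rise, azimuth i*twist and distance
    ``radius`` from the axis; beads are ordered N -> C and the helix is
    axially centred on the origin.
    """
    i = np.arange(spec.n_res)
    phi = np.radians(i * spec.twist)
    xyz = np.column_stack(
        [spec.radius * np.cos(phi), spec.radius * np.sin(phi), i * spec.rise]
    )
    xyz[:, 2] -= xyz[:, 2].mean()
    return xyz


def _bend(coords: np.ndarray, amplitude: float) -> np.ndarray:
    """Bow the helix with a single sinusoidal axis mode (zero at the ends).

    Displaces beads along local +x so the segmented axis vectors k_j differ
    measurably from the straight global axis, mimicking the bending and
    wiggling of real transmembrane helices.
    """
    if amplitude == 0.0:
        return coords
    n = len(coords)
    s = np.sin(np.pi * np.arange(n) / max(n - 1, 1))
    out = coords.copy()
    out[:, 0] += amplitude * s
    return out


def assemble_dimer(
    helixA: np.ndarray,
    helixB: np.ndarray,
    pose: DimerPose,
    *,
    time: float = 0.0,
    chainA: str = "A",
    chainB: str = "B",
    first_residue: int = FIRST_RESIDUE,
) -> BeadFrame:
    """Place two helices built along +z into the scripted dimer pose.

    Helix A is centred at x = -separation/2, helix B at +separation/2, so
    the inter-axis direction is +x. Spins are applied about each helix's own
    axis before tilting; crossing is realised by tilting A by +crossing/2
    and B by -crossing/2 about the inter-axis direction, which yields a
    measured signed crossing angle equal to ``pose.crossing`` under the
    left-handed-negative sign convention.
    """
    RzA = rotation_about_axis([0, 0, 1], pose.spinA)
    RzB = rotation_about_axis([0, 0, 1], pose.spinB)
    RtA = rotation_about_axis([1, 0, 0], +pose.crossing / 2.0)
    RtB = rotation_about_axis([1, 0, 0], -pose.crossing / 2.0)

    A = (RtA @ RzA @ helixA.T).T + np.array([-pose.separation / 2.0, 0.0, 0.0])
    B = (RtB @ RzB @ helixB.T).T + np.array(
        [+pose.separation / 2.0, 0.0, pose.slide]
    )

    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    if d.min() < 0.1:
        warnings.warn(
            f"beads overlap: min inter-helix distance {d.min():.3f} nm < 0.1 nm",
            stacklevel=2,
        )

    residsA = np.arange(first_residue, first_residue + len(A))
    residsB = np.arange(first_residue, first_residue + len(B))
    return BeadFrame(time=time, chains={chainA: (residsA, A), chainB: (residsB, B)})


def generate_trajectory(
    script: TrajectoryScript,
    dt: float,
    spec: HelixSpec | None = None,
) -> list[BeadFrame]:
    """Frames sampled every ``dt`` time units over the script's time span.

    Noise and bending are applied after posing; identical seeds give
    bit-identical output. The final waypoint time is always included.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    spec = spec or HelixSpec()
    rng = np.random.default_rng(script.seed)

    t0 = script.waypoints[0][0]
    t1 = script.waypoints[-1][0]
    times = np.arange(t0, t1 + dt / 2.0, dt) if t1 > t0 else np.array([t0])

    base = build_ideal_helix(spec)
    frames = []
    for t in times:
        pose = script.pose_at(float(t))
        hA = _bend(base, script.bend_amplitude)
        hB = _bend(base, script.bend_amplitude)
        frame = assemble_dimer(hA, hB, pose, time=float(t))
        if script.noise_sd > 0:
            for cid in frame.chain_ids:
                resids, xyz = frame.chains[cid]
                frame.chains[cid] = (
                    resids,
                    xyz + rng.normal(0.0, script.noise_sd, size=xyz.shape),
                )
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# Structure file writers (multi-model PDB in Angstrom, GRO in nm)

_SEQ3 = "ALA"  # placeholder residue name; the pipeline only uses bead positions


def write_pdb(frames: list[BeadFrame], path, *, bead_name: str = "BB", remarks=()):
    """Write frames as a multi-model PDB (coordinates converted nm -> A)."""
    lines = []
    for rem in remarks:
        lines.append(f"REMARK   1 {rem}")
    for m, fr in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for cid in fr.chain_ids:
            resids, xyz = fr.chains[cid]
            for resid, (x, y, z) in zip(resids, xyz * 10.0):
                lines.append(
                    f"ATOM  {serial:5d} {bead_name:^4s} {_SEQ3:>3s} {cid}{resid:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                )
                serial += 1
            lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_gro(frames: list[BeadFrame], path, *, bead_name: str = "BB", box=10.0):
    """Write frames as concatenated GRO blocks (nm; chains A then B).

    GRO has no chain field; chains are recovered on read from the residue
    number reset between the two consecutive 765-792 runs.
    """
    lines = []
    for fr in frames:
        lines.append(f"helix dimer frame t= {fr.time:.6f}")
        lines.append(f"{fr.n_beads():5d}")
        atom = 1
        for cid in fr.chain_ids:
            resids, xyz = fr.chains[cid]
            for resid, (x, y, z) in zip(resids, xyz):
                lines.append(
                    f"{int(resid) % 100000:5d}{_SEQ3:<5s}{bead_name:>5s}"
                    f"{atom % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
                )
                atom += 1
        lines.append(f"{box:10.5f}{box:10.5f}{box:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
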