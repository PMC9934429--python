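"""Per-residue helix rotation angles and the per-helix time series.

Each residue's rotation angle theta is measured in the plane perpendicular
to the local segment axis k_j of the four-residue group the residue belongs
to (residues 25-28 share the last segment axis k_6, since no k_7 exists).
The angle runs from the purified rotation reference h_perp (the frame's
reference vector h_ref with its component along k_j projected out) to the
projection of the residue bead onto that plane, and is positive for
counterclockwise rotation viewed from the C-terminal side (looking along
-k_j).

Helix-level rotation Delta-theta is the arithmetic mean over the 25
transmembrane-core residues of the per-residue changes relative to the
first frame. Because real rotations can exceed a full turn, per-residue
angles are unwrapped along time (successive differences mapped to
(-180, 180] and cumulatively summed) before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeadFrame, N_RES_TMD, as_unit, wrap_degrees
from .geometry import reference_vector, segment_axes

#: Beads whose in-plane projection is shorter than this (nm) have an
#: undefined rotation angle and are excluded from the helix average.
MIN_PROJECTION_NM = 1e-6

#: More undefined residues than this marks the frame unreliable.
MAX_UNDEFINED = 5


@dataclass
class RotationSeries:
    """Unwrapped rotation time series for both helices.

    ``dtheta_A``/``dtheta_B`` are (n_frames,) arrays in degrees, zero at
    frame 0; ``per_residue`` maps chain id -> (n_frames, n_res) unwrapped
    per-residue traces; ``times`` carries the frame time stamps.
    """

    times: np.ndarray
    dtheta_A: np.ndarray
    dtheta_B: np.ndarray
    per_residue: dict[str, np.ndarray]
    unreliable: np.ndarray  # bool per frame


def _group_index(i: int, n_groups: int) -> int:
    """Segment axis index j (0-based) for 1-based residue index ``i``.

    Residues 1..24 use their own group's axis; the trailing residues
    (25..28) reuse the last direction vector since none follows them.
    """
    return min((i - 1) // 4, n_groups - 2)


def residue_angle(
    bead: np.ndarray,
    group_center: np.ndarray,
    k: np.ndarray,
    h_ref: np.ndarray,
) -> float:
    """Signed rotation angle (degrees) of one bead about its segment axis.

    The axis point is the perpendicular foot of the bead on the line
    through ``group_center`` along ``k``; the angle is measured from the
    purified reference h_perp = normalize(h_ref - (h_ref.k)k) to the bead's
    in-plane offset, positive counterclockwise viewed from the C-terminal
    side. Raises if the bead sits on the axis (angle undefined).
    """
    k = as_unit(k)
    h_perp = h_ref - float(h_ref @ k) * k
    nh = np.linalg.norm(h_perp)
    if nh < 1e-9:
        raise ValueError("reference vector is parallel to the segment axis")
    h_perp /= nh
    rel = np.asarray(bead, dtype=float) - np.asarray(group_center, dtype=float)
    p = rel - float(rel @ k) * k
    if np.linalg.norm(p) < MIN_PROJECTION_NM:
        raise ValueError("bead lies on the segment axis; rotation angle undefined")
    return float(np.degrees(np.arctan2(float(np.cross(h_perp, p) @ k), float(h_perp @ p))))


def frame_angles(
    frame: BeadFrame,
    chain: str,
    partner: str,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Per-residue rotation angles (degrees) for one helix in one frame.

    Returns an array over all residues of the chain; entries are NaN where
    the angle is undefined (bead on the axis).
    """
    beads = frame.coords(chain)
    centers, ks = segment_axes(beads, strict=strict)
    h_ref = reference_vector(frame, chain, partner)
    out = np.empty(len(beads))
    for idx in range(len(beads)):
        j = _group_index(idx + 1, len(centers))
        try:
            out[idx] = residue_angle(beads[idx], centers[j], ks[j], h_ref)
        except ValueError:
            out[idx] = np.nan
    return out


def frame_rotation(
    frame: BeadFrame,
    reference: BeadFrame,
    chainA: str = "A",
    chainB: str = "B",
    *,
    n_average: int = N_RES_TMD,
) -> tuple[float, float]:
    """Mean per-residue rotation change of each helix relative to a
    reference frame, wrapped to (-180, 180] before averaging.

    Averages over the first ``n_average`` residues (default: the 25
    transmembrane-core residues). Frames where more than 5 residues have
    undefined angles raise.
    """
    out = []
    for chain, partner in ((chainA, chainB), (chainB, chainA)):
        th = frame_angles(frame, chain, partner)[:n_average]
        th0 = frame_angles(reference, chain, partner)[:n_average]
        d = wrap_degrees(th - th0)
        bad = np.isnan(d).sum()
        if bad > MAX_UNDEFINED:
            raise ValueError(
                f"{bad} residues with undefined rotation angle on chain {chain}; "
                "frame unreliable"
            )
        out.append(float(np.nanmean(d)))
    return out[0], out[1]


def rotation_timeseries(
    frames: list[BeadFrame],
    chainA: str = "A",
    chainB: str = "B",
    *,
    n_average: int = N_RES_TMD,
    strict: bool = True,
) -> RotationSeries:
    """Unwrapped per-helix rotation series over a trajectory.

    Per-residue angles are unwrapped frame-to-frame (successive differences
    mapped to (-180, 180], cumulatively summed) and then averaged over the
    transmembrane-core residues of each helix; frame 0 defines zero. This
    keeps multi-turn rotations (e.g. a scripted 0 -> 300 deg ramp) on the
    unwrapped scale instead of aliasing them to -60 deg.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for a rotation time series")
    times = np.array([f.time for f in frames])
    per_res: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    unreliable = np.zeros(len(frames), dtype=bool)
    for chain, partner in ((chainA, chainB), (chainB, chainA)):
        raw = np.stack(
            [frame_angles(f, chain, partner, strict=strict) for f in frames]
        )[:, :n_average]
        d = wrap_degrees(raw[1:] - raw[:-1])
        unwrapped = np.vstack([np.zeros(raw.shape[1]), np.nancumsum(d, axis=0)])
        unreliable |= np.isnan(raw).sum(axis=1) > MAX_UNDEFINED
        per_res[chain] = unwrapped
        means[chain] = np.nanmean(unwrapped, axis=1)
    return RotationSeries(
        times=times,
        dtheta_A=means[chainA],
        dtheta_B=means[chainB],
        per_residue=per_res,
        unreliable=unreliable,
    )
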