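"""Per-frame helix axis models and inter-helix descriptors.

Conventions
-----------
* Helix axes are unit vectors pointing N -> C, estimated as the direction
  from the mean of the four N-terminal backbone beads to the mean of the
  four C-terminal beads.
* The signed crossing angle Omega is the acute angle between the two axes
  (|Omega| < 90 deg); its sign encodes packing handedness, negative for a
  left-handed overlay and positive for a right-handed one. Operationally,
  with c the inter-axis direction from helix A to helix B,
  sign(Omega) = -sign(det[h1, h2, c]); the sign is calibrated so that a
  geometrically constructed left-handed supercoil comes out negative.
* Lateral separation L defaults to the centroid-centroid distance of the
  two backbone selections; a minimum bead-pair mode is available.
* delta_d = d(N-terminal end centers) - d(C-terminal end centers): positive
  when the dimer is opened at the N-termini (scissoring).

To tolerate helix bending, each 28-residue chain is additionally split into
seven groups of four consecutive residues; the six unit vectors between
successive group centers (k_1 ... k_6, N -> C) serve as local axes for the
per-residue rotation-angle analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeadFrame, as_unit

#: Below this crossing-angle magnitude (degrees) the cross-product rotation
#: reference is unreliable and the midpoint fallback is used.
FALLBACK_OMEGA_DEG = 14.4

#: Residue numbers whose beads define a helix midpoint for the fallback
#: rotation reference (middle of the transmembrane helix).
MIDPOINT_RESIDUES = (777, 778, 779, 780)

#: Crossing angles closer to zero than this (degrees, after acute mapping)
#: are reported as exactly zero with the degeneracy flag set.
DEGENERACY_DEG = 0.5


@dataclass
class HelixAxisSet:
    """Axis model of one helix in one frame.

    ``global_axis`` is the unit N->C axis; ``end_centers`` holds the
    N-terminal and C-terminal four-bead centers; ``group_centers`` the
    four-residue group means (7 for a 28-residue chain) and ``k_vectors``
    the 6 unit vectors joining successive group centers.
    """

    global_axis: np.ndarray
    end_centers: tuple[np.ndarray, np.ndarray]
    group_centers: np.ndarray
    k_vectors: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_centers)


@dataclass
class DimerGeometry:
    """Inter-helix descriptors of one frame."""

    omega: float  # signed crossing angle, degrees
    L: float  # lateral separation, nm
    delta_d: float  # N-end distance minus C-end distance, nm
    degenerate: bool = False  # crossing angle indistinguishable from 0


def global_axis(beads: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Unit helix axis (N -> C) plus the two four-bead end centers.

    The axis is the normalized vector from the center of the four leading
    (N-terminal) beads to the center of the four trailing (C-terminal)
    beads. Requires at least 8 beads so the two end groups do not overlap.
    """
    beads = np.asarray(beads, dtype=float)
    if len(beads) < 8:
        raise ValueError(f"need >= 8 beads for an axis estimate, got {len(beads)}")
    n_center = beads[:4].mean(axis=0)
    c_center = beads[-4:].mean(axis=0)
    return as_unit(c_center - n_center), (n_center, c_center)


def segment_axes(
    beads: np.ndarray, *, group_size: int = 4, strict: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Four-residue group centers and the unit vectors k_j between them.

    For the canonical 28-residue chain this yields exactly 7 group centers
    and 6 direction vectors k_1..k_6, each pointing from group center j to
    j+1 in the N->C sense. With ``strict`` (default) any other bead count is
    an error; otherwise the chain is split into ceil(n/group_size) groups,
    the last one possibly short.
    """
    beads = np.asarray(beads, dtype=float)
    n = len(beads)
    if strict and n != 28:
        raise ValueError(
            f"segmented axis model expects 28 beads (25 TMD + 3 linker), got {n}; "
            "pass strict=False for generalized grouping"
        )
    if n < 2 * group_size:
        raise ValueError("too few beads to form two groups")
    n_groups = int(np.ceil(n / group_size))
    centers = np.stack(
        [beads[j * group_size : (j + 1) * group_size].mean(axis=0) for j in range(n_groups)]
    )
    ks = np.stack([as_unit(centers[j + 1] - centers[j]) for j in range(n_groups - 1)])
    return centers, ks


def _axes_and_centroids(frame: BeadFrame, chainA: str, chainB: str):
    axA, _ = global_axis(frame.coords(chainA))
    axB, _ = global_axis(frame.coords(chainB))
    cenA = frame.coords(chainA).mean(axis=0)
    cenB = frame.coords(chainB).mean(axis=0)
    return axA, axB, cenA, cenB


def crossing_angle(
    axisA: np.ndarray, axisB: np.ndarray, inter_axis: np.ndarray
) -> tuple[float, bool]:
    """Signed crossing angle Omega in degrees plus a degeneracy flag.

    Parameters
    ----------
    axisA, axisB : unit N->C axes of the two helices.
    inter_axis : any vector pointing from helix A toward helix B (e.g. the
        centroid difference); only its component along the common
        perpendicular matters for the handedness sign.

    Returns the acute signed angle (|Omega| < 90; negative = left-handed).
    Near-parallel axes (closer than 0.5 deg after acute mapping) return
    (0.0, True): the handedness is geometrically undefined there.
    """
    h1 = as_unit(axisA)
    h2 = as_unit(axisB)
    if float(h1 @ h2) < 0.0:  # acute mapping: |Omega| < 90 by convention
        h2 = -h2
    cosw = float(np.clip(h1 @ h2, -1.0, 1.0))
    mag = np.degrees(np.arccos(cosw))
    if mag < DEGENERACY_DEG:
        return 0.0, True
    det = float(np.cross(h1, h2) @ np.asarray(inter_axis, dtype=float))
    if det == 0.0:
        raise ValueError("inter-axis vector lies in the plane of the two axes")
    return float(-np.sign(det) * mag), False


def lateral_separation(
    beadsA: np.ndarray, beadsB: np.ndarray, mode: str = "center"
) -> float:
    """Lateral helix separation L in nm.

    ``center`` (default): distance between the backbone-bead centroids of
    the two helices. ``min_pair``: minimum over all inter-helix bead pairs.
    """
    A = np.asarray(beadsA, dtype=float)
    B = np.asarray(beadsB, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty bead selection")
    if mode == "center":
        return float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    if mode == "min_pair":
        return float(
            np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=-1).min())
        )
    raise ValueError(f"unknown separation mode {mode!r}")


def delta_d(beadsA: np.ndarray, beadsB: np.ndarray) -> float:
    """N-terminal end-center distance minus C-terminal end-center distance.

    Positive when the two N-termini are farther apart than the two
    C-termini (dimer opened toward the extracellular side).
    """
    _, (nA, cA) = global_axis(beadsA)
    _, (nB, cB) = global_axis(beadsB)
    return float(np.linalg.norm(nA - nB) - np.linalg.norm(cA - cB))


def reference_vector(
    frame: BeadFrame,
    target: str,
    partner: str,
    *,
    omega: float | None = None,
) -> np.ndarray:
    """Rotation-reference unit vector h_ref for the target helix.

    For |Omega| >= 14.4 deg, h_ref is parallel to the cross product of the
    two global axes, oriented from the target helix toward its partner.
    For smaller crossing angles the cross product direction is unreliable
    (bent, nearly parallel helices), so h_ref falls back to the vector from
    the target helix midpoint (mean of the residue 777-780 beads) to the
    partner axis, which is perpendicular to the partner axis by
    construction.
    """
    axT, _ = global_axis(frame.coords(target))
    axP, _ = global_axis(frame.coords(partner))
    cenT = frame.coords(target).mean(axis=0)
    cenP = frame.coords(partner).mean(axis=0)
    if omega is None:
        omega, _ = crossing_angle(axT, axP, cenP - cenT)

    if abs(omega) >= FALLBACK_OMEGA_DEG:
        cr = np.cross(axT, axP)
        norm = np.linalg.norm(cr)
        if norm < 1e-9:
            raise ValueError("degenerate cross product outside fallback regime")
        h = cr / norm
        if float(h @ (cenP - cenT)) < 0:
            h = -h
        return h

    resids = frame.resids(target)
    mask = np.isin(resids, MIDPOINT_RESIDUES)
    if not mask.any():
        raise ValueError(
            "midpoint residues 777-780 absent from target chain; cannot build "
            "the small-crossing-angle rotation reference"
        )
    mid = frame.coords(target)[mask].mean(axis=0)
    # perpendicular foot of the midpoint on the partner axis line
    foot = cenP + float((mid - cenP) @ axP) * axP
    return as_unit(foot - mid)


def frame_geometry(
    frame: BeadFrame,
    chainA: str = "A",
    chainB: str = "B",
    *,
    l_mode: str = "center",
) -> DimerGeometry:
    """All inter-helix descriptors (Omega, L, delta_d) for one frame."""
    A = frame.coords(chainA)
    B = frame.coords(chainB)
    axA, _ = global_axis(A)
    axB, _ = global_axis(B)
    omega, degen = crossing_angle(axA, axB, B.mean(axis=0) - A.mean(axis=0))
    return DimerGeometry(
        omega=omega,
        L=lateral_separation(A, B, mode=l_mode),
        delta_d=delta_d(A, B),
        degenerate=degen,
    )
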