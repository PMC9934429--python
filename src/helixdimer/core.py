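"""Shared containers and constants.

Coordinates are always stored in nanometres internally, whatever the source
file format used (PDB files are Angstrom on disk and converted on read).
Residue numbering follows the transmembrane-domain author numbering: the
default analysed range is 765-792, i.e. the 25 TMD core residues 765-789
plus three juxtamembrane linker residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in kcal mol^-1 K^-1 (for Boltzmann inversion of
#: occupancy histograms into free energies).
KB_KCAL_PER_MOL_K = 0.0019872

#: First residue number of the analysed transmembrane-domain range.
FIRST_RESIDUE = 765

#: Number of TMD core residues averaged for helix rotation angles.
N_RES_TMD = 25

#: Number of residues per chain including the three linker residues.
N_RES_FULL = 28


@dataclass
class BeadFrame:
    """Backbone bead coordinates for the two helices at one time point.

    Attributes
    ----------
    time : float
        Time stamp of the frame (trajectory time units; ns by default).
    chains : dict[str, tuple[np.ndarray, np.ndarray]]
        Maps chain id -> (residue numbers (n,), coordinates (n, 3) in nm),
        with residues sorted ascending.
    """

    time: float
    chains: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def coords(self, chain: str) -> np.ndarray:
        """Coordinates (n, 3) in nm for one chain, N- to C-terminal order."""
        return self.chains[chain][1]

    def resids(self, chain: str) -> np.ndarray:
        return self.chains[chain][0]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def n_beads(self) -> int:
        return sum(len(r) for r, _ in self.chains.values())


def as_unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on (near-)zero input."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return np.asarray(v, dtype=float) / n


def wrap_degrees(angle):
    """Map angle(s) in degrees onto the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (degrees)."""
    u = as_unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    cross = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * cross + (1.0 - c) * np.outer(u, u)
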