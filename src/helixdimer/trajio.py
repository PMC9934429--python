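"""Reading multi-frame dimer structures and writing descriptor tables.

Multi-model PDB files are read through MDAnalysis (MODEL records delimit
frames; coordinates converted to nm). Concatenated multi-frame GRO files
are parsed with a small fixed-width reader because the GRO format has no
chain field and no widely supported multi-frame selection path: chains are
recovered from the residue-number reset between the two consecutive runs
(first 765-792 run = chain A, second = chain B).

Geometry is box-free: trajectories are assumed pre-imaged (no periodic
boundary handling), and GRO box lines are ignored.

Descriptor tables are CSV with '.' decimals, one row per frame, preceded by
'#' comment lines documenting the conventions and package version.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BeadFrame, FIRST_RESIDUE, N_RES_FULL

DESCRIPTOR_COLUMNS = [
    "time",
    "omega_deg",
    "L_nm",
    "delta_d_nm",
    "dtheta_A_deg",
    "dtheta_B_deg",
    "state",
]


@dataclass(frozen=True)
class SelectionSpec:
    """Which beads of which chains the analysis runs on.

    Defaults select backbone beads named "BB" (falling back to "CA" for
    atomistic input when ``allow_fallback``) of chains A and B over the
    author residue numbering 765-792 (25 TMD core + 3 linker residues).
    """

    chainA: str = "A"
    chainB: str = "B"
    residue_range: tuple[int, int] = (FIRST_RESIDUE, FIRST_RESIDUE + N_RES_FULL - 1)
    bead_name: str = "BB"
    fallback_bead_name: str = "CA"
    allow_fallback: bool = True

    def __post_init__(self):
        if self.residue_range[0] > self.residue_range[1]:
            raise ValueError("residue_range must be non-empty")
        if self.chainA == self.chainB:
            raise ValueError("chain identifiers must be distinct")

    @property
    def resids(self) -> np.ndarray:
        return np.arange(self.residue_range[0], self.residue_range[1] + 1)


def _check_contiguous(chain: str, found: np.ndarray, wanted: np.ndarray):
    missing = sorted(set(int(r) for r in wanted) - set(int(r) for r in found))
    if missing:
        raise ValueError(f"chain {chain}: missing residues {missing}")


def _read_pdb(path: Path, selection: SelectionSpec, dt: float) -> list[BeadFrame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    def pick(chain: str):
        ag = u.select_atoms(
            f"chainID {chain} and name {selection.bead_name} "
            f"and resid {selection.residue_range[0]}:{selection.residue_range[1]}"
        )
        if len(ag) == 0 and selection.allow_fallback:
            ag = u.select_atoms(
                f"chainID {chain} and name {selection.fallback_bead_name} "
                f"and resid {selection.residue_range[0]}:{selection.residue_range[1]}"
            )
        if len(ag) == 0:
            present = sorted(set(u.atoms.chainIDs))
            raise ValueError(
                f"chain {chain} with bead {selection.bead_name!r} not found "
                f"(chains present: {present})"
            )
        names = set(ag.names)
        if len(names) > 1:
            raise ValueError(f"chain {chain}: mixed bead names {sorted(names)}")
        return ag[np.argsort(ag.resids)]

    agA, agB = pick(selection.chainA), pick(selection.chainB)
    _check_contiguous(selection.chainA, agA.resids, selection.resids)
    _check_contiguous(selection.chainB, agB.resids, selection.resids)

    frames = []
    for i, _ts in enumerate(u.trajectory):
        frames.append(
            BeadFrame(
                time=i * dt,
                chains={
                    selection.chainA: (agA.resids.copy(), agA.positions / 10.0),
                    selection.chainB: (agB.resids.copy(), agB.positions / 10.0),
                },
            )
        )
    return frames


def _read_gro(path: Path, selection: SelectionSpec, dt: float) -> list[BeadFrame]:
    """Fixed-width parser for concatenated GRO frames (box lines ignored)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    model = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise ValueError(f"{path}: truncated GRO frame header at line {pos + 1}")
        try:
            natoms = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: bad atom count at line {pos + 2}") from exc
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(f"{path}: truncated GRO frame at line {pos + 1}")
        resids, names, xyz = [], [], []
        for ln in body:
            resids.append(int(ln[0:5]))
            names.append(ln[10:15].strip())
            xyz.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
        frames.append(
            _gro_to_beadframe(
                np.array(resids), names, np.array(xyz), selection, time=model * dt
            )
        )
        model += 1
        pos += 2 + natoms + 1  # title, count, atoms, box line
    if not frames:
        raise ValueError(f"{path}: no GRO frames found")
    return frames


def _gro_to_beadframe(resids, names, xyz, selection: SelectionSpec, time: float) -> BeadFrame:
    # split into chain blocks wherever the residue number decreases
    breaks = [0] + [i for i in range(1, len(resids)) if resids[i] < resids[i - 1]] + [len(resids)]
    blocks = [(resids[a:b], [names[i] for i in range(a, b)], xyz[a:b]) for a, b in zip(breaks, breaks[1:])]
    if len(blocks) != 2:
        raise ValueError(
            f"expected 2 chain blocks in GRO frame (residue-number resets), found {len(blocks)}"
        )
    chains = {}
    for cid, (rs, ns, co) in zip((selection.chainA, selection.chainB), blocks):
        name_ok = [n == selection.bead_name for n in ns]
        if not any(name_ok) and selection.allow_fallback:
            name_ok = [n == selection.fallback_bead_name for n in ns]
        in_range = (rs >= selection.residue_range[0]) & (rs <= selection.residue_range[1])
        mask = np.array(name_ok) & in_range
        rs_sel, co_sel = rs[mask], co[mask]
        order = np.argsort(rs_sel)
        _check_contiguous(cid, rs_sel, selection.resids)
        chains[cid] = (rs_sel[order], co_sel[order])
    return BeadFrame(time=time, chains=chains)


def read_frames(
    path,
    format: str | None = None,
    selection: SelectionSpec = SelectionSpec(),
    *,
    dt: float = 1.0,
) -> list[BeadFrame]:
    """Read a multi-frame dimer structure file into BeadFrames (nm).

    ``format`` is "pdb" or "gro" (inferred from the suffix when omitted).
    Frames carry time stamps model_index * dt when the file stores none.
    Beads are returned sorted by residue number within each chain.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(p, selection, dt)
    if fmt == "gro":
        return _read_gro(p, selection, dt)
    raise ValueError(f"unsupported format {fmt!r} (expected pdb or gro)")


def write_descriptors(records: pd.DataFrame, path, *, conventions: dict | None = None):
    """Write the per-frame descriptor table as a commented CSV.

    ``records`` must contain the canonical descriptor columns (time,
    omega_deg, L_nm, delta_d_nm, dtheta_A_deg, dtheta_B_deg, state).
    Raises on an empty table without creating the file.
    """
    from . import __version__

    if len(records) == 0:
        raise ValueError("refusing to write an empty descriptor table")
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"descriptor table missing columns {missing}")
    header = [
        f"# helixdimer descriptor table v{__version__}",
        "# omega_deg: signed crossing angle, negative = left-handed packing",
        "# L_nm: lateral helix separation; delta_d_nm: d(N-ends) - d(C-ends)",
        "# dtheta_*_deg: unwrapped helix rotation vs frame 0, + = counterclockwise"
        " viewed from the C-terminal side",
    ]
    for key, val in (conventions or {}).items():
        header.append(f"# {key}: {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        records[DESCRIPTOR_COLUMNS].to_csv(fh, index=False, float_format="%.6f")


def read_descriptors(path) -> pd.DataFrame:
    """Read back a descriptor CSV written by :func:`write_descriptors`."""
    return pd.read_csv(path, comment="#")
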