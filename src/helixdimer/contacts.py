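"""Residue-residue contact scoring (RRCS) and top-pair concordance.

The contact score of a residue pair sums, over all cross-residue atom (or
bead) pairs, a piecewise-linear kernel of the inter-atomic distance: full
weight at or below an inner cutoff, zero at or beyond an outer cutoff,
linear in between. With the atomistic defaults (inner 3.23 A, outer 4.63 A,
heavy atoms) this is the published RRCS; a bead-level variant with scaled
cutoffs is provided for coarse-grained frames and is explicitly
non-canonical (the canonical score is computed on back-mapped atomistic
structures).

Concordance between two ranked top-N pair lists is their unordered-pair
intersection; for N = 30 the agreement criterion is an overlap of more
than 25 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeadFrame

#: Published atomistic RRCS kernel cutoffs, in nm (3.23 A / 4.63 A).
ATOMISTIC_INNER_NM = 0.323
ATOMISTIC_OUTER_NM = 0.463

#: Non-canonical bead-level cutoffs for coarse-grained input, in nm.
CG_INNER_NM = 0.47
CG_OUTER_NM = 0.70

#: Residue range scored for interhelical contacts (TMD core).
CONTACT_RESIDUE_RANGE = (765, 789)

DEFAULT_TOP_N = 30
CONCORDANCE_MIN_OVERLAP = 25


@dataclass(frozen=True)
class ContactKernel:
    """Piecewise-linear distance kernel (cutoffs in nm)."""

    inner: float = ATOMISTIC_INNER_NM
    outer: float = ATOMISTIC_OUTER_NM

    def __post_init__(self):
        if not (0 < self.inner < self.outer):
            raise ValueError("require 0 < inner < outer cutoff")

    @staticmethod
    def coarse_grained() -> "ContactKernel":
        return ContactKernel(inner=CG_INNER_NM, outer=CG_OUTER_NM)

    def weight(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.clip((self.outer - d) / (self.outer - self.inner), 0.0, 1.0)


@dataclass
class ContactTable:
    """Scores for every unordered cross-chain residue pair in range."""

    residues_a: np.ndarray
    residues_b: np.ndarray
    scores: np.ndarray  # (len(residues_a), len(residues_b))

    def entries(self):
        """(resid_A, resid_B, score) triples, row-major."""
        for i, ra in enumerate(self.residues_a):
            for j, rb in enumerate(self.residues_b):
                yield int(ra), int(rb), float(self.scores[i, j])

    def top_pairs(self, n: int = DEFAULT_TOP_N) -> "PairList":
        """Top-n pairs by score, ties broken by ascending residue numbers."""
        triples = sorted(
            self.entries(), key=lambda e: (-e[2], e[0], e[1])
        )[:n]
        return PairList(pairs=tuple((a, b) for a, b, _ in triples),
                        scores=tuple(s for _, _, s in triples))


@dataclass(frozen=True)
class PairList:
    """Ranked residue pairs (chain A residue, chain B residue)."""

    pairs: tuple[tuple[int, int], ...]
    scores: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.pairs)


def contact_score(coords_i, coords_j, kernel: ContactKernel = ContactKernel()) -> float:
    """Contact score between two residues' coordinate sets (nm).

    Sums the kernel weight over all cross-residue position pairs; symmetric
    in its two arguments and invariant under rigid motion of the frame.
    """
    A = np.atleast_2d(np.asarray(coords_i, dtype=float))
    B = np.atleast_2d(np.asarray(coords_j, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("empty coordinate set")
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=-1))
    return float(kernel.weight(d).sum())


def interhelical_table(
    frame: BeadFrame,
    chainA: str = "A",
    chainB: str = "B",
    *,
    residue_range: tuple[int, int] = CONTACT_RESIDUE_RANGE,
    kernel: ContactKernel = ContactKernel(),
    atoms_by_residue: dict | None = None,
) -> ContactTable:
    """Score all cross-chain residue pairs within ``residue_range``.

    By default each residue contributes its single backbone bead from the
    frame; ``atoms_by_residue`` may map (chain, resid) -> (n, 3) coordinate
    arrays to score back-mapped atomistic structures instead. Residues
    missing from a chain are reported in the error message.
    """
    lo, hi = residue_range
    wanted = np.arange(lo, hi + 1)
    sets = {}
    for cid in (chainA, chainB):
        resids = frame.resids(cid)
        missing = sorted(set(wanted) - set(int(r) for r in resids))
        if missing:
            raise ValueError(f"chain {cid} missing residues {missing}")
        coords = frame.coords(cid)
        per_res = {}
        for r in wanted:
            if atoms_by_residue is not None and (cid, int(r)) in atoms_by_residue:
                per_res[int(r)] = np.asarray(atoms_by_residue[(cid, int(r))], float)
            else:
                per_res[int(r)] = coords[resids == r]
        sets[cid] = per_res

    scores = np.zeros((len(wanted), len(wanted)))
    for i, ra in enumerate(wanted):
        for j, rb in enumerate(wanted):
            scores[i, j] = contact_score(sets[chainA][int(ra)], sets[chainB][int(rb)], kernel)
    return ContactTable(residues_a=wanted.copy(), residues_b=wanted.copy(), scores=scores)


def concordance(list_a: PairList, reference: PairList) -> dict:
    """Overlap of two equal-length top-pair lists as unordered pairs.

    Returns overlap count, fraction, and a pass flag that fires when the
    overlap exceeds 25 common pairs for 30-pair lists (scaled as
    overlap > floor(25/30 * N) for other list lengths).
    """
    if len(list_a) != len(reference):
        raise ValueError("pair lists must have equal length")
    n = len(list_a)
    sa = {tuple(sorted(p)) for p in list_a.pairs}
    sr = {tuple(sorted(p)) for p in reference.pairs}
    overlap = len(sa & sr)
    min_overlap = int(np.floor(CONCORDANCE_MIN_OVERLAP / DEFAULT_TOP_N * n))
    return {
        "overlap": overlap,
        "fraction": overlap / n,
        "passed": overlap > min_overlap,
    }
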