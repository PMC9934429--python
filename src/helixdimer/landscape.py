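"""Dimer-state classification and Boltzmann-inversion free-energy grids.

The dimer state follows the lateral-separation thresholds: dimeric below
1.5 nm, pre-dimeric between 1.5 and 3 nm, monomeric beyond 3 nm. Frames
with L <= 3 nm feed a 2-D occupancy histogram over the two helix rotation
angles, inverted to a free energy via U = -kB T ln p. Two probability
conventions are supported: per-bin probability (U >= 0, minimum at the most
occupied bin) and probability density per rad^2 (can be negative for bins
wider-populated than one radian^2); the grid records which was used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import KB_KCAL_PER_MOL_K

#: Lateral-separation thresholds (nm) between dimer states.
DIMERIC_L_NM = 1.5
MONOMERIC_L_NM = 3.0

#: Simulation temperature (K) used by default for Boltzmann inversion.
DEFAULT_TEMPERATURE_K = 323.0

DEFAULT_BIN_WIDTH_DEG = 5.0
DEFAULT_SUPPORT_DEG = (-180.0, 360.0)


@dataclass
class RegionWindow:
    """Rectangular window in the (dtheta_A, dtheta_B) rotation plane."""

    a_min: float
    a_max: float
    b_min: float
    b_max: float

    def __post_init__(self):
        if self.a_min >= self.a_max or self.b_min >= self.b_max:
            raise ValueError("region window intervals must be non-empty")

    def contains(self, a, b) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return (a >= self.a_min) & (a <= self.a_max) & (b >= self.b_min) & (b <= self.b_max)


@dataclass
class FESGrid:
    """2-D binned free energy over the rotation-angle pair.

    ``U`` is in kcal/mol, NaN where the bin is empty; ``counts`` holds the
    raw occupancy; ``convention`` records the probability normalization
    ("per_bin" or "density_per_rad2").
    """

    edges_a: np.ndarray
    edges_b: np.ndarray
    counts: np.ndarray
    U: np.ndarray
    temperature: float
    convention: str = "per_bin"
    meta: dict = field(default_factory=dict)

    def min_free_energy(self) -> float:
        return float(np.nanmin(self.U))

    def to_files(self, csv_path, json_path):
        """Serialize as a CSV matrix of U plus JSON metadata."""
        pd.DataFrame(self.U).to_csv(csv_path, index=False, header=False, na_rep="nan")
        meta = {
            "edges_a_deg": self.edges_a.tolist(),
            "edges_b_deg": self.edges_b.tolist(),
            "temperature_K": self.temperature,
            "convention": self.convention,
            "total_counts": int(self.counts.sum()),
            **self.meta,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def classify_state(L: float) -> str:
    """Map a lateral separation (nm) to monomeric / pre_dimeric / dimeric.

    Boundaries: dimeric L < 1.5; pre_dimeric 1.5 <= L < 3.0; monomeric
    L >= 3.0 (each boundary belongs to the looser state).
    """
    if L < 0:
        raise ValueError("lateral separation cannot be negative")
    if L < DIMERIC_L_NM:
        return "dimeric"
    if L < MONOMERIC_L_NM:
        return "pre_dimeric"
    return "monomeric"


def filter_dimeric(records: pd.DataFrame, l_max: float = MONOMERIC_L_NM) -> pd.DataFrame:
    """Retain frames with L <= l_max (default 3 nm), preserving order.

    Only associated / pre-dimeric structures are meaningful for the
    rotation-angle landscape; separated monomers are discarded.
    """
    return records[records["L_nm"] <= l_max].copy()


def _invert(counts: np.ndarray, T: float, convention: str, bin_area_rad2: float):
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples to invert")
    p = counts / total
    if convention == "density_per_rad2":
        p = p / bin_area_rad2
    elif convention != "per_bin":
        raise ValueError(f"unknown FES convention {convention!r}")
    with np.errstate(divide="ignore"):
        U = np.where(counts > 0, -KB_KCAL_PER_MOL_K * T * np.log(np.where(p > 0, p, 1.0)), np.nan)
    return U


def fes_2d(
    dtheta_a,
    dtheta_b,
    *,
    temperature: float = DEFAULT_TEMPERATURE_K,
    bin_width: float = DEFAULT_BIN_WIDTH_DEG,
    support: tuple[float, float] = DEFAULT_SUPPORT_DEG,
    convention: str = "per_bin",
) -> FESGrid:
    """Boltzmann-inverted free-energy grid over (dtheta_A, dtheta_B).

    U(bin) = -kB T ln p(bin) with p the histogram estimate of the
    probability; empty bins are masked (NaN). The unwrapped support
    defaults to [-180, 360] deg on both axes with 5-degree bins.
    """
    a = np.asarray(dtheta_a, dtype=float)
    b = np.asarray(dtheta_b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need matching, non-empty rotation-angle samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lo, hi = support
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    counts, ea, eb = np.histogram2d(a, b, bins=[edges, edges])
    bin_area = np.radians(bin_width) ** 2
    U = _invert(counts, temperature, convention, bin_area)
    return FESGrid(
        edges_a=ea, edges_b=eb, counts=counts, U=U,
        temperature=temperature, convention=convention,
        meta={"bin_width_deg": bin_width},
    )


def region_summary(records: pd.DataFrame, window: RegionWindow) -> dict:
    """Mean Omega, L and delta_d over frames inside a rotation window.

    Returns ``{"count": 0, "empty": True}`` when no frame falls inside
    (never zero-valued means).
    """
    mask = window.contains(records["dtheta_A_deg"], records["dtheta_B_deg"])
    sub = records[np.asarray(mask)]
    if len(sub) == 0:
        return {"count": 0, "empty": True}
    return {
        "count": int(len(sub)),
        "empty": False,
        "mean_omega_deg": float(sub["omega_deg"].mean()),
        "mean_L_nm": float(sub["L_nm"].mean()),
        "mean_delta_d_nm": float(sub["delta_d_nm"].mean()),
    }


def average_fes(grids: list[FESGrid]) -> FESGrid:
    """Pool several grids into one: counts are summed, then re-inverted.

    Summing occupancies (rather than averaging U values, which would weight
    trajectories by their log-occupancy) is the convention used to combine
    per-trajectory landscapes into a final symmetric one. All grids must
    share bin edges, temperature and convention.
    """
    if not grids:
        raise ValueError("no grids to average")
    g0 = grids[0]
    for g in grids[1:]:
        if (
            not np.array_equal(g.edges_a, g0.edges_a)
            or not np.array_equal(g.edges_b, g0.edges_b)
            or g.temperature != g0.temperature
            or g.convention != g0.convention
        ):
            raise ValueError("grids have mismatched edges, temperature or convention")
    counts = np.sum([g.counts for g in grids], axis=0)
    bin_width = float(g0.edges_a[1] - g0.edges_a[0])
    U = _invert(counts, g0.temperature, g0.convention, np.radians(bin_width) ** 2)
    return FESGrid(
        edges_a=g0.edges_a.copy(), edges_b=g0.edges_b.copy(), counts=counts, U=U,
        temperature=g0.temperature, convention=g0.convention, meta=dict(g0.meta),
    )
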