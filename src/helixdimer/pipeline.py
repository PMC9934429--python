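"""Frame sequence -> per-frame descriptor table (the analysis core).

This is the composition layer the CLI and the tests share: given BeadFrames
it computes, per frame, the signed crossing angle, lateral separation,
delta_d, the unwrapped helix rotation angles relative to frame 0, and the
dimer-state label, returned as a pandas DataFrame in the canonical
descriptor column order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BeadFrame
from .geometry import frame_geometry
from .landscape import classify_state
from .rotation import rotation_timeseries
from .trajio import DESCRIPTOR_COLUMNS


def analyze_frames(
    frames: list[BeadFrame],
    chainA: str = "A",
    chainB: str = "B",
    *,
    l_mode: str = "center",
    strict: bool = True,
) -> pd.DataFrame:
    """Descriptor table with one row per frame.

    Rotation angles need at least two frames; for a single frame the
    rotation columns are zero (the frame defines its own reference).
    """
    if not frames:
        raise ValueError("no frames to analyze")
    geo = [frame_geometry(f, chainA, chainB, l_mode=l_mode) for f in frames]
    if len(frames) >= 2:
        series = rotation_timeseries(frames, chainA, chainB, strict=strict)
        dA, dB = series.dtheta_A, series.dtheta_B
    else:
        dA = dB = np.zeros(1)
    table = pd.DataFrame(
        {
            "time": [f.time for f in frames],
            "omega_deg": [g.omega for g in geo],
            "L_nm": [g.L for g in geo],
            "delta_d_nm": [g.delta_d for g in geo],
            "dtheta_A_deg": dA,
            "dtheta_B_deg": dB,
            "state": [classify_state(g.L) for g in geo],
        }
    )
    return table[DESCRIPTOR_COLUMNS]
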