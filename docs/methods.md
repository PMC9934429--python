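# Methods

This note documents the models, conventions and numerical choices behind
`helixdimer`, in enough detail to reproduce or audit any number the
package prints.

## The analyzed object

A transmembrane helix dimer reduced to one backbone bead per residue
(coarse-grained "BB" bead or Cα), two chains A and B, author residue
numbering 765–792. Residues 765–789 are the 25 TM-core residues
(N_res = 25); three juxtamembrane linker residues extend the chain to
N′_res = 28 so that it divides evenly into seven 4-residue groups. All
internal coordinates are nanometres; PDB files (Ångström) are converted on
read. Trajectories are assumed pre-imaged: the geometry is box-free and no
periodic-boundary handling is attempted, because no convention for the
original imaging is recoverable from typical inputs.

## Axis models

**Global axis.** Unit vector from the mean of the four N-terminal beads to
the mean of the four C-terminal beads (N→C). The same four-bead end
centers define Δd. Fewer than 8 beads is an error.

**Segmented axes.** The 28 beads are split into seven groups of four; the
six unit vectors k_j between successive group centers serve as local axes
for rotation angles, so a bent helix is followed piecewise instead of
being forced onto one straight line. Residues 1–24 use their own group's
axis k_⌈i/4⌉; residues 25–28 reuse k₆ since no k₇ exists. Chains of other
lengths are rejected by default (`strict=False` generalizes the grouping).

## Descriptors

**Crossing angle Ω.** |Ω| = arccos(h₁·h₂) after acute mapping (if
h₁·h₂ < 0, one axis is flipped so |Ω| < 90°). Handedness:
sign(Ω) = −sign(det[h₁, h₂, ĉ]) with ĉ the inter-axis direction from A to
B; negative = left-handed. The sign is calibrated against an analytic
left-handed two-start superhelix (the helix at +x has tangent (0, −a, 1),
the helix at −x has (0, +a, 1); ĉ from the first to the second is −x̂ and
det[h₁,h₂,ĉ] = +2a > 0, hence the leading minus sign). Axes closer than
0.5° after acute mapping return Ω = 0 with a degeneracy flag — handedness
is geometrically meaningless there.

**Lateral separation L.** Default is the centroid–centroid distance of the
two backbone selections. A `min_pair` mode (minimum over all cross-helix
bead pairs) is provided, but centroid separation is the default because
typical packed-dimer values of ~0.9–1.0 nm refer to axis-to-axis
distances, not bead contacts. The mode in effect is logged per run.

**Δd.** ‖N_A − N_B‖ − ‖C_A − C_B‖ over the four-bead end centers; positive
when the N-termini are farther apart. Symmetric under A↔B exchange,
antisymmetric under reversing both chains' directions.

**Dimer state.** dimeric L < 1.5 nm; pre-dimeric 1.5 ≤ L < 3 nm; monomeric
L ≥ 3 nm. Interval notation in the source material leaves the boundaries
open; each boundary is assigned to the looser state, and the
landscape filter keeps L ≤ 3.0 nm inclusive ("3 nm or less"). The three
states partition [0, ∞).

## Rotation angles

The reference vector h_ref of a helix is parallel to h₁×h₂, oriented
toward the partner helix (positive dot product with the target→partner
centroid vector). When |Ω| < 14.4° the cross product is unreliable for
bent, nearly parallel helices; h_ref then falls back to the vector from
the target helix midpoint (mean of the residue 777–780 beads) to the
perpendicular foot on the partner axis. The fallback threshold is applied
to the instantaneous signed Ω of each frame.

Residue i's angle θ is measured in the plane ⊥ k_j: from the purified
reference h⊥ = normalize(h_ref − (h_ref·k_j)k_j) to the residue bead's
offset from its perpendicular foot on the segment-axis line, signed
positive counterclockwise as seen from the C-terminal side (right-handed
about +k_j; the source convention names the sign but not the viewpoint, so
the viewpoint is fixed here and covered by a calibration test). Beads
within 10⁻⁶ nm of the axis have undefined angles and are dropped from that
frame's average; more than 5 undefined residues marks the frame
unreliable.

Helix rotation Δθ: per-residue angles are unwrapped along time (successive
differences mapped to (−180°, 180°], cumulatively summed) and then
averaged arithmetically over the 25 core residues (configurable to 28).
Unwrapping before averaging is the only consistent reading once rotations
exceed half a turn — a direct θ_s − θ₀ subtraction aliases a 300°
rotation to −60°. The arithmetic (not circular) mean is correct because
unwrapped values are real-valued displacements, not angles modulo 360°.

### Known bias of the axis construction

Four beads at 100°/residue span 1.11 turns, so a 4-bead center sits
0.111·radius ≈ 0.026 nm off the true axis, in a direction attached to the
body. The global axis therefore tilts by up to 0.71° as a helix spins, and
the tilt propagates into h₁×h₂ amplified by 1/sin|Ω|. On ideal
noise-free geometry the resulting spin-recovery bias is ≈3.3° at
|Ω| = 25°, ≈2.5° at 35° and ≈1.85° at 50°. This is a property of the
center-point axis construction itself, shared (smaller) by a covariance
principal axis (0.70°) and by a line fit through the seven group centers
(0.91°). Consequently the spin-recovery validation suite poses the dimer
at Ω = −50°, L = 1.0 nm — the pivot-open regime, which is both where the
mechanism under study has helix rotations occur and where the reference is
farthest from its 14.4° degeneracy. Users should treat rotation angles
measured at small |Ω| as carrying a few degrees of systematic
uncertainty.

## Free-energy landscapes

U(bin) = −k_B T ln p(bin), k_B = 0.0019872 kcal mol⁻¹ K⁻¹, T = 323 K by
default (the production-simulation temperature for this system class).
Bins are 5° × 5° over the unwrapped support [−180°, 360°] on each axis
(observed rotations reach ~360°; the bin width is a package default, not a
reported value). Empty bins are masked (NaN), never assigned pseudo-counts.
Two probability conventions are supported and always recorded in the grid
metadata: `per_bin` (probability mass per bin, U ≥ 0, exp(−U/k_BT) sums to
1 over occupied bins) and `density_per_rad2` (p divided by the bin area in
rad², a pure constant offset of −k_BT·ln(area) relative to per-bin, which
can make well depths negative). Printed basin depths from any particular
simulation campaign are trajectory-specific and are not reproduced here.

Grids are combined by summing occupancy counts and re-inverting — pooling
the sampling — rather than averaging U values, which would weight
trajectories by log-occupancy. Region summaries are arithmetic means of
Ω, L, Δd over frames whose (Δθ_A, Δθ_B) fall in a user-supplied rectangle
(regions are drawn by inspection of the landscape; no automatic basin
detection is promised); an unoccupied window returns an explicit empty
result, never zeros.

## Event detection

Detection runs on a centered moving average (default window 5 frames,
shrinking at the edges); reported Ω values are raw. Pivots are found by
turning-point (zigzag) analysis: reversals smaller than a hysteresis band
(25% of the threshold) are ignored; any swing between successive turning
points with magnitude ≥ threshold (default 45°, with 40° as an alternative
preset) marks an excursion, and the adjacent opposite-direction leg —
approach or return — is folded into the same event. This swing-based
trigger, rather than departure-from-baseline, is what makes a
down-and-back excursion like −6.4° → −51° → +4.6° a single event: its
baseline departure is only 44.6° but the return swing is 55.6°. The
recorded excursion magnitude is max |Ω − Ω(start)| over the event.

Handedness flips are sign changes of the smoothed Ω that exit a ±5° dead
band on both sides; the event time is the interpolated zero crossing.
The dead band suppresses chatter where handedness is ill-defined.

Rotation attribution: per event, Δθ over [start − pad, end + pad] (clamped
to the series; events extending outside the series are dropped with a
warning), labelled A-rotating / B-rotating / both / neither with a 50°
threshold. No formal event definition exists in the source literature;
every detector parameter is therefore exposed with the defaults above
rather than claimed as canonical.

## Contact scores

RRCS kernel: weight 1 at distance ≤ inner cutoff, 0 at ≥ outer cutoff,
linear between, summed over all cross-residue position pairs. Atomistic
defaults (3.23 Å / 4.63 Å) follow the published RRCS definition and are
meant for back-mapped all-atom structures (back-mapping itself is out of
scope; its output is consumed). The bead-level variant (4.7 Å / 7.0 Å,
scaled to MARTINI bead radii) is explicitly non-canonical and labelled as
such. Pair ranking is by score descending with ties broken by ascending
residue numbers, so top-30 lists are deterministic. Concordance of two
equal-length lists is the unordered-pair intersection; for 30-pair lists
the pass bar is more than 25 common pairs (> ⌊25N/30⌋ for other N).

## Synthetic trajectories

The generator is purely kinematic — no force field, lipids, solvent or
integrator — and exists to make every stage testable by parameter
recovery. Ideal helices use canonical α-helix backbone parameters (rise
0.15 nm, twist 100°/residue, radius 0.23 nm). Dimers are posed by spinning
each helix about its own axis, tilting A and B by ±crossing/2 about the
inter-axis direction (so neither helix is privileged and the measured
signed Ω equals the scripted value), separating them along that direction
and sliding B axially. Scripts interpolate pose parameters linearly
between waypoints without angle wrapping (a 0 → 300° spin means 300°).
Bending is a single sinusoidal displacement mode, zero at the termini,
applied before posing so the segment axes k_j measurably deviate from the
global axis; Gaussian positional noise (per coordinate, isotropic) is
added last from a seeded generator — identical seeds give bit-identical
frames and files.

What the generator does *not* emulate: thermal correlation in time,
lipid-mediated forces, helix stretching/compression, sequence-specific
side-chain packing, and periodic images. Passing parameter-recovery tests
therefore demonstrates the correctness of the descriptor algebra and the
detector logic on known geometry, not the biophysical realism of any
particular trajectory.

## Validation problem sizes

The shipped validation suite uses 21–41-frame scripted ramps per spin
(22 noise-free + 8 noisy ramps), 120–171-frame event fixtures, 100-sample
closed-form histograms and 30-pair concordance lists — sizes chosen so the
whole suite re-runs in seconds while every check still exercises the full
code path end to end.

## Limitations

- Rotation angles carry a systematic error growing like 1/sin|Ω| at small
  crossing angles (see above); interpret Δθ near Ω ≈ 0 cautiously.
- The L thresholds (1.5/3.0 nm) and the 14.4° fallback are fixed
  conventions of the descriptor set, not fitted quantities.
- `min_pair` vs `center` separation can differ by several Å for packed
  dimers; comparisons across studies must match modes.
- GRO input relies on the residue-number reset to split chains (the format
  has no chain field); files with renumbered chains need PDB input
  instead.
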