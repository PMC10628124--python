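# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `elevatormd`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Elevator geometry

Domains are residue-range selections in the topology's own (author)
numbering, defaulting to: transport 76–151, 173–196, 332–436; scaffold
207–305, 436–507; bottom halves 76–93/117–137/185–196/351–380 (transport)
and 207–216/272–292/449–507 (scaffold); hinge = upper scaffold
217–271/293–305/437–448.  Residue 436 belongs to both domains; selections
simply include it in both, which perturbs the z-shift metric by its COG
weight (≈0.5 % for the synthetic system) — an accepted property of
range-based selections rather than something to silently special-case.

* **z-shift**: z(COG transport) − z(COG scaffold).
* **rotation**: the angle at the hinge COG between the transport-bottom and
  scaffold-bottom COG vectors, in [0°, 180°].
* Geometry uses raw wrapped coordinates and assumes a whole, centered
  protein; `assert_whole` turns a broken molecule into an explicit error
  instead of a silent artifact.  Every metric takes a chain id, so a dimer
  yields two independent samples per frame.

## Conformational landscape

Features are raw (unstandardized) inter-Cα distances in Å of an arithmetic
residue subset (default every 5th residue of 76–505, i.e. 86 residues and
3655 pairs).  Standardizing would change the meaning of the DBSCAN radius:
eps = 2 is interpreted in unscaled PC units, so the features stay in Å.
DBSCAN (eps = 2, min_samples = 150) runs on exactly the first two PCs;
noise points form the "unassigned" fraction.  Cluster medoids minimize the
mean pairwise Cα RMSD after optimal superposition (Kabsch via batched 3×3
SVDs); the alignment selection defaults to the TMD Cα of the analyzed
chain and is configurable since nothing forces that choice.  The
−RT ln δ surface masks empty bins (undefined, not infinite); RT defaults
to 0.593 kcal/mol (298.15 K) and is configurable because the rendering
temperature is a display convention.

## Excluded-lipid area

Leaflets are split by lipid reference-atom z (default phosphorus) against
the mean reference z.  "Protein center" is the xy centroid of the protein
atoms in the frame, distances are lateral with periodic minimum imaging —
the standard membrane convention.  The bulk area divides the box area
*minus the (box-clipped) exclusion disk* by the bulk lipid count; using
the full box area instead would bias the APL upward by construction, and
the biased variant is kept behind a flag for sensitivity checks only.  The
bulk cutoff defaults to 70 Å (production-scale boxes); synthetic tests use
smaller boxes and pass a smaller cutoff explicitly.  Lattice tests respect
the intrinsic quantization of the method: a disk footprint is recovered
only to within roughly half its perimeter times the lattice spacing.

## Water history and chloride states

Bulk slabs are z beyond the phosphate planes ± a margin (default 5 Å; the
bulk regions are a convention, so the margin is explicit and recorded).
A water's label is the last bulk slab it visited; waters that have not yet
reached either slab carry their initial side-of-midplane label flagged
*provisional* rather than being dropped, which avoids systematic
undercounting early in trajectories while letting strict consumers exclude
them.  Counting is inclusive (≤ 5 Å) against any of a residue's N/CA/C
atoms, one count per water–residue pair, with 3-D periodic minimum
imaging.  Accessibility aggregates report per-frame means and SDs per
(residue, cluster) and also totals, since either summary may be wanted.

Chloride classification: bound (2) within 7 Å of the Cα of F137, S396 and
S398; partially bound (1) within 7 Å of both serines only; else unbound
(0).  Both the per-frame max and mean over chlorides are exposed.

## Electrostatics and gating charge

CC_TMD is the |q|-weighted mean z over atoms of charged residues
(Asp/Glu/Arg/Lys by default, configurable) in the TMD; MC_MEM the
mass-weighted mean z of the phosphates; CZ their difference, invariant to
global z translation.  Unwrapping is per-atom continuity unwrapping
(minimum-image steps between consecutive frames), with a warning when a
step approaches half the box and becomes ambiguous.  Q_d sums over **all**
atoms by default — the Q-route is a system-level quantity — with an
optional selection.  Block means partition the post-equilibration series
into three contiguous blocks (mirroring 3 × 25-length production blocks);
the gating charge is the intercept offset at 0 mV between per-state linear
fits of block-mean Q_d vs voltage, its SD the spread over fits using the
k-th block of every voltage, and the fitted slopes double as a
capacitance consistency check (the two states share one system
capacitance).

## Electrophysiology

The NLC model is the bell-shaped derivative of a two-state Boltzmann
charge–voltage relation, C_lin + (Q_max/α)e^{−u}/(1+e^{−u})², implemented
in an overflow-safe even-in-u form.  Its analytic properties — peak at
V_½ with height Q_max/(4α), area Q_max — are asserted in tests
independently of the fitting path.  Fits are unweighted nonlinear least
squares (scipy `curve_fit`) with data-driven initial guesses (peak
location, half-height width ≈ 3.53 α); traces whose nonlinear component is
below 3× the residual noise are flagged `flat` rather than rejected.

P/N leak subtraction scales and sums the n subpulse responses (each
evoked at polarity·ΔV/n) so that any component linear in voltage cancels
identically; P/+1 is rejected as degenerate.  Charge integration is
trapezoidal after subtracting the trailing-window steady level.
Bleach correction fits a constant-plus-double-exponential envelope on
voltage-quiescent samples only and *divides* it out (photobleaching scales
emission; a subtractive mode exists behind a flag), then normalizes to the
pre-step mean.  F-V points are means over the last 10 ms of each step
(steady state; the window position is configurable).  The 1.5 ms boxcar
is display-only and never applied before fitting, since smoothing
correlates noise and biases least squares.

## The synthetic generators

`make_elevator_trajectory` is **kinematic, not physical** — no force
field, no energies.  It emulates exactly the structure the analyses
assume:

* A C2-symmetric dimer of pseudo-residues 76–507 (N/CA/C per residue).
  Transport-domain atoms rigidly twist about the vertical axis through
  their chain's hinge COG and translate along z between states (defaults:
  1.5 Å down, 7° in the expanded state).  The chain-local layout puts the
  hinge, transport-bottom and scaffold-bottom COGs in one horizontal plane
  so the hinge-angle metric responds one-to-one to the applied twist, and
  the C2 arrangement cancels the lateral centroid shift of the transition,
  keeping the protein-center definition of the area analysis stable.
* Lipids on a square lattice of spacing √APL (default 65 Å²), offset by an
  irrational fraction so hole counts grow smoothly with the footprint
  radius.  The state-dependent intracellular footprint removes whole
  lattice sites; when the expanded-state radius is derived from a target
  fractional area increase (default 5.4 %), the hole grows by the whole
  number of sites closest to that target.  Displaced lipids re-appear as
  far-bulk interstitials, emulating the bulk compression an expanding
  inclusion causes at fixed box and lipid number.  The extracellular
  leaflet's footprint is state-independent by default.
* Waters perform Gaussian random walks (3 Å/frame) with reflecting box
  walls; the membrane slab is impermeable except through an intracellular
  vestibule cylinder that is open only in the expanded state (a gate
  particle occupies it otherwise, and closing the gate expels any water
  still inside).  A small scripted cohort of "pathway waters" (default 8)
  transits the open vestibule, guaranteeing a strong, label-consistent
  conformation-dependent access signal at toy scale where free walkers
  rarely find the channel.  Truth labels are generated by the same
  last-bulk-slab rule the analysis implements, so replay oracles are
  exact.
* One chloride follows the pocket (bound in CS, partially bound in ES,
  with placement margins ≫ positional noise); extra chlorides stay
  unbound.  Six transport ARG (+1 e on Cα) and four scaffold GLU (−1 e)
  carry the mobile charge; per-frame truth Q_d comes from the noiseless
  state templates.
* Protein thermal jitter defaults to σ = 0.1 Å.  The generator's task is
  to realize two *DBSCAN-resolvable* density modes under the fixed
  clustering parameters (eps = 2, min_samples = 150) at the 500-frame
  scale used throughout; the jitter is chosen well inside that regime
  (within-cluster PC spread ≪ eps-connected density requirement).  Real
  trajectories have far larger conformational noise *and* orders of
  magnitude more samples; the toy keeps the ratio of separation to spread
  realistic for the sample count, not the absolute fluctuation amplitude.

`make_cefield_system` reduces the constant-field setup to its essentials:
a mover charge displaced by dz between two otherwise identical static
conformations, a probe charge whose height encodes the capacitive C·V
response, and a jittering unit charge injecting Gaussian Q_d noise
(default 0.02 e).  Truth: Q_g = q·dz/L_z.

The ephys generators sample the same Boltzmann models the fitters use,
with multiplicative double-exponential bleaching (amplitudes 0.15/0.10,
taus 2/20 s), Gaussian noise, ohmic leak, and P/−8 subpulses modeled as
purely linear — the idealization under which P/N subtraction is exact
(experimentally the subpulse range is chosen where sensor charge is
immobile).  VCF fluorescence responds instantaneously to voltage; response
kinetics are not modeled, which is irrelevant to late-window F-V
extraction but means activation time courses are not testable against
these traces.

### What passing tests do and do not show

Recovery on these generators validates the *computations*: selection
logic, metric algebra, clustering wiring, label bookkeeping, unwrapping,
fitting.  It does not validate force-field realism, sampling convergence,
lipid packing beyond a lattice, or water kinetics — none of which the
package claims to model.  Fraction-of-frames per cluster, absolute
explained-variance ratios and similar quantities are properties of the
synthetic conditions, not predictions about any real trajectory.

## Problem sizes and numerics

Default study sizes: 500-frame trajectories (~3,400 atoms, 100 ps/frame
cadence), 75 frames per constant-field voltage (3 × 25-frame blocks,
three voltages: ±200 and 0 mV), 2 mV NLC grids over −250…100 mV, 10 mV
step families over −120…200 mV at 10 kHz.  These sizes keep every
analysis exact-oracle-checkable (O(n²) RMSD matrices, brute-force double
loops) while exercising the full code paths.

Tie-breaks and degeneracies: DBSCAN label ids are arbitrary (tests match
clusters by majority truth state); medoid ties resolve to the lowest
frame id via argmin; empty landscape bins are masked; flat NLC traces are
flagged, not errors; a bleach fit that cannot converge falls back to a
constant envelope with a warning.  Boundary conventions are closed
(≤ cutoff counts) everywhere a cutoff appears.

## Limitations

* Trajectory IO covers PDB topologies and XTC/DCD/TRR frames via
  MDAnalysis; charges/masses come from a sidecar CSV since PDB carries
  neither.  Axon/HEKA binary ephys formats are out of scope (delimited
  tables only).
* No pore-profile geometry, no electrostatic-potential post-processing,
  no per-residue gating-charge decomposition, no group statistics.
* The continuity unwrapping is a documented stand-in for re-centering
  protocols used with production MD engines; it assumes no atom moves
  half a box between frames and warns otherwise.
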