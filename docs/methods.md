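# Methods

This note documents the models, numerical choices and limitations behind
each deerscape module, in the order data flows through the pipeline.

## Structures and geometry (`structio`)

Structures are flat sequences of atom records in author numbering with
coordinates kept internally in Å (the PDB native unit); every public
distance-like quantity is reported in nm. The PDB reader handles the
ATOM/HETATM fixed-column subset with MODEL/ENDMDL: the first model is read
by default, a multi-model reader returns a snapshot list for trajectory
work. Alternate locations collapse to the highest-occupancy conformer
(first on a tie); insertion codes are rejected with a clear error — the
proteins this package was built around use plain sequential numbering, and
silently reinterpreting insertion codes would corrupt site references.
Malformed records raise with the offending line number.

Residue renumbering applies the paper-minus-PDB shift for the supported
deposited entries (3KBR: −25; 5HPQ, 6BQE, 5T0W, 5TUJ, 5JOS, 6WUP: −11),
records the applied offset, and refuses a second application.

Radius of gyration is mass-unweighted over non-hydrogen atoms,
Rg = √(mean‖xᵢ − x̄‖²); the selection predicate is configurable. Torsions
follow the IUPAC sign convention in (−180°, 180°]. Atom placement from
internal coordinates uses the natural-extension reference frame (NeRF)
construction, which is exact: a placed atom reproduces its requested bond,
angle and torsion to ~1e-9.

## Gd(III) tag model (`tagmodel`)

The propargyl-DO3A-Gd(III) label is represented by an internal-coordinate
template running Cα → Cβ → phenyl ring → para-triazole → methylene →
chelator attachment → Gd pseudo-atom. Only dihedrals are conformational
degrees of freedom:

- χ1/χ2 (side-chain) are chosen by an exhaustive grid scan (default 10°)
  of the aromatic probe; the conformer with the fewest steric clashes wins,
  ties going to the smallest χ1 then χ2 on the ascending grid.
- χ6 (ring–triazole) defaults to 180°; χ9 and χ10 default to −140° and 70°,
  the values that orient the chelator for metal coordination by the nearest
  triazole nitrogen.
- The ensemble variant rotates χ9 over a grid (default 10°, configurable —
  tests use 30° for speed) and χ10 over {−60°, 60°, 180°}, giving
  |grid| × 3 conformers.

A clash is a heavy-atom pair (tag atom, protein atom outside the tagged
residue) closer than 2.5 Å; the clash score counts such pairs. Conformers
scoring above the exclusion threshold (default 0) are dropped from
ensembles; if that would empty the ensemble the threshold relaxes to the
ensemble minimum with a warning, so a crowded site still yields its least-
clashing conformers rather than an error.

Bond lengths and angles are idealized organic-geometry values (aromatic
C–C 1.39 Å, C–N ~1.40 Å, planar rings, anti linker torsions, Gd 2.4 Å from
the chelator attachment), collected in one table (`TAG_TEMPLATE`) and
calibrated so the Cα→Gd arm measures ≈1.1 nm in the default conformation
(≈1.4 nm fully extended). Point-mode Gd–Gd distances use the least-clash
single conformer at each site; ensemble mode histograms all cross-pair
conformer distances on the standard r-grid. The module is fully
deterministic. Validation against deposited crystal structures is exposed
as `validate_crystal_predictions(pdb_dir)`; the coordinate files must be
supplied by the user.

## DEER simulation and inversion (`deer`)

**Kernel.** D = 52.04 MHz·nm³ (two free-electron g-values; the <1%
deviation of the Gd(III) g-factor is far below the grid resolution).
Pseudo-secular S = 7/2 effects are neglected — the weak-coupling kernel is
standard for Gd–Gd at r > 2.5 nm. The orientation integral is evaluated by
Gauss–Legendre quadrature on z ∈ [0, 1]; the order defaults to 201 and is
raised automatically to ~0.55 × (3·ω_max·t_max) + 101 when the accumulated
phase demands it, since Gauss–Legendre converges to machine precision only
once its order passes roughly half the total oscillation phase. The
quadrature kernel is cross-checkable against the independent Fresnel-
integral closed form (they agree to ~1e-13 on the working grid). Kernels
are memoized per (t, r, order).

**Grids.** Default r-grid 1.5–8.0 nm in 0.02 nm steps; default time
sampling 8 ns. Traces are assumed phase- and zero-time-corrected with
t = 0 as the first point.

**Background.** Stretched-exponential B(t) = exp(−(kt)^(d/3)), d = 3
(homogeneous solution) by default, fitted on the final 60% of the trace.
The fit runs in log space, where fixed-d fitting is a linear regression in
t^(d/3); a direct nonlinear amplitude × decay fit is amplitude/rate
degenerate on short tail windows and was observed to wander. Fitting d as
well is available but only identifiable for (near-)pure-background traces.
The fitted amplitude estimates 1 − λ; the dipolar signal is
(F − (1 − λ))/λ with F the form factor rescaled to F(0) = 1.

**Inversion.** min ‖Kp − D‖² + α²‖Lp‖² with second-difference L, solved as
non-negative least squares on the stacked system and renormalized to unit
integral.

**α selection.** The L-curve (log residual vs log seminorm over a
29-point grid spanning 1e-4–1e3) is traced with the *unconstrained*
Tikhonov solutions: the non-negativity constraint is itself a strong
regularizer and flattens the corner. Two corner locators are provided. The
default is the triangle/chord rule — the point of maximum signed distance
from the chord joining the curve's endpoints on axis-normalized
coordinates — which is robust to wiggles in the discrete curve. The
discrete maximum-curvature rule is also available, restricted to the lower
half of the residual range because a second convex bend always appears
where the curve approaches its fully-smoothed asymptote. On repeated noisy
simulations the curvature rule occasionally jumps to that spurious bend;
the chord rule does not, which is why it is the default.

**Uncertainty.** The validation band re-runs background correction and
inversion over a grid of background-window starts and added-noise
replicates (noise level estimated from the nominal reconstruction
residual), at the α chosen once on the nominal analysis, and reports
pointwise mean ± 2 s.d. clipped at zero. The band quantifies background-
correction and noise variability only; it does not absorb regularization
bias, so a truth sharper than the working resolution can poke out of the
band near peak tops even when the analysis is healthy. Only background
start and noise are perturbed, not α.

**Reliability zones.** Four thresholds cᵢ·t_max^(1/3) with defaults
c = (5.0, 6.0, 6.5, 7.0) nm·μs^(−1/3), ordered shape ≤ width ≤ mean ≤
detect; the constants are configurable conventions, not fitted quantities.

## State classification (`states`)

Membership is a pure function of the Cα–Cα distance and the window table;
intervals are closed on both ends. A distance inside more than one window
is "ambiguous" rather than first-match — the one overlap in the shipped
tables (open ∩ wide-open) is exactly the case that PCA resolves, and a
silent first-match would hide that step. PCA runs on flattened Cα
coordinates after least-squares (Kabsch) superposition on the rigid
domain; frames split by a deterministic 1-d 2-means along PC1 seeded at
the extreme scores, and clusters map to the candidate state whose
unambiguous-frame mean distance is nearest. If PC1 variance is negligible
or the split collapses, frames stay ambiguous with a warning.

Distribution-route populations integrate p(r) over each state's Gd–Gd
window; mass under k overlapping windows is split equally among them (a
formalization — the overlap comparison is qualitative in practice), and
out-of-window mass is reported as unassigned.

The shipped per-protein windows (`data/state_definitions.yaml`) are the
reported closed/open/wide-open Cα–Cα and Gd–Gd ranges for AncCDT-1,
AncCDT-3, AncCDT-5 and PaCDT.

## Dilution statistics (`oligostats`)

Binomial(3, p) arithmetic, computed in closed form. Monomer exchange is
assumed independent (samples equilibrate before freezing); no
cooperativity parameter. Human-readable output rounds to integer percent
for k = 1, 2 and one decimal for k = 3, matching reporting practice; raw
probabilities are retained in machine output.

## Kinetics (`kinetics`)

Beer–Lambert with ε = 17,500 M⁻¹cm⁻¹ and l = 1 cm by default; rates are
least-squares slopes of product vs time restricted to points below 20%
substrate conversion (points beyond are excluded and counted), with the
blank slope subtracted over the same points — a regression, not a
two-point difference, because it uses every valid aliquot. The
Michaelis–Menten fit is unweighted nonlinear least squares (initialized at
KM₀ = median(S), vmax₀ = 1.2·max(v), Jacobian-scaled, tight tolerances so
noiseless data recover exactly); SEs come from the Jacobian covariance at
the optimum, which assumes homoscedastic noise — the Monte-Carlo
calibration in the tests uses additive noise accordingly. kcat/KM carries
the quadrature-propagated SE. Note that efficiencies recomputed from
*rounded* printed parameters can differ from a table's own value in the
last digit (e.g. 5.68 vs 5.67); agreement is therefore asserted to one
unit in the last printed digit.

## Synthetic data (`synthdata`)

The hinge generator emulates the one feature the analysis actually
measures — a controlled inter-site Cα–Cα distance between two rigid
domains — with the closed form d(θ) = 2L·sin((γ₀+θ)/2) (L = 25 Å arm,
γ₀ = 30° base angle; range 1.29–4.83 nm over θ ∈ [0°, 120°], covering the
2.5–4.8 nm state windows). Domains are ideal helical Cα bundles; full
backbone is emitted only at tag sites, the minimum needed to exercise the
real tag-building code path. An optional twist of the mobile domain about
its arm axis adds a second conformational coordinate that leaves d
unchanged — the degenerate-distance situation PCA disambiguation exists
for. Trajectories are Markov chains started from the stationary
distribution, with per-state Gaussian distance jitter; DEER datasets pair
a noisy trace with its exact generating density. All generators are pure
functions of spec + seed.

What the synthetic data does *not* emulate: side-chain packing and real
rotamer environments (clash scans on synthetic fixtures exercise logic,
not chemistry), orientation selection and multispin effects in DEER,
force-field energetics, and solvent. Passing tests therefore demonstrate
correctness of the computational chain under known ground truth, not
accuracy of tag-rotamer predictions on real proteins — that is what the
deposited-structure validation entry point is for.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script complete
in minutes on one core: 0.02 nm inversion grids where accuracy is asserted
(0.04 nm in property sweeps), 5,000-frame trajectories for population
recovery, 100-frame PCA fixtures, 200–500 Monte-Carlo kinetics replicates,
and 30° χ-grids in ensemble tests (10° default in the API).
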