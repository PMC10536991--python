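# Methods

## Model

`splinetb` implements a self-consistent-charge (SCC) tight-binding model in
a minimal valence basis (H: 1s; C, N, O: 2s, 2p) whose every interaction is
constrained to the Slater–Koster file (SKF) representation:

* per-shell on-site energies ε and Hubbard parameters U are trained
  constants;
* the one-electron Hamiltonian channels H1 (ssσ, spσ, ppσ, ppπ per element
  pair) and the overlap channels S are one-dimensional functions of the
  interatomic distance, represented as quintic B-splines on ~100 uniform
  breakpoints;
* the repulsive pair potentials R are cubic B-splines on ~50 breakpoints;
* the Coulomb kernel γ(R; U_a, U_b) is the standard analytic SCC kernel for
  exponentially decaying s-like charge densities with decay τ = (16/5)U per
  shell, shell-resolved, interpolating between γ(0) = U and 1/R.

Matrix elements follow the standard s/p Slater–Koster direction-cosine
rules. The closed-shell SCC equations are solved by symmetric (Löwdin)
orthogonalization, aufbau filling with two electrons per orbital, Mulliken
shell populations, and Anderson-accelerated linear mixing
(mixing 0.3, depth 4, tolerance 1e-7 e, at most 60 iterations;
non-convergence is flagged, not raised). The total energy is

    E = Tr(P H1) + 1/2 Δq^T γ Δq + E_rep + E_ref,

with Δq the shell Mulliken fluctuations, E_rep the sum of pair repulsive
splines, and E_ref = Σ_Z N_Z C_Z + C_0 a linear per-element reference that
absorbs constant shifts between methods (so energy comparisons are
atomization-energy comparisons). Dipoles are point-charge moments
D = Σ_A q_A R_A of the Mulliken atomic charges (q positive =
electron-deficient).

### Spline representation and boundary conditions

Channels vanish identically at and beyond their upper cutoff: electronic
channels at 4.5 Å (beyond which all trained functions are zero), repulsive
channels at the nearest-neighbor cutoff derived from the first minimum of
the kernel-smoothed pair-distance distribution (bandwidth 0.05 Å). The
zero-value/zero-slope condition at the cutoff is built into the basis: with
a clamped knot vector those two constraints pin exactly the last two
B-spline coefficients, so the trainable vector lives in the remaining
coordinates and every reachable function satisfies the boundary exactly,
while penalties and the repulsive fit stay linear in the free parameters.
Below the lower knot (0.02 Å under the shortest observed distance) the
first polynomial piece continues smoothly; no lower boundary condition is
imposed. Matrix assembly tolerates distances up to 0.05 Å below the lower
knot before warning.

## Regularization

Three penalties keep trained channels physically shaped, all evaluated on a
dense 500-point grid per channel:

* **convex**: squared hinge of the wrong-signed second derivative. The
  required sign is upward curvature for channels approaching zero from
  above, downward from below, assigned automatically from the channel's
  values over the outer half of its range.
* **single-inflection** (overlap channels): the required sign flips once at
  a trainable location, parameterized by an unconstrained latent squashed
  through a sigmoid into (r_low, r_cut) and entering the penalty through a
  smooth tanh sign profile (width = 2 grid spacings) so the location is
  differentiable. Locations within half a grid spacing of r_low degenerate
  exactly to the plain convex penalty.
* **smoothing**: sum of squared third derivatives. It requires a continuous
  third derivative — the reason the electronic splines are quintic — and is
  never applied to the cubic repulsive splines.

Default weights: convex 1e3 (the optimization is insensitive to the value
as long as it is large enough to suppress violations), smoothing 1e-4
(chosen as a small value that removes knot-scale piecewise-linear artifacts
without visibly biasing fits on the synthetic suite). The hinge is
quadratic, so a small transient violation survives during gradient
training and decays as training proceeds.

## Training

The loss is a weighted sum of mean squared errors per property,
L = Σ_prop (1/N_prop) Σ_i (w_prop r_i)², with defaults w = 6270 Ha⁻¹
applied to the per-heavy-atom energy residual, 100 (eÅ)⁻¹ per Cartesian
dipole component, and 1 e⁻¹ per atomic charge; N_prop counts scalar
residuals. One source describes this loss both as an L2 loss and as
combining root-mean-square errors; the two phrasings agree up to monotone
reparameterization, and the quadratic (sum-of-squares) form is what is
implemented — each component equals (w × RMSE)². Energy residuals compare
totals with the trained reference folded in, which equals an
atomization-energy comparison; a config switch controls the per-heavy-atom
normalization.

Training inverts the SCC and descent loops: every 10 epochs a full batched
SCC solve refreshes the frozen charge fluctuations on all training and
validation configurations (warm-started from the previous refresh), and the
repulsive splines plus reference coefficients are refit globally by a
convex quadratic program (interior-point, primal-dual predictor-corrector,
tolerance 1e-10) under per-pair shape constraints R' ≤ 0 and R'' ≥ 0 on a
500-point grid, with the boundary built into the basis. Between refreshes,
ADAM (lr 1e-5, default moments) updates spline coefficients, on-site
energies, Hubbards, and inflection latents against the loss with charges
held fixed. Batch membership (10 configurations) is frozen for the whole
run — the precompute caches depend on it — and only the batch order
reshuffles per epoch. A plateau scheduler multiplies the learning rate by
0.9 when the validation loss has not improved by 1e-4 (relative) over 50
epochs; the best-validation parameter vector is returned. Configurations
whose SCC solve fails at a refresh are excluded from that cycle and
counted.

Gradients are analytic throughout: the density matrix is differentiated by
occupied-subspace perturbation theory (only occupied–virtual energy
denominators appear, so degeneracies within the occupied or virtual blocks
are harmless; a degenerate frontier gap flags the configuration), Hubbard
derivatives of the Coulomb kernel come from complex-step evaluation (two
evaluations per step regardless of parameter count), and
spline/on-site gradients are transposed sparse design maps. Checks against
central finite differences hold to 1e-5 relative.

**Validation gauge.** With few held-out formulas, per-bond constants inside
the repulsive's sampled band are collinear with molecular composition, so
raw validation energy residuals drift along a direction that
atomization-energy comparisons are invariant to. The validation loss used
for checkpointing and the plateau scheduler therefore projects energy
residuals onto the complement of the per-element composition design.

## Synthetic ground truth and what it does (not) emulate

The generator builds a full "true" parameter set: overlap channels are
two-center integrals of Slater-type valence orbitals (1s/2s/2p with
moderately compressed exponents — compression keeps the minimal-basis
overlap matrix of crowded distorted molecules safely positive definite),
evaluated in prolate-spheroidal coordinates by tensor Gauss–Legendre
quadrature; H1 channels follow a Wolfsberg–Helmholz ansatz (0.5·K·(ε_i +
ε_j)·S, K = 1.75); repulsive walls are convex decaying exponential-like
functions with exact zero value/slope at their cutoffs. Every channel is
projected onto its curvature class by a small convex fit (sign constraints
with a strict margin on the penalty grid), so generated channels satisfy
the penalties *exactly* while reproducing the orbital integrals to better
than 1e-6 below the taper region (the top ~1.1 Å before the 4.5 Å cutoff is
replaced by a smooth decay to zero — the model's hard cutoff is a
representational restriction, not a property of the integrals).

Geometries are Gaussian-distorted copies (default scale 0.06 Å per
Cartesian component) of twelve built-in templates at standard bond lengths
(H2 through acetaldehyde, including peroxide/hydrazine/hydroxylamine so
every element pair occurs), with rejection below a hard 0.6 Å contact
floor. Targets are the toy model's converged SCC energies (plus per-element
offsets and optional Gaussian noise), dipoles, and charges.

The training *seed* is built by the same two-center procedure with
exponents uniformly scaled by 0.93 — the role of a pre-existing
physics-based parameter set: qualitatively right shapes and sign classes,
quantitatively off, and systematically overbinding (diffuser orbitals), so
the non-negative repulsive correction is feasible. On-site energies and
Hubbards start at the free-atom table both in the generator and the seed,
as tight-binding practice does.

What this emulates: distorted near-equilibrium organic geometries,
realizable targets, formula-level train/test separation. What it does not:
conformer sampling of a real quantum dataset, target noise between
electronic-structure methods, open-shell species, and distance
distributions of systems larger than 3 heavy atoms — passing tests
demonstrate the machinery and its identifiable quantities, not chemical
accuracy on real data.

## The recovery study and identifiability

The closed-loop study (2000 configurations, ≤3 heavy atoms, batch 10,
charge/repulsive refresh every 10 epochs, 300 epochs) uses a
formula-disjoint split with a coverage condition: a held-out formula must
only probe (pair, distance-band) interactions that remain represented in
training (tolerance 0.15 Å up to 2.5 Å). With 12 formulas this is the
analog of the dense coverage a 471-formula dataset provides implicitly;
without it, a bond type carried only by held-out formulas (e.g. the C=O
double bond) puts the potentials into an extrapolation regime no training
could constrain.

Held-out accuracy after the reference refit reaches a few tenths of a
kcal/mol. Pointwise recovery of individual H1/S channels, however, is
limited to the tens-of-kcal/mol-equivalent scale: the observables determine
only coupled combinations of channels (an effect the underlying method is
known for — deviations in one potential can cancel deviations in another),
and training started *at* the generating parameters drifts along this
near-flat manifold at the kcal/mol scale without measurable loss change.
The study therefore reports both the held-out observable errors (the
identifiable quantities) and the channel-space deviations (documenting the
degeneracy); see the acceptance notes.

Problem sizes throughout (2000 configurations, 300 epochs, 100/50 knots,
500-point penalty grids) are the package's standard desk-scale study
configuration.

## Numerical choices

* Löwdin orthogonalization with a 1e-10 eigenvalue floor; non-positive-
  definite overlaps and degenerate frontier gaps are flagged per
  configuration during batched work and raised in the strict per-geometry
  API.
* Padded batching: configurations share a common orbital count; padded
  orbitals are decoupled identity rows of S with large distinct H diagonal
  energies, so they stay unoccupied.
* The interior-point QP adds a relative ridge (1e-9 of the quadratic
  trace) for strict convexity; restarting from random feasible points
  changes the optimum by < 1e-8 relative.
* Unit conventions: Å and e at every I/O boundary, bohr/hartree inside the
  kernels and the SKF files (1 Å = 1.8897259886 bohr, 1 Ha = 627.509474
  kcal/mol).
* SKF export uses the classic (non-extended) dialect, 0.02 bohr grid,
  s/p table columns, cubic-spline repulsive block with an exponential
  short-range head; spσ/psσ of a heteronuclear pair live in the two
  ordered-pair files.

## Known limitations

* Closed-shell systems only; no spin polarization, fractional filling,
  forces, or periodic boundary conditions.
* Individual channel functions are identified by the data only up to
  coupled combinations (see above); exported SKF files are faithful to the
  trained model, not to any unique "true" decomposition.
* The reference coefficients and per-pair repulsive levels are jointly
  determined only up to the atomization-energy gauge when the formula set
  is small.
* The 20-SD outlier rule uses the population standard deviation of signed
  residuals (a flag switches to absolute residuals).
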