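# splinetb

Trainable spline-parameterized self-consistent-charge tight binding for
organic molecules (H, C, N, O), with Slater–Koster file export.

## The problem

Semiempirical tight-binding methods get their speed from a drastic
constraint: in a minimal valence basis, every electronic interaction is a
*one-dimensional function of the interatomic distance*. A parameter set is
then a handful of constants (on-site energies ε, shell Hubbard parameters
U) plus, per element pair, the distance-dependent Slater–Koster channels —
Hamiltonian integrals H1 (ssσ, spσ, ppσ, ppπ), overlaps S, and a short-range
repulsive potential R. `splinetb` treats all of these as *trainable*:
channels are regularized B-splines (quintic for H1/S, cubic for R) fitted
end-to-end by gradient descent against reference energies, dipoles, and
atomic charges, and the result exports to the standard SKF format that
downstream tight-binding codes consume.

The model solved on every forward pass is the second-order SCC equation

    E = Tr(P H1) + ½ Δq᜖ γ(U) Δq + Σ_pairs R(r) + Σ_Z N_Z C_Z + C_0

with P the closed-shell density matrix of the generalized eigenproblem
H C = S C ε, Δq the Mulliken shell-charge fluctuations, γ the analytic SCC
Coulomb kernel, and a linear per-element reference energy that makes all
energy comparisons atomization-energy comparisons.

Training uses the loop-inversion schedule: charge fluctuations are frozen
between periodic full SCC refreshes (every 10 epochs), so ADAM steps never
backpropagate through SCF iterations; on the same schedule the repulsive
splines and reference coefficients are refit globally by a convex quadratic
program under shape constraints (monotone decreasing, convex, exact zero
value and slope at the cutoff). Shape regularizers — a curvature-sign
("convex") penalty, its single-inflection extension for overlaps, and a
third-derivative smoothing penalty — keep the splines physical. Everything
is verifiable offline: a synthetic-data module generates a full "ground
truth" parameter set from analytic Slater-orbital integrals, distorted
molecular geometries, and targets, closing the loop from data generation to
parameter recovery.

Who this is for: people developing or studying tight-binding
parameterizations who want a transparent, fully-testable reference
implementation of spline-parameterized SCC models with analytic gradients —
not a production quantum-chemistry package.

## Worked example

```python
import numpy as np
from splinetb import Geometry, make_toy_paramset, solve_geometry

params = make_toy_paramset(elements=(1, 8))     # synthetic H/O parameter set
water = Geometry([8, 1, 1], [[0.0, 0.0, 0.0],
                             [0.758, 0.0, 0.588],
                             [-0.758, 0.0, 0.588]])
res = solve_geometry(water, params)
print(f"converged in {res.n_iterations} SCC iterations")
print(f"total energy      {res.total_energy:.6f} Ha")
print(f"  electronic      {res.electronic_energy:.6f} Ha")
print(f"  charge-fluct.   {res.coulomb_energy:.6f} Ha")
print(f"  repulsive       {res.repulsive_energy:.6f} Ha")
print(f"atomic charges    {np.round(res.charges, 4)} e")
print(f"dipole moment     {np.round(res.dipole, 4)} e*angstrom")
```

prints

```
converged in 9 SCC iterations
total energy      -3.638985 Ha
  electronic      -3.795383 Ha
  charge-fluct.   0.036036 Ha
  repulsive       0.120362 Ha
atomic charges    [-0.8395  0.4198  0.4198] e
dipole moment     [0.     0.     0.4936] e*angstrom
```

The electronic term is the band energy of the converged density; the
charge-fluctuation term is the second-order Coulomb energy of the Mulliken
charges (oxygen pulls ~0.84 electrons from the hydrogens); the repulsive
term is the sum of the O–H and H–H pair walls; the dipole is the
point-charge moment along the molecular axis.

Exporting and re-importing a parameter set through SKF files:

```python
from splinetb import skf_read, skf_write
skf_write(params, "skf-out")           # H-H.skf, H-O.skf, O-H.skf, O-O.skf
params2 = skf_read("skf-out", [1, 8])  # tabulated form, assembles identically
```

A command line mirrors the library (`tt make-synthetic`, `tt data
filter|split|histogram`, `tt train --config run.yaml`, `tt fit-repulsive`,
`tt evaluate`, `tt export-skf`); see `tt --help`.

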