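# Methods

## Exciton model of DNA circular dichroism

### Model

Each nucleobase carries a small set of localized electronic transitions
(the in-plane pi-pi* bands). A transition is specified by its vertical
energy `E` (eV), its electric transition dipole magnitude `mu` (Debye), and
an in-plane polarization angle `phi` measured from the base's glycosidic
axis. The packaged table `quadbind/params/base_transitions.json` holds two
representative transitions per base type (energies 4.5-5.4 eV, dipoles
1.5-3.5 D); it is a documented, editable input, not a fitted quantity. In
the full multiscale treatment these parameters would come from per-snapshot
excited-state calculations; here they are fixed monomer values oriented by
each base's instantaneous reference frame, which keeps the exciton
machinery intact while making the calculation desk-scale. Consequences:
simulated band positions carry a system-dependent offset relative to
experiment (corrected, when desired, by an explicit rigid energy shift),
and the model carries no ligand absorption at all — spectral changes upon
binding reflect DNA deformation only.

Base frames: origin at the ring-atom centroid; `z` is the least-squares
ring-plane normal with its sign fixed by the circulation of the ordered
hexagon cycle N1-C2-N3-C4-C5-C6 (an intrinsic choice, hence equivariant
under rigid motions); `x` is the C1'->N9 (purine) or C1'->N1 (pyrimidine)
direction projected into the plane; `y = z cross x`.

The Frenkel Hamiltonian has site energies (cm^-1) on the diagonal and
point-dipole couplings off it:

    V_ij = C [ mu_i . mu_j - 3 (mu_i . r_ij)(mu_j . r_ij) ] / r_ij^3,

`C = 5034.12 cm^-1 / (D^2 A^-3)`. Coincident-center pairs (two transitions
of one base) take a configurable intra-base coupling, default 0; the
point-dipole rule is guarded below 0.1 A separation. Diagonalization uses
a symmetric eigensolver with a deterministic sign fix (first nonzero
eigenvector coefficient positive), which also resolves degenerate pairs
reproducibly.

Rotational strengths use the electric-dipole-only coupled-oscillator
matrix method,

    R_k = -(pi nu0 / 2) c_k^T A c_k,   A_ij = R_ij . (mu_i x mu_j),

with `nu0` the mean site wavenumber shared by all states. The sign makes
the long-wavelength component of a right-handed twisted dimer positive —
the textbook exciton-couplet convention, and the reason the idealized
right-handed B-DNA ensemble shows its positive lobe red of the negative
one. Sharing `nu0` makes the zero-sum rule `sum_k R_k = 0` exact
(`tr A = 0` plus eigenvector orthogonality); weighting each state by its
own excitonic wavenumber is available as an option, at the price of an
approximate sum rule. Intrinsic (magnetic-dipole) monomer strengths are
taken as zero.

Spectra: each state contributes `R_k` times a Gaussian of width
`sigma = 0.15 eV` (default), unit-normalized in the energy domain, so the
energy integral of the spectrum equals `sum_k R_k`. Ensembles are
unweighted pointwise means over identical wavelength grids. Energy shift
and uniform intensity scaling are explicit user parameters recorded in the
spectrum metadata; a least-squares shift/scale matcher against a reference
spectrum exists but only reports values, it never silently applies them.

### Topology classification

The classifier detects extrema by prominence (default 5% of the global
absolute maximum) inside 225-310 nm and requires a one-to-one match, sign
included, between the detected extrema and one topology's band pattern
within +/-10 nm: parallel -240/+265, antiparallel -260/+295, hybrid
-240/+270/+290 nm. No match, or more than one, returns "unknown". The
one-to-one rule is what keeps a three-band hybrid spectrum from also
matching the two-band parallel pattern. Note these are *experimental* band
positions: unshifted model spectra of the idealized fixtures generally sit
at higher energy and classify as "unknown" unless an appropriate shift is
applied — the honest behavior for a phenomenological Hamiltonian.

## Idealized geometries and what they do (and do not) emulate

Duplex fixtures place planar idealized bases (regular-polygon rings,
1.38 A bonds) in pairs whose midpoints sit exactly on the helix axis,
successive pairs separated by the rise (default 3.38 A) and rotated by the
twist (default 36 deg, right-handed); the complementary strand is the
180-degree dyad partner, giving antiparallel strands. An intercalation
pocket doubles the central step's rise and inserts a planar dummy
chromophore (hexagonal ring plus one "cationic-N" marker atom) with a
left/right lateral offset; the two poses have identical DNA and exactly
mirror-imaged ligands across the plane containing the helix axis and the
pocket axis. (The *complete* left/right complexes cannot be exact global
mirror images — reflection would flip the helix handedness — so the mirror
property is defined, and tested, on the ligand relative to the pocket.)

G-quadruplex fixtures stack square-planar guanine quartets (ring centroids
4.0 A from the axis, inter-tetrad rise 3.3 A, twist 30 deg) with
glycosidic patterns anti/anti/anti/anti (parallel), anti/syn/anti/syn
(antiparallel), and anti/anti/syn/anti (hybrid); syn guanines are flipped
about their glycosidic axis and annotated. An end-stacked ligand sits
3.4 A above the top tetrad with its marker atom pointing toward the
central channel ("in") or the periphery ("edge").

Snapshot ensembles jitter every residue independently: a random rotation
about its centroid (angle ~ N(0, 3 deg)) plus a Gaussian translation
(sd 0.15 A). This emulates the *decorrelating* effect of thermal motion on
exciton couplings — enough to test ensemble averaging and the robustness
of band-shape signatures — but none of the correlated backbone dynamics,
groove breathing, ion coordination, or ligand-induced relaxation of real
trajectories. Passing tests therefore validate the spectroscopic
machinery, not the conformational ensemble of any real sequence.

## Titration analysis

The 1:1 complex concentration is the exact mass-balance root computed in
the conjugate form `HG = 2 H0 G0 / (S + sqrt(S^2 - 4 H0 G0))`,
`S = H0 + G0 + 1/Kb`, which is accurate when `Kb H0 >> 1` where the
textbook quadratic formula cancels catastrophically. DNA is expressed as
per-base concentration (strand concentration times the number of bases),
matching how such titrations are analyzed; `n_bases` is an explicit input.

Fitting is nonlinear least squares over `(ln Kb, eps_free, eps_bound)`
(ln parameterization keeps `Kb` positive; trial values clipped to
`e^+/-46` to protect the forward model), multi-started from seven
log-spaced `Kb` guesses spanning 1e2-1e8 M^-1 and keeping the lowest-cost
optimum. Standard errors come from the Gauss-Newton curvature; the free
energy is `-RT ln Kb` with `R = 1.98720e-3 kcal mol^-1 K^-1` at a default
298.15 K, and its uncertainty is `RT (Kb_se / Kb)`. `eps_free` can be
frozen to an independently measured value; by default it floats. Constant
absorbance (including the all-zero series) is reported as a non-converged
fit with a diagnostic message, not an exception.

The synthetic generator uses a 20-point schedule — a ligand-only point
followed by geometrically spaced additions from 0.2 to 30 ligand
equivalents — the spacing practitioners use to resolve the isotherm's
curvature, with i.i.d. Gaussian absorbance noise (default scenarios use
sd 0.002 on signals of ~0.3). Under these conditions the fitted `Kb` has a
typical relative error of ~5%, so a 10% recovery band is roughly a
2-sigma statement: reproducible at the fixed seeds the tests use, but not
guaranteed for every seed.

## Alchemical bookkeeping

FEP legs are estimated per window by exponential averaging,
`-kT ln <exp(-dU/kT)>`, evaluated via log-sum-exp; window errors come from
a seeded block bootstrap (10 contiguous blocks, 200 resamples) and combine
in quadrature. TI is trapezoidal quadrature of `<dU/dlambda>`. Both are
estimator-level tools: the package performs no sampling of molecular
systems, and cluster-scale binding free energies are out of scope.

The bulk restraint-release term is analytic. With harmonic springs on
`(r, theta, phi)` and `(Theta, Phi, Psi)`, the restrained configurational
integrals factor into six one-dimensional integrals with Jacobians
`r^2 sin(theta)` and `sin(Theta)`:

    dG_rest_bulk = -kT ln(V0 / Z_trans) - kT ln(8 pi^2 / Z_orient),

`V0 = 1661 A^3`. Each integral is evaluated in closed form — the `r^2`
integral via real error functions, the `sin` integrals via the error
function of a complex argument — so the result is exact over the true
finite domains (not a stiff-spring approximation) and numerically stable
for arbitrarily stiff springs, where the erf terms saturate. Polar
references must avoid the coordinate poles where the Jacobian vanishes.
Each cycle component is defined as the free energy of its arrow drawn
toward the bound, unrestrained state; the total is the plain four-term sum
with quadrature-combined uncertainties.

## Numerical conventions and edge cases

- Units: eV and cm^-1 for spectroscopy (1 eV = 8065.544 cm^-1,
  lambda[nm] = 1239.842 / E[eV]), Debye and Angstrom for dipoles and
  geometry, kcal/mol for thermodynamics.
- `Kb = 0` returns zero complex concentration by limit; coincident
  exciton centers below 0.1 A are an error.
- Degenerate eigenvalues are resolved by the first-coefficient sign rule.
- Spectrum shifting re-evaluates on the fixed nm grid by linear
  interpolation in energy, zero-filled outside the original support;
  successive shifts compose additively in the metadata and to
  interpolation accuracy in the intensities.
- PDB residue-name dialects (A/DA/ADE, terminal 5'/3' variants) normalize
  to one-letter codes; water, ions, and unrecognized het groups are
  dropped; LIG/CHE residues are retained as ligand dummies and excluded
  from exciton assignment.
- All randomness flows through explicit seeds or `numpy.random.Generator`
  instances; CLI runs with the same config and seed are byte-identical.

## Known limitations

- Fixed monomer transition parameters ignore environment and
  conformation dependence of site energies; absolute band positions are
  therefore offset and only band *shapes* are meaningful.
- Point-dipole couplings overestimate interactions at sub-stacking
  distances compared to transition-density treatments.
- The jittered ensembles contain no correlated dynamics (see above).
- The titration module fits strictly 1:1 binding on per-base
  concentration; cooperative or multi-site binding is out of scope.
- FEP/TI operate on user-supplied samples; no BAR/MBAR estimators.
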