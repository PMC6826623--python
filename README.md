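# quadbind

Desk-scale analysis of small-molecule binding to duplex and G-quadruplex
DNA, combining three views of the same problem:

1. **Exciton-model circular dichroism.** Stacked nucleobases are coupled
   chromophores; diagonalizing the Frenkel Hamiltonian (site energies on
   the diagonal, point-dipole couplings off it) yields excitonic states
   whose rotational strengths determine the ECD spectrum. Because ECD is
   exquisitely sensitive to chromophore geometry, the simulated band shape
   reports on helix handedness, G-quadruplex topology, and the structural
   perturbation a bound ligand induces.
2. **UV-Vis titration fitting.** Adding DNA to a ligand solution of fixed
   concentration shifts the absorbance at a wavelength where only the
   ligand absorbs. Fitting the 1:1 isotherm
   `A = eps_free (L0 - [HG]) + eps_bound [HG]`, with `[HG]` the exact
   mass-balance root, gives the association constant `Kb` and the binding
   free energy `dG = -RT ln Kb`.
3. **Alchemical free-energy bookkeeping.** The double-decoupling cycle
   `dG0 = dG_rest_site + dG_alch_site + dG_rest_bulk + dG_alch_bulk`
   is assembled from per-window free-energy-perturbation samples
   (exponential averaging), thermodynamic-integration gradients, and an
   analytic standard-state restraint-release term for harmonic restraints
   on spherical coordinates `(r, theta, phi)` and Euler angles
   `(Theta, Phi, Psi)`.

The package also generates its own idealized fixtures: fiber-model B-DNA
duplexes (with optional left/right intercalation pockets), stacked
G-tetrad quadruplexes of parallel, antiparallel, and hybrid glycosidic
patterns (with optional "in"/"edge" end-stacked ligand), jittered snapshot
ensembles, noisy synthetic titrations, and Gaussian FEP sample sets.

Intended users: spectroscopists and modellers who want a transparent,
fully tested reference implementation of these three calculations without
a molecular-dynamics or quantum-chemistry pipeline.

## Worked example

```python
import numpy as np
import quadbind as qb
from quadbind.titration import default_dna_points

# --- titration: simulate a noisy 1:1 binding experiment and re-fit it
series = qb.simulate_titration(Kb=1.1e5, eps_free=3.0e4, eps_bound=1.5e4,
                               ligand_total=1.0e-5,
                               dna_base=default_dna_points(1.0e-5),
                               noise_sd=0.002, seed=11)
fit = qb.fit_binding(series)
print(f"Kb = {fit.Kb:.3g} +/- {fit.Kb_se:.2g} M^-1")
print(f"dG = {fit.delta_g:.2f} +/- {fit.delta_g_se:.2f} kcal/mol")

# --- exciton CD of an idealized right-handed B-DNA ensemble
models = qb.snapshot_ensemble(qb.GeometryRecipe("duplex", sequence="A" * 14),
                              10, seed=17)
avg = qb.ensemble_average(
    [qb.snapshot_spectrum(qb.exciton_calculation(m)[0]) for m in models])
lam_pos = avg.wavelengths[np.argmax(avg.intensity)]
lam_neg = avg.wavelengths[np.argmin(avg.intensity)]
print(f"positive lobe at {lam_pos:.0f} nm, negative lobe at {lam_neg:.0f} nm")
```

prints

```
Kb = 1.13e+05 +/- 4.6e+03 M^-1
dG = -6.89 +/- 0.02 kcal/mol
positive lobe at 268 nm, negative lobe at 252 nm
```

The fitted `Kb` recovers the generating value (1.1e5 M^-1) within its
standard error, and the free energy is the direct `-RT ln Kb` conversion at
298.15 K. The duplex ensemble produces the conservative exciton couplet
expected for a right-handed helix: positive lobe at longer wavelength than
the negative one. `qb.classify_g4_signature(spectrum)` labels a spectrum
"parallel" / "antiparallel" / "hybrid" by matching its extrema against the
characteristic G4 band patterns (-240/+265, -260/+295, -240/+270/+290 nm),
returning "unknown" for anything ambiguous.

## Command line

```sh
quadbind spectrum --recipe recipe.json --snapshots 20 --seed 7 --out-dir out/
quadbind titrate --csv titration.csv --ligand-total 1e-5 --n-bases 22
quadbind fep --csv windows.csv --seed 1
quadbind cycle --rest-site 1.2 0.1 --alch-site -20.0 0.4 \
               --rest-bulk -7.5 0.0 --alch-bulk 24.0 0.5
quadbind fixtures --seed 42 --out-dir fixtures/
```

Identical configuration and seed give byte-identical outputs.

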