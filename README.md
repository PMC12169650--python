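# dnaadapt

Analysis toolkit for **sequence-dependent DNA structural adaptation upon
minor-groove protein binding** — the kind of adaptation the bacterial
nucleoid-structuring protein H-NS induces in AT-rich DNA, where B-form
duplexes develop localized A-like features (North sugar pucker, anti
glycosidic angles, undertwisting, minor-groove widening, increased
bending).

The package is written for structural biophysicists who combine molecular
simulation with fluorescence spectroscopy. It covers the full analysis
chain:

- **Rigid base parameters** — the six base-pair descriptors
  (shear, stretch, stagger, buckle, propeller, opening) and six base-step
  descriptors (shift, slide, rise, tilt, roll, twist), extracted by
  standard-base frame fitting and a mid-frame hinge decomposition with an
  *exact* closed-form inverse.
- **Backbone conformation** — sugar pseudorotation (P, ν_max) via the
  Altona–Sundaralingam relation
  `tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°))`,
  glycosidic torsion χ, and North/South, anti/high-anti classification
  with per-position fraction profiles over ensembles.
- **Helix geometry** — minor/major groove widths from refined cross-strand
  P–P distances (−5.8 Å correction), local helical axis, and bend
  magnitude/direction relative to the minor groove.
- **Protein–DNA contacts** — the two contact coordinates of minor-groove
  binding, C_minor–QGR (QGR motif, residues 112–114, vs minor-groove
  acceptors N3/O2/O4′) and C_sugar–Trp (Trp-109 NE1 vs deoxyribose atoms),
  plus the bound-state rule (C_minor–QGR > 25 with ≥ 2 Trp–sugar contacts)
  and 2D contact densities.
- **Metadynamics free energy** — PLUMED-HILLS-dialect parsing and
  reconstruction of the twist free-energy profile as the negative
  accumulated Gaussian bias, with windowed averaging (sub-profiles every
  2 ns, mean ± SD over 40 ns from 10 ns), free-diffusion diagnostics, and
  the run-pruning rule for opened base pairs.
- **Binding spectroscopy** — inner-filter correction
  `F_corr = F_obs exp((A_ex + A_em)/2)`, Hill-isotherm fits
  `θ = c^n / (K^n + c^n)`, Gibbs energies `ΔG = −RT ln(1/K_D)` at 298 K,
  and IRF-reconvolution multi-exponential lifetime fits
  `I(t) = Σ α_i exp(−t/τ_i)`.
- **Synthetic data** — a first-class generator for every input: duplex
  coordinates built from rigid-base parameters and sugar targets (ideal
  A/B fiber forms or perturbed ensembles with controlled fluctuations and
  neighbor twist coupling), planted protein probes with exactly known
  contact counts, a Langevin walker depositing metadynamics hills
  (σ = 0.04 rad, h = 0.1 kJ/mol, every 4 ps, bounded to 10–60°), Hill
  titrations, and Poisson-noise TCSPC decays.

## Worked example

```python
import numpy as np
from dnaadapt import (build_duplex, generate_titration, hill_fit,
                      generate_hills, windowed_profiles,
                      fes_minimum_and_width, DoubleWellPotential,
                      pseudorotation, classify_pucker, chi_angle)
from dnaadapt.rigidbase import duplex_parameters

# an ideal B-form 12-mer with the AT-rich core sequence
dup = build_duplex("GCATATATATGC")
pp, sp, _ = duplex_parameters(dup)
print(f"central step twist: {sp[5].twist:.2f} deg, rise: {sp[5].rise:.2f} A")

res = dup.strand_watson[5]
P, numax = pseudorotation(res)
print(f"residue A6 sugar: P = {P:.1f} deg ({classify_pucker(P)}), "
      f"chi = {chi_angle(res):.1f} deg")

# a noiseless synthetic quenching titration, fitted to the Hill isotherm
conc = np.geomspace(1e2, 1e7, 14)
fit = hill_fit(generate_titration(1.57e4, 1.38, 100.0, 20.0, conc, 0.0))
print(f"Hill fit: K = {fit.K:.3g} nM, n = {fit.n:.2f}, "
      f"dG = {fit.delta_G:.2f} kcal/mol")

# a biased walker on a twist double well, reconstructed per the
# windowed production protocol
hills = generate_hills(DoubleWellPotential(minima=(25.0, 45.0), barrier=5.0),
                       duration_ns=52.0, seed=3)
prof = windowed_profiles(hills, every_ns=2.0, window_ns=(10.0, 50.0))
res = fes_minimum_and_width(prof)
print(f"FES minimum at {res['s_min']:.2f} deg, valley width "
      f"{res['width']:.1f} deg ({prof.n_subprofiles} sub-profiles averaged)")
```

prints

```
central step twist: 36.00 deg, rise: 3.38 A
residue A6 sugar: P = 162.0 deg (South), chi = -100.0 deg
Hill fit: K = 1.57e+04 nM, n = 1.38, dG = -6.55 kcal/mol
FES minimum at 24.75 deg, valley width 7.5 deg (21 sub-profiles averaged)
```

The built duplex is an extractor fixed point (twist 36°, rise 3.38 Å, the
C2′-endo/South sugar of B-DNA); the Hill fit inverts the generator exactly
and converts K_D = 1.57 × 10⁴ nM to −6.55 kcal/mol; the windowed
metadynamics average locates the 25° well of the double-well landscape to
within the grid resolution.

## Command line

`dnaadapt` exposes the pipeline as subcommands: `simulate`,
`analyze-conformation`, `analyze-rigid-base`, `analyze-grooves`,
`analyze-bend`, `analyze-contacts`, `fes reconstruct|diagnose`,
`binding hill-fit|decay-fit|delta-g`, and `run-all`. A full run

```sh
dnaadapt run-all --out run --seed 7
```

writes per-stage CSV/JSON plus a manifest (config hash, seed, versions);
identical config and seed reproduce every output byte for byte.

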