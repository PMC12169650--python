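# Methods

This note records the models, conventions and numerical choices behind
`dnaadapt`, and what the synthetic generators do and do not emulate.

## Rigid-base frames and parameters

Each base carries a right-handed orthonormal frame obtained by
least-squares superposition (proper rotation only, reflection corrected
through the SVD sign) of an embedded standard base onto the observed ring
heavy atoms. The embedded coordinates place the base in the standard
nucleic-acid reference frame: origin near the ring centre, x toward the
major groove, y toward the strand-I backbone. Because the builder places
bases with exactly these coordinates, frame fitting on built structures is
exact to machine precision, and the builder/extractor pair forms a strict
inverse — the property the test suite enforces (< 1e-9 on 500 random
parameter sets; < 1e-6 through a full 12-mer).

The relative geometry of two frames is decomposed by the mid-frame hinge
construction: both frames are rotated by half the bending angle Γ about
the hinge axis z₁ × z₂ so their z-axes coincide; the remaining rotation
about the common z is the twist ω, and the hinge phase φ is measured from
the mid-frame y-axis. Then roll (propeller) = Γ cos φ, tilt (buckle) =
Γ sin φ, opening/twist = ω, and translations are the origin difference
expressed in the mid-frame. This triple is inverted exactly by
`Rz(ω/2−φ) Ry(Γ) Rz(ω/2+φ)`. Two numerical points matter:

- Γ is computed as `atan2(‖z₁×z₂‖, z₁·z₂)`; the arccos form loses half
  the significant digits for nearly parallel z-axes and fails the 1e-9
  round trip there.
- the hinge construction (not a z-y-z Euler extraction) keeps the
  (Γ, φ, ω) branch consistent with the inverse when φ exceeds ±90°,
  i.e. for strongly negative rolls.

The Crick frame is flipped 180° about its own x-axis before pairing, so
two coincident ideal bases give all-zero pair parameters, and strand
swapping negates exactly buckle and shear (verified by test). Relative
rotations or twists ≥ 179° raise a degenerate-hinge error.

## Sugar model

Deoxyribose rings are generated from the pseudorotation targets (P,
ν_max): a planar pentagon (radius 1.293 Å) is puckered with out-of-plane
displacements `z_j ∝ q cos(4πj/5 + φ_cp)`, and (q, φ_cp) are solved
numerically (trust-region least squares, four phase starts) so that the
realised Altona–Sundaralingam (P, ν_max) — recomputed from the ring's own
endocyclic torsions — match the target. Realised phases agree with the
request to ~1e-13 in practice; the acceptance band is ±5° to cover the
idealised bond geometry. The glycosidic attachment solves the two-cone
problem (angles N–C1′–O4′ = 108.2°, N–C1′–C2′ = 113.7°) on the backbone
side of the ring — the branch that winds the backbone outward with
natural D-deoxyribose handedness — and the ring is then rotated about the
glycosidic bond so χ (O4′–C1′–N9–C4 for purines, O4′–C1′–N1–C2 for
pyrimidines) is exact. C5′/O3′/O5′ are placed by ideal internal
coordinates; the bridging phosphate sits on the O3′(i)–O5′(i+1) segment
with ideal P–O bonds where the gap allows, using a direction built from
local bond vectors so that uniform helical parameters give a perfectly
uniform backbone (this covariance is what makes ideal-fiber groove widths
position-independent). Backbone torsions are otherwise unconstrained:
only sugar and base geometry feed the analyses downstream.

Canonical fixture constants (configurable): B-form — twist 36.0°, rise
3.38 Å, slide 0, roll 0, P 162°, χ −100°; A-form — twist 32.7°, rise
2.56 Å, slide −1.5 Å, roll 8.0°, P 18°, χ −160°. These are textbook
fiber-model values used only as generator targets. The default χ class
boundaries (anti [−180°,−120°), high-anti [−120°,−60°), syn [0°,90°))
are declared decisions chosen so the canonical A χ is anti and the
canonical B χ is high-anti; North/South split at P = 90°/270° with
half-open intervals and no East/West classes.

## Ensembles

`sample_ensemble` draws per-frame step parameters from a multivariate
normal around the spec means. Adjacent-step twist coupling uses a
tridiagonal Toeplitz covariance with correlation ρ on the first
off-diagonal (positive definite for |ρ| up to ≈ 0.52 at 11 steps;
violations raise). Coordinates are rebuilt per frame; the drawn parameter
arrays are attached for diagnostics. The generator emulates the
*stationary fluctuation statistics* of an MD ensemble — means, SDs and
nearest-neighbour twist correlations — but not time correlation,
anharmonicity, backbone substates (BI/BII), ions or solvent; conclusions
from passing tests are about the analysis chain, not about force-field
realism.

## Groove widths, axis and bend

Groove widths follow the refined cross-strand P–P convention: at pair i
the minor width is the minimum over Crick phosphates of pairs i−2 and i−3
of the distance to the Watson phosphate of pair i+1, minus 5.8 Å for two
phosphate van der Waals radii (major: offsets +2, +3). Offsets are
configurable; positions lacking phosphates (termini) are missing, not
zero. Absolute widths differ between conventions by a constant — only
relative changes are interpreted.

The local helical axis at a step is the z-axis of the mid-step frame,
vector-averaged over a sliding window (default 3 steps). The screw axis
of the step transform is *not* used: for any uniform-parameter helix all
step screw axes are exactly parallel (a uniform helix has a single global
screw axis), which would make bend identically zero even for strongly
rolled, visibly curved duplexes. The mid-frame z tracks the local
tangent: uniform roll 5° with zero twist turns it 5° per step, giving the
closed-form window-averaged bend of 40° over 11 steps that the tests
check against a composed-rotation oracle. Total bend is the angle between
the averaged axes of the first and last windows; bend direction is the
signed angle, in the plane perpendicular to the entry axis, from the
central pair's minor-groove vector (−y of the pair frame) to the exit
axis' perpendicular component.

## Contacts

Contacts are strict `d < 4.5 Å` heavy-atom pairs (cutoff configurable, a
community default — the statements consumed downstream are thresholds on
counts, not absolute counts). Minor-groove acceptors are purine N3,
pyrimidine O2 and sugar O4′. The bound-state rule is C_minor–QGR > 25
co-occurring with ≥ 2 Trp–sugar contacts. Probe fixtures plant
pseudo-atoms at exact distances, choosing among 256 sphere directions the
one leaving no stray atom of the relevant group inside the cutoff, so
planted counts are known exactly and verified against an O(n²) oracle.

## Metadynamics reconstruction

The free-energy profile is the negative sum of deposited Gaussians,
min-shifted to zero, on a 0.25° grid bounded to [10°, 60°] with the bias
treated as zero outside. Sub-profiles are taken every 2 ns, *min-aligned
before averaging* (the standard choice, declared so the SDs are
interpretable), and the production profile is their pointwise mean ± SD
over the 40 ns window starting at 10 ns. Well-tempered rescaling is not
supported: a biasfactor ≠ 1 in a HILLS file is warned about and ignored.
The pruning rule treats a base pair as "open" when all Watson–Crick
donor–acceptor heavy-atom distances exceed 3.5 Å, "unrecovered" when it is
open at every frame from its first opening to the end of the run, and
excludes a run when more than one central pair is unrecovered.

The hill generator is an overdamped Euler–Maruyama walker (kT =
2.494 kJ/mol, default γ = 1.25 kJ·mol⁻¹·ps·deg⁻², dt = 0.5 ps) with
reflective walls at the bias boundaries and deposition parameters σ =
0.04 rad, h = 0.1 kJ/mol, stride 4 ps. The mobility is chosen so the
walker traverses the window well inside the 10 ns free-diffusion
deadline. A known limitation of bounded, non-tempered deposition: the
stationary bias ripple scales like √(deposition rate × range × σ × kT / D)
≈ 0.5–1.5 kJ/mol here — several hill heights — and reflective-wall spikes
*grow* with run length, so longer runs do not flatten the profile
further. The flat-landscape convergence test therefore asserts interior
flatness (3σ in from the walls) below kT at the production window rather
than below a few hill heights; well depths and minima positions, which is
what the analysis consumes, are unaffected (double-well minima recovered
within 1° and stable across seeds).

## Binding analyses

Hill fits run on inner-filter-corrected fluorescence against log₁₀
concentration, with F0 and F_inf fitted by default (θ = (F0−F)/(F0−F_inf)
is not measured directly); standard errors come from the fit covariance
mapped through K = 10^{log K}. ΔG = −RT ln(1/K_D) uses R = 1.98720e-3
kcal/(mol·K), T = 298 K, K_D on the 1 M standard state. Wald 95%
intervals on K cover the truth in ≈ 91% of seeded θ-noise replicates
(σ_θ = 0.02, n = 200) — acceptable for the mild nonlinearity at this
noise level. Decay fits convolve the multi-exponential with the
normalised IRF by discrete causal convolution on the data grid (Gaussian
IRF, 1 ns FWHM default) and minimise Poisson-weighted least squares
(weights 1/max(counts,1)); amplitudes are reported normalised with the
scale separate, components are capped at 3 (identifiability), and τ
guesses spread a decade around the count-weighted mean time.

## Pipeline problem sizes

The bundled pipeline and the acceptance script use desk-scale sizes
chosen as the package's own defaults: ensembles of tens to 2000 frames
(2000 where fluctuation statistics are asserted, giving 3-SE mean checks
and ±0.05 Pearson bands), 52 ns of hill deposition (13 000 hills, 21
sub-profiles in the production window), 14-point titrations spanning
both sides of K, 2048-channel decays at 10⁶ counts, and 200-replicate
coverage simulations. Each stage is deterministic under a fixed seed.

## Known limitations

- The synthetic ensembles have no time correlation, so convergence
  diagnostics that depend on autocorrelation cannot be exercised.
- Groove widths and helix axis use local constructions; no curvilinear
  global axis is computed, so strongly kinked structures are summarised
  coarsely.
- The probe complexes are geometric fixtures, not physical protein
  poses; contact densities over ensembles of such fixtures test the
  bookkeeping, not binding thermodynamics.
- PDB is the only mandatory structure format; trajectories must be
  supplied as multi-model PDB.
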