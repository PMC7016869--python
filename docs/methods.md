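# Methods

This note records the models, numerical choices and limitations behind
`confensa`.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Curve reduction

**Frame averaging.** Repeated exposures are screened by reduced χ²
against the elementwise *median* curve (robust to a single damaged frame
dragging a mean reference toward itself); the rejection threshold is the
99th percentile of the χ² distribution at the per-curve point count.
Survivors combine by inverse-variance weighting, with σ propagated.

**Buffer subtraction and transmission.** For dilute macromolecules the
net signal I/σ falls below 1σ over q ≈ 0.1–0.7 Å⁻¹, so the subtracted
intensity should average to zero there.  The scalar transmission factor t
in I_sub = I_sample − t·I_buffer is solved so that the error-weighted mean
of I_sub over the window vanishes.  Because the low-q side of the window
can still contain real signal, the window start is trimmed upward while a
*smoothed* run of residuals (11-point moving average) exceeds its standard
error — a prefix-only trim, so noise cannot be self-selected.  The
residual floor of this estimator in the synthetic world is the flat
point-scatterer tail of the bead models (≈0.5% of the buffer level),
which bounds t recovery at about half a percent; with the signal below 1%
of buffer in the window, recovery is within 1%.

**Calibration.** Intensities multiply by (calibration constant /
concentration in mg/mL) so that extrapolated I(0) equals the molecular
weight in daltons — the convention used for the MW(I0) estimator.

## Invariants

**Guinier.** Weighted linear fit of ln I vs q² (weights (I/σ)²), iterated
so the window satisfies q·R_g ≤ 1.3 (configurable).  With `auto_range`
the window additionally sheds a leading run of positive residuals (low-q
upturn from aggregation) and shrinks from the top while the residuals
carry statistically significant curvature (|quadratic coefficient| > 3σ),
which removes the ~2% high bias a fixed q·R_g = 1.3 window incurs on
sphere-like particles.  Errors come from the fit covariance.

**P(r).** The transform I(q) = 4π∫P(r)·sinc(qr)dr is discretized on 201
points with trapezoid quadrature, endpoints pinned to zero, and solved by
Tikhonov-regularized least squares with a second-difference smoothness
matrix; positivity is off by default.  α defaults to the L-curve corner
(maximum discrete curvature over a 21-point log grid).  When D_max is not
given it is scanned over [2R_g, 4.5R_g] (26 points, fixed scan α = 1e-6)
and the *smallest* value whose χ² is within 10% (or +0.05) of the minimum
is chosen — larger D_max only buys unconstrained oscillation room.  A
boundary optimum warns.  Real-space invariants come from the moments:
I(0) = 4π∫P dr, R_g² = ∫r²P dr / 2∫P dr.

**Molecular weight.** MW(I0) = calibrated I(0) (requires calibration
metadata, otherwise omitted).  MW(Porod): Q = ∫q²(I−B) dq to q = 0.25 Å⁻¹
with a flat background B from a K/q⁴+B fit to the (noise-smoothed) upper
third of the range, a Guinier completion below q_min, and a Porod
continuation I(q_c)·q_c³ beyond the cutoff; V_p = 2π²I(0)/Q and
MW = V_p/1.6 (Å³/Da, apparent hydrated-protein ratio).  MW(Vc):
V_c = I(0)/∫qI dq (integral to 0.3 Å⁻¹ with Guinier completion),
Q_R = V_c²/R_g, MW = Q_R/0.1231.  Both constants are recorded in the
output for auditability.  These empirical constants presume protein-like
curve shapes; on a single compact sphere-like body (deep form-factor
minima) MW(Vc) reads ~20% low, which is why oligomer numbers should be
formed against a monomer reference measured with the same estimator.

## Model scattering

Residue-level beads with a uniform q-independent form factor (f = 1) and
no hydration shell; model-vs-experiment R_g comparisons therefore carry a
±2% systematic allowance rather than a modelled shell.  The Debye sum
uses scipy `pdist`; above 300 beads the pair distances are spread over a
0.5 Å grid with *cubic (4-node Lagrange) weights*, so contracting the
sinc kernel with the histogram interpolates it to O(Δ⁴) — measured
≤2×10⁻⁵ relative deviation from the exact double sum, far inside the
0.2% target.  Scale/background fits are closed-form weighted least
squares; reduced χ² uses n−2 degrees of freedom.  Mixtures follow the
calibrated-I(0) convention: each component normalized to I(0) = its mass,
so a dimer slot contributes twice a monomer slot at equal mass
concentration.

## Conformer pools

Linkers are self-avoiding random walks with fixed 3.8 Å C-alpha bonds;
steric exclusion is 3.0 Å against context and against walk beads three or
more bonds away (i−1, i−2 are quasi-bonded: their distances encode the
bond and bond-angle constraints, not excluded volume).  The measured
end-to-end inflation over the ideal chain value n·b² is ≈1.4× — excluded
volume swells the chain, as it must; tests freeze the band (1.0, 1.6).
Bridging walks bias step directions toward the target when the remaining
contour length tightens and then close by iterative end-point correction
(drag proportional to position along the chain, bond lengths
re-normalized each pass) to within 0.25 Å, accepted at 0.5 Å.

Pools re-sample every flexible segment per member, processing segments
C→N so that each block N-terminal of a segment (tethered first domain,
or the whole regulatory block above a melted hinge) is rigidly
repositioned at the sampled exit with a random orientation, subject to a
zero-clash test.  Members store float32 coordinates; curves are computed
lazily on a shared q grid.  Same seed ⇒ identical pool.  Representative
melted-hinge sub-templates come from k-means (k = 4) on the unit vectors
from the hinge exit to the swung block centroid over a coarse ensemble.

Rigid-body refinement is simulated annealing (geometric cooling, move
amplitudes shrinking as √T) over block rotations (≤15°), translations
(≤5 Å) and segment re-sampling, the latter re-bridged so chain continuity
is free; the score is χ² + 0.5·clashes + 10·Σ gap excess over 4.2 Å at
body joins.  P2 mode searches the monomer pose against a fixed two-fold
axis and scores the generated dimer.

## Ensemble selection and state decomposition

The GA works on multisets of `ensemble_size` = 20 member indices
(repeats allowed) over all pools; fitness is the closed-form scale+
background χ² of the (mass-scaled) average curve.  Elites (10% of a
population of 50) carry over unchanged — best-so-far fitness is provably
monotone — parents are picked by 2-way tournaments, children by uniform
crossover with per-slot mutation (rate 0.1) to a uniform pool draw.
Defaults follow common ensemble-optimization practice and are echoed in
every output (`EnsembleFit.params`).  Independent seeds agree on χ² to
within 5% on the tested worlds; the pipeline runs 5 seeds, reports the
best and aggregates the union of selections for the distribution.

R_g histograms of the selection (with multiplicity) and of the pools
share a common grid.  Peak decomposition fits k = 1..3 Gaussians chosen
by BIC; when the histogram's member count is known the fit and the BIC
use multinomial standard errors √(max(p, 0.5/N)/N) — essential for small
distant peaks whose unweighted residual contribution is negligible.
Degenerate fits (two components within 2σ of each other) are rejected as
re-parameterized single peaks.  Each retained peak is re-tested as a
flat-top: an equal-height split-center double Gaussian replaces it if it
lowers BIC by >2 with a genuine split (|c₂−c₁| > σ), and its FWHM is then
measured numerically on the summed pair.  Areas integrate analytically;
peaks under 3% are absorbed into their nearest neighbour (only
significant states are reported).

## Shape reconstruction (lite)

Dummy beads on a cubic lattice (spacing 2·bead radius, default 3 Å)
inside a sphere of diameter D_max.  The bead count is fixed by the Porod
volume of the input curve (V_p/spacing³), and the annealer uses only
bead-conserving relocation moves (a random occupied bead moves to an
empty neighbour of the body), so the volume stays physical while the
shape morphs.  The energy is log χ² (scale-free, so the penalties have
constant leverage) + 1.0·(beads with no occupied neighbour) +
0.5·looseness (mean empty-neighbour fraction); ~20 proposed moves per
lattice site with geometric cooling 0.5→0.003, then stray fragments are
relocated onto the main body's surface and a greedy relocation polish
runs to convergence.  P2 symmetry flips site pairs related by the z
two-fold, so symmetric models are exact by construction.  Averaging
superposes all runs (inversion-corrected NSD alignment) onto the
lowest-mean-NSD member, discards runs beyond mean+2sd (filtering), votes
site occupancies at 50% and trims to the median volume.  This module is
assessed at shape level only (R_g, NSD, axis ratios) — never bead-level
identity with the established reconstruction tools.

## Synthetic data: what it emulates, what it does not

Domains are jittered-cubic-lattice globules at 176 Å³ per residue — the
*apparent* (hydrated) scattering volume implied by the Porod ratio
(1.6 Å³/Da × 110 Da/residue), deliberately larger than dry packing so MW
estimators see realistic curves.  The default architecture mirrors a
six-domain ~100 kDa exchange factor: an N-terminal domain on a 15-residue
tether, regulatory and catalytic blocks separated by a 5-residue hinge.
Two-state scenarios plant each state as a 20-conformer sub-ensemble drawn
from the same tether-sampling distribution the analysis pools use, so
recovery is well-posed; the dimer scenario plants a P2 dimer ensemble
against a monomer ensemble with the monomer *mass* fraction as the dial.
The buffer is b₀e^(−q/0.2)+b₁ with b₁ = b₀ and the level set to 10× the
signal at q = 0.2 Å⁻¹ (flat-dominated, like water/capillary scattering);
counting noise is σ(q) = √(I·E)/E with exposure factor E = 0.1, giving
I(0)/σ ≈ 100 — self-consistent by construction (χ² ≈ 1 when the true
model is fit to its own data).

Not emulated: detector geometry and smearing, inter-particle structure
factors (crowding), the q-dependence of real residue form factors (the
flat high-q tail of point beads is the visible artifact, handled by the
transmission solver's trimming), radiation damage.  A green test on this
world therefore establishes the correctness of the *analysis machinery*,
not instrument-specific reduction.

## Known limitations

* MW constants (1.6, 0.1231) are protein-empirical; non-protein-like
  shapes bias MW(Vc) by up to ~20%.
* D_max from the scan is noise-limited: ±5% on clean data, ~±15% at
  I(0)/σ ≈ 100.
* The GA quantifies pool *weights* robustly (±5 points over replicates),
  but single-run peak tables of sparse minor states (a few slots) can
  merge; aggregate several seeds (the pipeline default) before
  decomposing.
* The shape annealer is a simplified single-phase reconstruction; P2 is
  the only symmetry supported.
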