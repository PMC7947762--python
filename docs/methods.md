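# Methods

This note documents the models and numerical procedures implemented in
`lporlab`, the defaults chosen where the underlying experimental protocols
leave them open, and what the synthetic-data generators do and do not
emulate.

## Scope and data model

The package analyses the bespoke computations around light-dependent
protochlorophyllide oxidoreductase (LPOR) characterisation and the genomics
of aerobic anoxygenic phototrophic bacteria (AAPB): spectral-titration
dissociation constants, pulsed-illumination enzyme kinetics, nanoDSF
melting temperatures, marker-gene AAPB classification, tree-support
counting, and small SAXS/sequence utilities.  Units are fixed throughout:
wavelengths nm, concentrations µM, temperatures °C, path length cm, time s,
absorbance AU.  Spectra are stored on strictly increasing grids; series are
resampled by linear interpolation onto the intersection grid (spectrometer
exports differ by fractions of nm, and no instrument grid is canonical).
Missing table cells are rejected rather than imputed, because all downstream
least-squares steps assume complete spectra.

## Dissociation constant from a spectral titration (`binding`)

**Model.** A fixed pigment concentration [B] (default 2 µM) is titrated with
apo-protein [A] from 0 to 200 µM with NADPH saturating, so protein+NADPH is
one binding partner A.  Binding red-shifts the pigment Q_y band; every mixed
spectrum is a nonnegative combination of the free and bound reference
spectra plus a turbidity baseline `a·λ⁻ⁿ + y0` with n fixed to 2.  At
these concentrations ligand depletion is severe, so the bound signal follows
the Morrison quadratic

    x_AB([A]) = S0 + (Smax−S0) · (Kd+B+A − √((Kd+B+A)² − 4AB)) / (2B).

The implementation evaluates the equivalent conjugate form
`2A / (Kd+A+B + √(…))`, which avoids the catastrophic cancellation of the
difference form when Kd → 0 with A ≫ B; the discriminant is clamped at zero
against rounding underflow.  An independent brute-force mass-action root
finder (`simulate.equilibrium_bound_fraction`, bracketed Brent iteration on
the complex concentration) serves as the oracle in tests; the two agree to
better than 1e-12 absolute over six orders of magnitude in (Kd, A, B).

**Per-spectrum unmixing.** Bounded linear least squares (BVLS) over
{free reference, bound reference, λ⁻², 1} with the reference coefficients
and scatter scale constrained nonnegative (mole fractions and turbidity are
physical) and the offset free.  Scatter parameters are per-spectrum.
References closer than cosine similarity 0.995 set a collinearity flag.

**Global fit and bound-reference refinement.**  The free reference is the
zero-protein spectrum; the bound reference is initialised from the
highest-concentration spectrum after subtracting a scatter baseline fitted
to the band-free long-wavelength tail (top 15 % of the scan).  Both
mole-fraction profiles are then fitted globally (Levenberg–Marquardt, via
lmfit) to the depletion curve with shared Kd, S0, Smax, the free profile
modelled as the complement of the bound one.  Because the initial bound
reference contains a fraction φ of free pigment, the fitted bound plateau
extrapolates to Smax = 1/(1−φ); the refinement therefore estimates
φ = (Smax−1)/Smax, subtracts φ·free from the bound reference, renormalises,
and repeats unmix→fit until |ΔKd|/Kd < 1e-4 (cap 10 rounds).  This is the
unique linear correction that maps the fitted plateau back to 1 and the
mole fractions onto [0, 1].  Cumulative contamination is reported as
1 − Π(1−φ_k).  The reported Kd uncertainty is the asymptotic standard error
from the Jacobian at the optimum; replicate-based error estimates are out of
scope.  Titrations without curvature (all free or all bound) raise an
identifiability error rather than returning a meaningless Kd.

## Photoconversion kinetics (`kinetics`)

Frames recorded during a light pulse, or standing more than 0.1 AU (median
across wavelengths when spectra are available) above the local linear trend,
are removed before analysis; the spike test is one-sided because
illumination leakage only ever adds signal.  The initial velocity is the
ordinary-least-squares slope of the longest prefix of at least 4 frames with
R² ≥ 0.99 (the window therefore stops where substrate depletion bends the
trace); if no prefix qualifies the first 4 frames are used and the result is
flagged.  Beer–Lambert conversion uses ε672 = 69,950 M⁻¹ cm⁻¹ and 1 U =
1 µmol product min⁻¹; specific activity is U per mg enzyme.  Note that a
pulsed protocol dilutes the intrinsic rate by the duty cycle
(pulse/(pulse+dark)); the generator reports both wall-clock and
per-light-minute slopes.

Condition profiles (pH, temperature) are summarised by the argmax (ties →
midpoint of the tied set) and by the total width over which the
piecewise-linear interpolant stays at or above 80 % of the maximum; ranges
touching a profile boundary are flagged as truncated.  Monovinyl/divinyl
substrate preference uses the fold-difference max/min, rounded half-up to
one decimal for reporting, with a preference called when the unrounded fold
exceeds 1.5.  Published one-decimal activity tables are arithmetically
consistent with this rule for most but not all columns — the remaining
columns were evidently computed from unrounded replicates, so the package
makes no attempt to reproduce them from rounded inputs.

## Melting temperatures (`dsf`)

T_M is the temperature of the maximum of the first derivative of the
F350/F330 fluorescence ratio.  The ratio is smoothed with a degree-2
Savitzky–Golay filter (default window 9 points) whose analytic derivative is
used directly; the grid argmax is refined by a parabola fitted over the
upper half of the derivative peak (at least ±window points).  A 3-point
parabolic interpolation would not average noise at the instrument's
~0.028 °C step (0.5 °C/min ramp sampled 18×/min), which is why the wider
vertex fit is used; on noiseless sigmoids both agree to < 0.05 °C.  A trace
whose derivative maximum does not stand 5 robust standard deviations
(1.4826·MAD) above the median derivative raises a no-transition error.
T_M is invariant to scaling both channels and to additive linear baselines.

## AAPB classification (`markers`)

A genome is called (putative) AAPB iff it has all three DPOR subunits
(BchB ∧ BchL ∧ BchN), both type-II reaction-center subunits (PufL ∧ PufM),
at least one cyclase (AcsF ∨ BchE), and lacks RuBisCO and/or PRK, i.e. is
disqualified only when both Calvin markers are present.  The "and/or"
reading of the Calvin clause is the default; a strict variant requiring both
absent is selectable.  RC II requires both subunits because both are used as
markers.  Marker presence: at least one profile-HMM hit meeting the model's
trusted cutoff (a bit score — curated trusted cutoffs are bit scores, not
E-values); models without a curated cutoff fall back to E ≤ 1e-5.
Provenance per cell records the best qualifying hit.  Running the external
search engine is out of scope; the package consumes its tabular output
(parsed with Biopython's hmmer3-tab reader) or precomputed matrices.

## Tree support and consensus (`trees`)

Trees are unrooted for all topology operations (rooted input loses its root
edge on load).  A label set is monophyletic in a tree iff it is one side of
an edge bipartition; bipartitions are canonicalised as the side not
containing the lexicographically smallest leaf.  The majority-rule consensus
contains exactly the nontrivial bipartitions occurring in strictly more than
the threshold fraction (default 0.5) of trees; for thresholds ≥ 0.5 the
retained splits are pairwise compatible and form a laminar family, from
which the consensus tree is built directly, with frequencies as internal
node labels.  Ties are excluded (strict majority).  Multifurcations beyond
what majority rule produces are not resolved further.  The bipartition
extraction and consensus are independent code, cross-checked in tests
against exhaustive split enumeration on all unrooted topologies with up to
7 leaves and against dendropy's consensus.

## SAXS and sequence utilities (`biophys`)

Mass rules: MW(Da) = V_Porod/1.7 and MW(Da) = V_excluded/2 (the latter for
averaged, filtered dummy-atom models).  The Guinier fit of ln I vs q²
iterates window selection (q·Rg ≤ 1.3, the convention for globular
proteins) to a fixpoint, then (a) flags and excludes leading points that
rise systematically (> 2 SD) above a fit made without them — the
aggregation signature — and (b) shrinks the window while systematic
curvature dominates point-to-point noise (RMS residual > max(2× high-
frequency noise, 1e-4)), so exact Guinier data keep the full window
(recovery to 1e-6 relative) while a sphere form factor is fitted only where
the approximation holds (≤ 1 % error against Rg = √(3/5)·R).  ε280 and
average molecular mass come from amino-acid composition (5500·nTrp +
1490·nTyr, plus 125 per cystine when the oxidised convention is selected;
the all-reduced convention is the default because assay buffers are
reducing).  Porod/excluded volumes are inputs, not computed from profiles.

## Synthetic data (`simulate`)

The generators emulate, with known ground truth:

* **Titrations** — Gaussian Q_y bands: free pigment at 630 nm (σ 9 nm,
  0.030 AU/µM ≈ ε 3.0e4 M⁻¹cm⁻¹), bound band red-shifted +8 nm (a
  resolvable shift of typical magnitude; the true value is not published and
  is configurable); scatter a·λ⁻² with a = 50 AU·nm² per µM protein (1e4 at
  the 200 µM endpoint, a few hundredths of an AU); grid 620–720 nm at 1 nm;
  Gaussian noise 0.002 AU (typical absorbance noise of a bench
  spectrophotometer at these optical densities).  Bound fractions come from
  the brute-force equilibrium solver, independent of the closed form under
  test.
* **Time courses** — 1 s light / 11 s dark cycles (6 s/18 s for weak
  enzymes), Beer–Lambert product absorbance, +0.5 AU broadband artifact on
  frames overlapping a pulse, hard saturation after a configurable converted
  fraction (default 50 %).
* **DSF traces** — two-state logistic in F350/F330 with inflection exactly
  at T_M, width 1.5 °C (≈ 120 kcal/mol unfolding enthalpy for a mid-40s °C
  transition), baselines 0.8/1.3, ratio noise 3e-4 (nanoDSF optics are far
  quieter than absorbance measurements).
* **Marker tables** — AAPB-patterned, oxygenic-patterned (both Calvin
  markers and photosystem genes present) and non-phototroph rows, with
  labels retained.
* **Tree sets** — random topologies by sequential joining with a chosen
  clade monophyletic in exactly round(frequency·n) trees; the remainder
  break it by swapping one clade leaf with an outsider (which provably
  destroys monophyly whenever ≥ 2 taxa lie outside the clade).

RNG contract: all draws come from numpy's `default_rng` (PCG64), seeded per
call; identical seeds give identical output across platforms.  The CLI fans
a single seed out to per-stage `SeedSequence` substreams so adding a stage
never perturbs another stage's draws.

What the generators do *not* emulate: instrument drift, wavelength
miscalibration, correlated (pink) noise, photophysics of the catalytic
cycle, non-two-state unfolding, draft-genome marker fragmentation, and
branch-length/rate heterogeneity in trees.  Recovery results on synthetic
data therefore demonstrate correctness of the estimators under the stated
models, not robustness to every real-world artifact.

## Problem sizes and verification

The test-suite and the reproduction script run the titration recovery at
4 noiseless + 100 noisy replicates (41 spectra × 101 wavelengths each), the
melting-point recovery at 2 × 50 seeds (2520-point traces), the AAPB rule
over all 512 relevant marker patterns plus 1000 simulated genomes, tree
support over 100-tree sets of 20 taxa plus exhaustive topology enumeration
to 7 leaves, and the binding-curve/solver comparison over ~1e4 parameter
points.  These sizes were chosen to estimate medians and worst cases
stably while keeping a full run in seconds.

## Known limitations

* The Kd fit assumes one binding site and a common S0/Smax across the
  series; cooperative or multi-site binding is out of scope.
* The published "±" uncertainties on Kd may be replicate standard
  deviations; the package reports asymptotic standard errors, which need
  not match them.
* The fold-difference arithmetic reproduces published values only where the
  printed one-decimal activities are self-consistent (see above).
* The initial-rate window rule ("longest prefix with R² ≥ 0.99") is one
  reasonable operationalisation of "initial linear rise"; window indices
  and a fallback flag are reported so users can audit it.
* Whether the derivative-peak or a fitted two-state midpoint was reported
  by the original DSF software is unknowable from the traces; the package
  reports the derivative peak, which differs slightly for sloped baselines.
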