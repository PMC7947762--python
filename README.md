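# lporlab

Analysis toolkit for the biochemistry of **light-dependent
protochlorophyllide oxidoreductases (LPORs)** and the genomics of **aerobic
anoxygenic phototrophic bacteria (AAPB)**.  LPOR is a single-subunit,
NADPH-dependent photoenzyme that reduces protochlorophyllide (Pchlide,
Q_y ≈ 630 nm) to chlorophyllide (Chlide, Q_y ≈ 672 nm) only under
illumination; its recently recognised presence in AAPBs raises questions —
how tightly do these enzymes bind their substrate, how active and how
stable are they, and which genomes qualify as AAPB at all — that this
package answers quantitatively from standard lab and bioinformatics data.

It is aimed at protein biochemists and microbial genomicists who have
spectrophotometer exports, nanoDSF traces, HMMER search tables or newick
tree sets and want the corresponding derived quantities with tests and
provenance.

## What it computes

**Dissociation constant of the ternary LPOR·NADPH·Pchlide complex.**
A fixed pigment concentration [B] is titrated with apo-protein [A]; each
UV-Vis spectrum is unmixed into free and bound pigment plus a turbidity
baseline a·λ⁻² + y0, and the mole-fraction profiles are globally fitted
(Levenberg–Marquardt) to the ligand-depletion (Morrison) binding curve

    x_AB([A]) = S0 + (Smax − S0) · (K_d + B + A − √((K_d + B + A)² − 4AB)) / (2B)

with a shared K_d.  The initially unknown bound-pigment spectrum is taken
from the highest-protein spectrum and iteratively purged of its free-pigment
contamination (estimated from the fitted plateau) until K_d converges.

**Photoconversion kinetics.**  Pulsed-illumination A672 time courses are
filtered for illumination artifacts; the initial linear rise gives the
velocity, converted by Beer–Lambert (ε672 = 69,950 M⁻¹cm⁻¹) to µM/min and
specific activity (1 U = 1 µmol/min).  Includes pH/temperature optimum
profiles with the 80%-of-maximum range, the >1.5 fold-difference rule for
monovinyl vs divinyl substrate preference, and the in vivo
bacteriochlorophyll index OD860/OD660.

**Melting temperatures.**  T_M as the peak of the first derivative of the
nanoDSF F350/F330 ratio, with Savitzky–Golay smoothing and sub-grid peak
refinement.

**AAPB classification.**  Marker presence/absence matrices from HMMER
tblout (trusted bit-score cutoffs) and the rule: DPOR subunits
BchB ∧ BchL ∧ BchN, RC II PufL ∧ PufM, cyclase AcsF ∨ BchE, and not
(RuBisCO ∧ PRK).

**Tree support.**  Clade frequency ("monophyletic in 83 of 100 trees") and
majority-rule consensus with per-clade support over newick tree sets.

**SAXS & sequence utilities.**  Molecular mass from Porod volume (/1.7) and
excluded volume (/2), Guinier R_g (iterative q·R_g ≤ 1.3 window), and
composition-based ε280 / molecular mass.

Every input class has a synthetic generator with known ground truth
(`lporlab.simulate`), so the whole pipeline is testable end to end without
instrument data.

## Worked example

Simulate a titration at the standard design (2 µM pigment, 0–200 µM
protein, true K_d = 40 µM) and fit it back:

```bash
lporlab --seed 7 --outdir run simulate --preset titration --true-kd 40
lporlab --seed 7 --outdir run fit-kd run/titration.csv run/titration.meta.json
```

which prints

```
Kd = 40.6 µM (+/- 1.7)
```

and writes `run/kd_fit.json`:

```json
{
  "kd_uM": 40.566108214044725,
  "kd_se_uM": 1.6877778513458346,
  "s0": 0.02410122054072424,
  "smax": 1.0000000961914077,
  "contamination": 0.14157264373468859,
  "rounds": 3,
  "converged": true
}
```

The fitted K_d (40.6 ± 1.7 µM) recovers the configured 40 µM within the
noise of the simulated spectra (0.002 AU).  `contamination` is the free-
pigment fraction that the refinement removed from the initial bound
reference (for K_d = 40 µM about 17 % of the pigment is still unbound at
the 200 µM endpoint, so the first bound-spectrum guess is impure by
construction).  `smax ≈ 1` confirms the refinement converged to pure
species spectra, and `run/mole_fractions.tsv` holds the free/bound
profiles on [0, 1].

The same pattern works for the other stages (`simulate --preset
{kinetics,dsf,markers,trees}` followed by `activity`, `dsf`,
`classify-genomes`, `tree-support`), and `saxs-mass` / `protparams` operate
directly on `.dat` / FASTA files.  The library API mirrors the CLI
one-to-one (`lporlab.binding.fit_kd_global`, `lporlab.dsf.melting_temperature`,
...).

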