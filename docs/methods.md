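# Methods

`triazopep` models a family of branched peptidomimetic inhibitors of the
neuropilin-1/VEGF-A165 interaction in which 1,4-disubstituted
1,2,3-triazole rings replace selected backbone amide bonds.  This note
documents the chemical model, the descriptor and regression definitions,
the bioassay arithmetic, the synthetic-data generators, and the design
choices made where the underlying study left the procedure open.

## Chemical model

### Blocks and formulas

Every compound is a chain of registered blocks — standard alpha amino
acids (Gly, Ala, Pro, Phe, Lys, Arg), guanidinylated residues (Har =
homoarginine), shortened diamino acids (Dab, Dap), omega amino acids
(6Ahx, 5Ava), the glycyl-triazole unit `GlyΨ[Trl]`, and the Fmoc cap.
Formulas use the dehydrated residue convention: the molecular formula is
the sum of residue formulas plus one H2O; an Fmoc cap contributes a net
C15H10O2 (its C15H11O2 carbamate/fluorenyl fragment replaces one hydrogen
of the capped amine).  Stereo flags (`D-`) never change composition.

### The glycyl-triazole unit

The unit descends from the synthesis route: the backbone amine of the
growing peptide is converted to an azide (diazotransfer), then
cycloaddition with an Fmoc-propargylamine alkyne closes a
1,4-disubstituted 1,2,3-triazole.  Consequences encoded in the model:

* the unit's fragment is N_am–CH2–C4 with ring C4–C5–N1–N2–N3; the azide
  nitrogen becomes ring N1;
* N1 **is** the backbone nitrogen of the following residue.  At assembly
  the following block's own N atom is merged into N1 (carrying no
  hydrogen), which is why the unit's residue formula is C3H3N3 despite
  the fragment holding four nitrogens;
* a unit cannot open a chain (its amide N must be acylated), cannot end a
  chain or stand as a branch (N1 would dangle and the molecule would lack
  its carboxyl terminus), and cannot precede proline (a secondary amine
  cannot be converted to the ring azide).  The first restriction is
  enforced at parse time, the others when a formula or graph is built.

The last restriction was found by the package's own cross-check: the
additive and graph formula routes disagreed by one hydrogen on
`…GlyΨ[Trl]Pro…`, which is precisely the signature of a ring closed from
an amine with no hydrogen to give up.

### Termini, branches and validation

Free backbone amines gain one hydrogen over the mid-chain state; the
C-terminal acyl carbon gains a hydroxyl; a branch (Har acylating the
side-chain amine of Lys/Dab/Dap) removes one hydrogen from that amine.
Monoisotopic masses use lightest-isotope atomic masses (H 1.0078250319,
C 12, N 14.0030740052, O 15.9949146221) and a proton mass of 1.007276 Da;
reported m/z is rounded half-up to 4 decimals, and comparisons against
printed values use |Δ| ≤ 0.00005.

The whole chemistry layer is validated against the shipped 23-compound
characterized panel: all 23 printed formulas are reproduced by both
formula routes, and 22 of 23 printed calculated m/z values match to 4
decimals.  The one remaining row (compound 23) is an internal misprint
of the source table: its printed formula C19H34N14O3 implies
[M+H]+ = 507.3011, which equals the row's printed *measured* value,
while the printed *calculated* value (507.3020) matches no mass
convention; the package reports the arithmetic truth and the validation
report flags the row.

## Descriptors

* **dis_N-C** — number of heavy atoms strictly between the two guanidine
  carbons (Har and Arg) on a bond path.  Two conventions are exposed:

  * `ring_side="nitrogen"` (default): paths traverse each triazole ring
    on its N1–N2–N3 edge.  This is the convention under which both
    published models are reproduced at printed precision, and it is the
    natural one for a chemist tracing the drawn backbone through the
    ring's nitrogen side.
  * `ring_side="shortest"`: unconstrained BFS, which crosses each ring
    via C5 (one bond fewer per ring).

  The *counting* convention (`count="atoms_between"` vs `"bonds"`) is an
  affine, panel-wide shift and provably irrelevant after normalization
  (asserted by test).  The ring-side choice is **not** affine — it scales
  with the number of rings on the path — and is the one structural
  convention that matters for the models; both are therefore implemented
  and the default is the model-reproducing one.
* **dis_N-C,norm** — min–max normalization over the analyzed panel
  (smallest value 0, largest 1).  A degenerate panel (max = min)
  normalizes to 0 and is flagged.
* **2Trl_C-N** — 1 if the second backbone linkage counted from the
  C-terminus is a triazole junction (the junction *out of* a unit; the
  amide *into* a unit's N_am counts as an amide).
* **am_2N** — 1 if a residue flanking the second backbone linkage counted
  from the N-terminal end bears a free, uncapped alpha-amine.  When the
  first main-chain residue carries the arm, the count starts at the arm
  residue, so linkage 1 is the side-chain amide.  Side-chain amines (the
  epsilon-amine of a backbone lysine) and omega-amino acids do not
  qualify.  This rule needs no per-compound exceptions: it assigns the
  Fmoc-armed compounds 1 (their lysine alpha-amine is free) and the
  backbone-lysine compound 0, the unique assignment under which the
  published three-variable equation is reproduced.  An explicit override
  column is still accepted for sensitivity analyses.

## Regression models

Plain OLS with classical standard errors
(SE(β_j) = √(σ̂²·[(XᵀX)⁻¹]_jj), σ̂² = RSS/(n−p−1)) — the estimator a
spreadsheet regression produces, matching the source analysis.
Implementation is statsmodels; tests require agreement with an
independent normal-equations oracle to 1e-10.  Exactly collinear designs
are refused with the dependent columns named; under-determined fits
(n ≤ p+1) are refused.

On the reconstructed 23-compound matrix:

* Model 1 (inhibition on raw distance): R² = 0.54;
* Model 2 (normalized distance + am_2N + 2Trl_C-N): coefficients
  8.6 (±5.0), 20.9 (±8.6), 8.7 (±4.5), 8.6 (±4.6), R² = 0.63 —
  the published equation at printed precision.

`best_subset` enumerates all column subsets up to `k_max` and ranks by
adjusted R² (the "fit quality vs number of variables" criterion made
explicit), with ties — e.g. between affinely identical raw- and
normalized-distance models — broken deterministically by subset size and
column order.

## Bioassay arithmetic

* **Percent inhibition**: inh = 100 − (S − NS)·100/(Pmax − NS); undefined
  when Pmax = NS, 0% at S = Pmax, 100% at S = NS, invariant under joint
  affine rescaling of all three signals.  (The source footnote reuses one
  symbol for both the percent and the maximum binding signal; this is the
  only reading under which S = Pmax gives 0%.)
* **Replicates**: mean ± sample SD (n−1); a single value leaves the SD
  undefined rather than zero.
* **Dose–response**: inh(c) = 100/(1 + 10^{h·(logIC50 − log₁₀c)}),
  rising to 100% at saturating inhibitor.  The Hill slope h is fit
  (initialized at 1) or fixed to 1; at least four distinct concentrations
  are required; SEs come from the Jacobian at the optimum (scipy
  `curve_fit`); R² is computed on the inhibition scale.  IC50 in µM is
  10^(logIC50+6), reported to 2 decimals (−5.076 → 8.39 µM).
* **Stability decay**: f(t) = 100·exp(−kt) by least squares with k ≥ 0;
  t½ = ln2/k.  If the fitted decline over the observation window is
  below a resolution threshold (default 10 percentage points), the series
  is censored and t½ reported as a lower bound at the window end — the
  honest summary for compounds that out-live the experiment (the study's
  48 h window, sampled every 8 h).

## Synthetic data

The study's raw plate signals, dose–response curves and stability series
were never deposited, so seeded generators emulate them with the
statistical structure the analysis assumes — additive Gaussian noise
around the respective model expectation in every case, since only means
± SD are reported and nothing richer is inferable:

* **Panels**: sequences sampled from the notation grammar (arm ∈
  {Lys(Har) and stereo variants, Dab(Har), Dap(Har), backbone-Har arms},
  linkers of 1–3 blocks with configurable triazole placement probability,
  C-terminal Arg), constrained to synthesizable chemistry.  Default size
  23, the study's panel size.
* **Activities**: linear predictor from the published coefficients
  (8.6, 20.9, 8.7, 8.6) plus N(0, σ) noise, clipped to [0, 100] with clip
  flags.  The default σ = 7.86 percentage points is the residual SD of
  the three-variable model refit on the real panel (RSS/(n−4) with
  n = 23), calibrated once and recorded here; it puts synthetic refits in
  the observed R² ≈ 0.63 signal-to-noise regime.
* **Plates**: S = NS + (Pmax − NS)(1 − inh/100) + noise (defaults
  NS = 0.05, Pmax = 1.0, σ = 0.02 absorbance-like units, triplicate).
* **Curves**: default logIC50 = −5.076 (the best compound), half-log
  concentration grid 0.1–300 µM, σ = 5 percentage points.
* **Decay**: default 0–48 h every 8 h (the study's schedule), σ = 2
  percentage points.

What passing the synthetic tests shows: the estimators recover their own
generating models (exactly at σ = 0; within ~3 SE with ~95% two-SE
coverage at stated noise).  What it does not show: anything about plate
artefacts, non-Gaussian error, Hill slopes far from 1, multi-phase
degradation, or any other structure real raw data might contain — none
of which is observable from the published summaries.

## Problem sizes and numerics

Tests and the acceptance script run the real 23-compound panel end to
end; simulation-based checks use 200–500 seeds, sizes at which the
binomial noise on a 95% coverage estimate (±~2–3 percentage points) is
well inside the asserted bands.  Optimizer defaults: dose–response and
decay fits start from the median log-concentration / k = 0.01 h⁻¹ with
up to 20000 function evaluations; flat decay series short-circuit to
k = 0.  Reported rounding is centralized: 4 dp for m/z (half-up), 1 dp
for inhibition and coefficients, 2 dp for R² and IC50.

## Known limitations

* The study's own descriptor appendix is not public; the matrix here is
  reconstructed from the stated definitions and validated by reproducing
  both regression models at printed precision.  The reconstruction, not
  the original matrix, is the package's ground truth.
* Only C/H/N/O chemistry is registered — sufficient for the panel's
  block set; new blocks (e.g. sulfur-containing residues) would need
  registry and mass-table entries.
* No 3D structure, conformers, protonation states or isotope patterns
  beyond the monoisotopic peak; the geometric consequences of the
  triazole replacement are outside scope.
* The decay model is single-exponential by construction; it summarizes,
  not discovers, degradation kinetics.
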