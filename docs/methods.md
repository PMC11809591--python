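# Methods

`posiso` computes carbon-positional ¹³C fractional enrichments and molar
assimilation rates of 3-phosphoglycerate (3PGA) from GC-MS in-source fragment
isotopologue measurements. This note documents the models, the numerical
choices, what the synthetic generator does and does not emulate, and the known
limitations.

## The measurement model

A TMS/MEOX-derivatized metabolite ion carries two kinds of carbon: *labelable*
carbons inherited from the parent metabolite and *derivatization* carbons from
the silyl/methoxyamine moieties, which are never tracer-labeled. The observed
isotopologue abundance vector of a fragment is modeled as the convolution of

1. the tracer-label count distribution over the labelable carbons, where a
   tracer-derived position carries ¹³C with probability equal to the tracer
   purity (default 0.99, the purity of the ¹³CO₂ used for the pulse) and an
   ambient position carries ¹³C at the natural abundance (default 1.109 %,
   configurable in `chem.isotope_table`);
2. the natural-abundance isotope patterns of the derivatization carbons and of
   all non-carbon elements (H, N, O, P, Si; masses from AME2020, abundances
   from IUPAC representative values).

Silicon matters: TMS fragments have ~8 % combined ²⁹Si/³⁰Si per Si atom, so
the natural M+1/M+2 of a 3-Si fragment rivals genuine single-label signal.
The correction therefore supports a `full` resolution mode (all elements,
default) and a `carbon_only` mode for high-mass-resolution data in which
Si-driven isotopologues are mass-resolved away from ¹³C shifts. On unlabeled
Si-rich fragments, `carbon_only` applied to nominal-mass data overestimates
enrichment — the package tests pin the sign of that difference.

## NIA/tracer-purity correction

Column *j* of the correction matrix is the theoretical observed pattern of a
species with exactly *j* tracer-derived labels. The matrix is rectangular:
measured windows longer than n+1 channels (recommended for TMS fragments) are
kept as extra rows and the system is solved in the least-squares sense. The
default solver is non-negative least squares; an unconstrained solve with
clipping is available for speed. NNLS is the default because small negative
components arise from noise, and clipping after an unconstrained solve biases
enrichment near the 0 and 1 boundaries.

Outputs per measurement: the corrected label-count vector, the relative
isotopologue abundance (RIA, normalized to 1), the corrected total (the
label-invariant quantifier used for concentrations), and the fractional
enrichment E¹³C = Σᵢ i·xᵢ / (n·Σᵢ xᵢ), the average ¹³C fraction per labelable
carbon. Correctness is tested against an independent isotope-assignment
enumeration oracle (exact within an 8-channel window, 1e-10) and by
forward-model inversion round trips.

Validated abundance windows per fragment/instrument are enforced by
`validity_range_check`: below the window the additive noise floor inflates
E¹³C (the generator reproduces this), above it detector saturation distorts
the leading isotopologues. Flagged samples are excluded from enrichment
outputs.

## Positional algebra

The enrichment of a substructure is the average over its carbon positions, so
with the complete-backbone feature (fragment 459, 1,2,3-C₃) and the in-source
fragment retaining 2,3-C₂ (fragment 357):

    E1 = 3·E123 − 2·E23
    rel.E(%) = E23/E1 × 100
    C¹³C₁₂₃ = 3·E123·C₃PGA,  C¹³C₂₃ = 2·E23·C₃PGA,  C¹³C₁ = 1·E1·C₃PGA

Design choices:

- **Carbon-count weighting** of molar ¹³C concentrations (×3/×2/×1). The
  weighting is forced by additivity — C¹³C₁₂₃ = C¹³C₁ + C¹³C₂₃ must hold
  exactly, since the complete molecule is the union of its positional groups.
  A per-position-average convention is switchable but breaks additivity.
- **Out-of-range E1** (possible from noise, since E1 is a difference) is
  flagged and excluded from rate fits, never clamped: clamping would bias
  early-time points toward zero. A tolerance of 1e-12 absorbs solver float
  dust. Flagged *t = 0* samples are a special case: they are pre-pulse, their
  molar ¹³C is zero by definition, so rate fits keep the time point at 0
  instead of dropping the pulse start.
- **rel.E denominator**: below E1 = 0.01 the ratio is reported as an
  undefined marker (NaN), not 0 or infinity — pre-pulse samples have E1 ≈ 0
  and the ratio is meaningless there. During photosynthetic pulse labeling
  rel.E cannot exceed 100 % (the 1-C carboxyl position assimilates first);
  values above 100 % raise a data-quality flag, the signature of
  nominal-mass-resolution bias.

## Absolute quantification

The quantifier is the NIA-corrected isotopologue sum of fragment 357 — label
invariance of the corrected sum (tested to 0.5 %) is what licenses one
calibration across a labeling time course. Samples and calibration standards
are both normalized to the ¹³C₆-sorbitol internal standard so the
normalization cancels. The calibration line is ordinary least squares inside
a linear range; automatic range detection selects the longest contiguous
amount window whose log-log slope is within 1 ± 0.1 *and* whose per-level
log residuals stay below 0.2 — the second condition is needed because a
window that sneaks one saturated level past the slope test otherwise wins on
length. A user-declared range always overrides.

ng → nmol·OD₇₅₀⁻¹·mL⁻¹ conversion uses the free-acid molar mass of 3PGA
(186.06 g/mol) with explicit, overridable factors for reference-substance
purity and extraction-volume bookkeeping, since the full conversion chain of
a given laboratory protocol is instrument- and protocol-specific.

## Kinetics

Molar ¹³C time courses (grid 0/5/10/15/30/60 min; later points are kept for
plots but excluded from fits) are fitted per replicate culture with the
logistic I(t) = i_max/(1+exp(−a(t−t_mid))), whose maximum slope — the
assimilation rate A¹³C — has the closed form i_max·a/4 at t_mid. Replicates
are aggregated afterwards (mean ± SE), not pooled before fitting.

- **Multi-start**: 1,000 seeded random initializations inside data-driven
  bounds are screened by penalized SSE; the best eight plus a data-driven
  start are polished by bounded least squares and the lowest SSE wins.
- **t₀ constraint**: the pre-pulse intensity must be ~0; since a logistic
  never reaches 0, this is a soft penalty on I(0) > 0.05·i_max.
- **Identifiability cap**: fitted steepness is bounded by 2·ln 19 divided by
  the smallest sampling interval — a logistic whose 5–95 % rise fits inside
  one sampling gap is indistinguishable from a step, and without the cap the
  optimizer escapes into step-like minima whose maximum slope is arbitrary.
  With the cap, the median replicate-triplet error of A¹³C at 10 %
  multiplicative noise is ~0.09–0.12 for courses with midpoints at 5.4–8.4
  min; steeper courses (a ≈ 1/min) approach the identifiability edge and
  degrade to ~0.16–0.20 (measured envelopes, asserted in the tests).
- **Classification**: `sigmoidal` requires convergence, data reaching 0.75 of
  the fitted plateau (threshold intensity ratio), the plateau being reached
  inside the observation window (≥ 0.95·i_max at the last time point — this
  is what rejects plateau-free ramps), and the t₀ constraint. Zero series are
  `no_signal`; everything else `ambiguous`.
- The exponential alternative I(t) = i_max(1−e^(−kt)) with initial slope
  k·i_max is provided for comparison; it cannot represent the lag phase
  caused by Ci diffusion and CBB-cycle redistribution, so the logistic is
  the default rate estimator.

Group comparisons use the heteroscedastic two-tailed Welch t-test with the
conventional star notation (≤0.05/≤0.01/≤0.001); the implementation is
cross-checked against a hand-computed example and a permutation test.

**Not-detected rule**: a positional signal counts as detected only if its
late-course plateau enrichment exceeds the pre-pulse blank mean by three
times the measurement scatter (the larger of blank SD and plateau SD — a
blank-based limit of detection). Undetected channels are reported with the
explicit `n.d.` sentinel, distinct from 0 and from missing.

## Carbon-fate maps

Steady-state positional predictions for glucose feedings use atom-level fate
maps: EMP glycolysis (glucose carbons 3/4 → 1-C, 2/5 → 2-C, 1/6 → 3-C of the
two 3PGA products) and the oxidative PPP (1-C of G6P decarboxylated; 3 G6P →
5 3PGA, three products carrying (4,5,6) and two transketolase/transaldolase
rearrangement products with G6P 2-C and 3-C at their 1-C positions). Only the
1-C sources of the two rearranged products are fixed by the stated
stoichiometry; their 2-C/3-C sources are completed from the canonical
non-oxidative PPP fate map, drawn from the rearranged 2-C/3-C pool — this
completion is a derivation, serializable and user-overridable, and is
irrelevant for enrichment-level predictions (it would matter only for
isotopomer-level ones). Pathway pools are mixed by molar 3PGA yield per
consumed glucose (2 for EMP, 5/3 for OPP) times the flux fraction, because
enrichment is a property of the 3PGA pool; raw-flux weighting is switchable
and differs little at realistic OPP fractions (~0.11). The RuBisCO map
(CO₂ → 1-C of one of two products; RuBP 1,2-C₂ mapping inversely to 2,3-C₂)
provides the photosynthetic interpretation. Dynamic G6P-pool dilution is not
modeled; experiments normalize via the measured-reference adjustment
(`adjust_to_reference`) instead.

## The synthetic generator

The generator replaces instrument files and defines the conditions under
which the pipeline is validated:

- **Truth courses**: E1(t) logistic; E23(t) a delayed logistic with the same
  steepness, scaled by an anaplerotic plateau ≤ 1 (ambient-carbohydrate
  mobilization keeps rel.E below 100 % at steady state); E123 is the
  positional average by construction. Equal steepness with delayed midpoint
  is required for a physically consistent rel.E course (monotone rise from
  ~0 toward the plateau, never above 100 %). The t = 0 sample is pre-pulse
  and exactly zero; steepness therefore satisfies I(0) ≤ 1 % of plateau
  (a·t_mid ≥ ln 99).
- **Presets** parameterize wild-type-like, Δgapdh1-like (delayed midpoints)
  and Δgapdh2-like (no 2,3-C₂ labeling, delayed and reduced 1-C assimilation,
  low 3PGA pool) kinetics under steady-state (HC-HC) and shift (LC-HC)
  regimes, with midpoint times anchored at the reported phenotypes (5.4/8.4
  and 6.1/8.8 min; ~1.9× delayed Δgapdh2 1-C under HC). Plateaus and pool
  concentrations are illustrative, chosen once so that wild-type A¹³C lands
  near 0.33 and Δgapdh2 near 0.02 nmol·OD₇₅₀⁻¹·mL⁻¹·min⁻¹.
- **Emission**: positional truths are composed position-independently into
  fragment label-count distributions (the positional-isotopomer joint is
  unidentifiable from the two measured fragments; independence is the
  maximum-entropy completion and is exactly consistent with the positional
  averaging algebra), pushed through the same forward model the correction
  inverts, scaled by a linear detector response and internal standard,
  and degraded with per-channel log-normal noise (default 10 %), an additive
  floor, and a saturation ceiling. The floor is what reproduces the
  enrichment inflation below the validated abundance window.
- **Instrument bias**: nominal-mass (EI-like) detection is emulated as a
  constant relative spectral floor in every channel, which mechanically
  inflates low enrichments and deflates high ones; high-resolution
  (APCI-like) mode is near-unbiased (<0.002).
- **Determinism**: a single seeded generator drives every draw; identical
  seed and configuration give byte-identical tables.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: chromatographic co-elution and matrix interference,
retention-time drift, derivatization-incomplete species, deuterium exchange,
correlated (non-independent) channel noise, and positional isotopomer
correlations within a molecule. Real-sample validation still requires the
case-by-case abundance-window and qualifier-correlation checks the package
provides.

## Problem sizes

The shipped validation suite uses desk-scale problem sizes chosen to exercise
every code path: 3 replicates × 7 time points × 2 fragments per pipeline run,
200 seeded replicate-triplet simulations for rate-recovery statistics, and
10,000 time points for the rel.E bound. The whole suite runs in well under
two minutes on one CPU.

## Known limitations

- E1 is a difference of two measured enrichments; its noise is ~3.6× the
  per-fragment noise, and the package propagates rather than suppresses this
  (flags, no clamping).
- Steepness (hence A¹³C) is weakly identified when the logistic midpoint sits
  within one sampling interval of the transition; the identifiability cap
  makes the estimate stable but cannot create information the grid does not
  contain. Midpoint times are robust (±1 min at 10 % noise).
- The OPP rearrangement completion and the anaplerotic plateau values are
  documented conventions, not measurements.
- No mechanistic fragmentation prediction: the fragment library records which
  ions exist and which positions they retain; users extend it via TSV.
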