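# Methods

This note documents the models, defaults and numerical choices behind
`commrobust`, and what the synthetic study can and cannot show about real
communities.

## Study layout

The community has nine members inoculated at equal optical density
(0.05 OD₆₀₀ each, 0.45 total), grown statically for 72 h. The design set
is: the full mix, nine single-species dropouts, nine monocultures — 19
designs, enumerated in reporting order (mix, dropouts, monocultures).
Dropouts and monocultures are distinct *roles* even when membership
coincides (the two-species edge case), because downstream statistics
group by role. Single absences only: multi-species (leave-k-out) designs
are outside the study's scope.

Inoculum arithmetic: CFU/ml = OD × CFU-per-OD. The default CFU-per-OD is
2×10⁹ for all members except *C. gleum*, which sits 0.4 log₁₀ below the
others' mean — so 0.05 OD corresponds to ~1×10⁸ CFU/ml.

## Assay conversion

Colorimetric substrates (NPB, NPP, NPPC) release nitrophenol, read as
A410. Blank-corrected deltas convert by Beer–Lambert with
ε = 17,700 M⁻¹cm⁻¹. The optical pathlength of a plate-reader well is not
a chemical constant; it defaults to 1.0 cm and is the dominant systematic
unknown when comparing absolute activity scales across instruments, which
is why absolute monoculture activities are generator parameters rather
than anchored values. The canonical internal unit is molar-based
(nmol·ml⁻¹·min⁻¹·OD₆₀₀⁻¹); mass-based views (ng, µg) multiply by the
nitrophenol molecular weight (139.11 g/mol) and are derived only —
mass-based "PLC units" are ambiguous about whose mass is meant, so the
molar unit is authoritative internally.

Negative blank-corrected signals are clipped to zero with a warning
rather than raising: assay noise makes small negatives routine. Protease
uses each sample's t=0 autofluorescence as its baseline; colorimetric
classes use a substrate-only blank. Percent lysis is reported unclipped
with an out-of-range flag, since supernatant components can destabilize
liposomes beyond either control.

## Differential plating and deconvolution

Growth scores (none / slow / normal) per (species, temperature ×
supplement) come from the packaged susceptibility table. For signature
construction, *slow* counts as no-growth by default — slow growers form
colonies under half normal size and are conservatively assumed unscored —
with a flag to include them. *P. myrsianacearum* is encoded as no-growth
at 37 °C without selection (it grows exceedingly slowly there).

The default panel is no-selection, gentamicin-25 and trimethoprim-100 at
30 and 37 °C plus cetrimide-200 at 37 °C, combined with colony classes
(orange *C. gleum*, yellow Sphingomonads, rough-edged *R. insidiosa*,
white/beige otherwise). The cetrimide plate — on which only
*B. multivorans* grows — is load-bearing: without it the two
gentamicin-resistant white species (*C. metallidurans*,
*B. multivorans*) have identical signatures. Cetrimide is the selective
agent of Pseudomonas Isolation Agar, so a PIA plate and the cetrimide
column are treated as equivalent.

Deconvolution assumes every plate received the same sample volume (up to
recorded dilution factors). Then each (condition, colony-class) cell
count estimates the summed reference-volume count of its species, giving
an overdetermined linear system solved by non-negative least squares,
normalized to proportions. This volume-consistency assumption is what
makes one-species plates informative: a within-plate-ratio formulation
would discard them and lose identifiability. Standard errors are
multinomial at the panel's total counting depth; dilution factors scale
counts Poisson-style. The NNLS non-negativity constraint biases very
rare species (~1% at 500 colonies/plate) upward by well under one
percentage point — measured by Monte-Carlo in the test suite; solved
counts inconsistent with the phenotype matrix (relative residual > 0.25)
raise rather than silently fitting.

## Diversity indices

Inputs are renormalized to sum to one before any index (printed percent
tables carry rounding error; columns summing to 99.8 are expected), zeros
are dropped, richness counts detected species only, and Shannon is
natural-log with no base option. Note the Simpson λ = Σp² of the packaged
full-mix composition is ≈0.17 and of the eight-member community ≈0.20;
published summary values of 0.34/0.46 for these communities are not
reproducible from the composition table under any standard Simpson
variant (nor is the eight-member Shannon 1.61 vs the table-derived
≈1.75), so those published values are documented here but never asserted.
The eight-member evenness 0.77 *is* reproducible as 1.61/ln 8 from the
reported H itself.

## Synthetic-data generator

The generator is the study's forward model; its defaults are the study
conditions, fixed once.

**Endpoint composition.** Proportions ∝ fitness × presence-modifiers.
Fitness of the eight non-Cg members equals their reference −Cg endpoint
proportion; Cg's fitness is t/(1−t) of its full-mix share; Cg's modifier
on each member is the ratio of the member's full-mix share (rescaled to
the non-Cg total) to its −Cg share. By construction the zero-noise
generator reproduces both reference compositions exactly — the +Cg
column including Cg at 27.7%, and the release of *B. cepacia* and both
Sphingomonads when Cg is absent. Interactions are present/absent
multiplicative modifiers, not density-dependent: the simplest structure
able to encode the release effect. Composition noise is mean-one
lognormal (CV 0.08, matching 1–3-point SDs on 10–30% shares).

**Activities.** Monoculture intrinsic activities are chosen so that
*S. sanguinis*, *B. multivorans* and *B. cepacia* lead every enzyme
class while the rest span a wide low-to-middling range. Mixed-community
output is a pluggable mixing rule over member activities and endpoint
proportions, times a per-enzyme regulation factor (defaults 0.5; NPPC
0.35), times activity-level presence effects. Three rules ship:

- `weighted_mean` — abundance-weighted mean of intrinsic activities;
- `proportional_sum` — the even-inoculum mean (prediction from input
  shares);
- `dominant` (default) — the best producer among members.

The default is `dominant` rather than `weighted_mean` as a deliberate
design choice: with widely varying monoculture activities, a weighted
mean makes the removal of any top producer a large, detectable drop,
so *no* parameterization of that rule can simultaneously show wide
monoculture variation and dropout robustness. A redundancy-style rule —
community output set by the best producer at a regulated fraction —
expresses the insurance-hypothesis behavior the robust phenotype
implies. Similarly, the −Cg rise in NPPC is carried by an activity-level
effect (Cg present ⇒ community NPPC × 0.55) rather than by composition
alone, because the composition shift is numerically insufficient to
produce a ~80% activity increase. Regulation and presence effects apply
only to designs with ≥ 2 members; monocultures express intrinsic
activity exactly, which is what makes them valid null-model inputs.

Activity noise is mean-one multiplicative lognormal (σ² = ln(1+CV²)),
CV 0.15 by default, applied per replicate; nine replicates per design
model three experiments × three biological replicates, pooled (the
blocked alternative is out of scope since experiment is not modeled as a
factor). Signals are generated by inverting the assay conversions
(Beer–Lambert forward model; linear fluorescence for protease), so
conversion recovers the simulated activity exactly at zero noise — the
pipeline's central parameter-recovery property.

**Plate counts.** A plating volume containing `count_total` (default
500) cells is drawn multinomially from the composition; only species
able to grow on a plate are observed. An exact mode returns fractional
expected counts for round-trip tests.

What the generator does *not* emulate: growth dynamics (no ODEs, no
spatial biofilm structure), signaling mechanisms, density-dependent
interactions, day/experiment batch effects, or pipetting/dilution error
beyond the lognormal and multinomial terms. Passing tests therefore
demonstrate the pipeline's correctness and the qualitative
reproducibility of the robustness pattern under these assumptions — not
mechanistic claims about real communities.

## Null model

Expected activity uses only monoculture means (replicate-averaged) and
member proportions. Both conventions are first class and every output
row records which was used: `literal_divide` (E = Σ Aᵢ/pᵢ, the default)
follows the stated dividing-by-proportion arithmetic even though it
inflates E by n² under evenness; `proportional_sum` (E = Σ Aᵢ·pᵢ) is the
conservative additive prediction. Input weighting uses exact fractions
(1/9, 1/8); endpoint weighting uses resolved compositions with zeros
excluded and the rest renormalized, and is only available for the
communities that were plated (full mix and −Cg). Differences are
actual − expected, so under-producing communities are negative. Under
the default generator, all mixture NPPC differences are negative under
both conventions and both weightings — the high monoculture NPPC of the
producer trio drives every expectation above the regulated community
output.

## Statistics

Dunnett's many-to-one comparisons use the multivariate-t implementation
in scipy with a fixed quadrature seed; adjusted p-values are
reproducible to ~10⁻³, below any reporting threshold used here. The
omnibus one-way ANOVA F is reported alongside. Family-wise calibration
is checked by simulating null datasets and comparing the maximal
balanced many-to-one t statistic (pooled variance, df = k(n−1)) against
the critical value obtained by root-finding on the multivariate-t
rectangle probability — an event identical to "any adjusted p < α", but
vectorizable to 10,000 datasets in seconds.

Composition tables are compared in a two-way species × condition layout:
pooled within-cell mean square, per-species condition contrasts,
Sidak-adjusted over the number of species (p_adj = 1−(1−p)^m).
Proportions are tested untransformed by default (arcsine/logit
transforms would be trivial to add but are not the reference analysis).
Robustness is the operational definition: an enzyme is robust iff no
dropout design differs from the full mix at the family-wise α = 0.05.
No equivalence (TOST) testing is attempted — absence of significance is
reported as exactly that.

## Problem sizes and determinism

Default runs use 9 activity replicates per design, 3 plating replicates
per plated community, 500 colonies per plate, and 10,000 datasets for
the null calibration; these sizes keep a full study run in seconds while
leaving Monte-Carlo error well inside the asserted tolerances. All
stochastic stages draw from child streams spawned from the single run
seed; outputs embed the seed and a hash of the scientific configuration,
and reruns are byte-identical.

## Known limitations

- Absolute activity scales are not comparable to any particular
  instrument without a calibrated pathlength and substrate lot; only
  relative and qualitative statements are asserted.
- The `dominant` mixing rule is a phenomenological stand-in for
  regulation; it reproduces the observed robustness pattern but has no
  mechanistic content.
- NNLS deconvolution is slightly biased upward for species below ~1–2%
  at realistic counting depths.
- The two-way ANOVA assumes independent replicate compositions; actual
  compositional covariance (proportions summing to one) is ignored, as
  in the reference analysis.
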