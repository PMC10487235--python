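# Methods

## Model

`ribofis` implements a Mamdani fuzzy inference system mapping the
concentrations of four semi-defined-medium components to a riboflavin titre.
Every variable carries exactly three triangular linguistic terms anchored at
peaks p₁ < p₂ < p₃ with the shoulder construction

- low = (p₁, p₁, p₂), medium = (p₁, p₂, p₃), high = (p₂, p₃, p₃),

so the extreme terms are degenerate shoulders sitting on the universe edges.
Two consequences are load-bearing throughout the package:

1. **Partition of unity.** The three memberships sum to one at every point
   of the universe (each interior point lies on exactly two complementary
   slopes). Tests assert this to 1e−9 on 1,001-point grids.
2. **Coverage without clamping.** Every in-universe input activates at
   least one rule antecedent, so "no rule fired" can only arise from an
   incomplete rule base — and is raised as an error rather than silently
   defuzzified to a value outside the output range.

Variable universes and peaks: casamino acid 5–20 g/L (5 / 12.5 / 20), GTP
0.01–0.04 g/L (0.01 / 0.025 / 0.04 — the medium peak is the range midpoint,
by analogy with the other inputs), sodium acetate and glycine 5–15 g/L
(5 / 10 / 15), riboflavin output 340–440 µg/L (340 / 390 / 440; edge-and-
midpoint placement following the same construction pattern). "ppb" and
"µg/L" are treated as identical units in dilute aqueous media.

Inference uses the classical Mamdani operator triple — min for AND and
implication, max for aggregation — and centroid defuzzification on a
uniform grid over the output universe. The `Operators` record exists so
alternatives could be added, but only this triple is implemented: it is the
standard toolbox default, and the centroid is the only common defuzzifier
whose output on a symmetric clipped consequent equals the consequent peak,
which the validation arithmetic presumes. Out-of-universe inputs are
rejected, not clamped: the model is only defined on its stated ranges.

### Numerical choices

- **Output discretisation**: 1,001 grid points over [340, 440] µg/L →
  0.1 µg/L resolution, far below the percent-level variations of interest.
  The discrete centroid agrees with a 10×-finer Riemann-sum oracle to well
  under 0.1% relative error (measured ≈ 0.008%).
- **Determinism**: identical model and inputs give bit-identical
  predictions; no randomness exists outside the synthetic generator.
- **Degenerate inputs**: zero-width triangles are rejected at construction;
  a degenerate shoulder's collapsed slope evaluates to degree 1 at its peak.

## Rule induction

The rule base is reconstructed from OFAT data with one-pass Wang–Mendel
generation. For each observation the concentration and the response are
fuzzified; each takes its maximum-membership term (ties break toward the
lower-order term — deterministic, and conservative in that it never
overstates predicted yield); the candidate rule *level-term → response-term*
gets degree = product of the two memberships; per antecedent the
highest-degree candidate wins, ties again toward the lower term. Provenance
(winning observation and its degrees) is retained per rule.

Edge policies: responses outside the output universe are clamped to the
nearest edge with a logged warning, because the unoptimised baseline titre
(≈346 µg/L) sits near the 340 µg/L floor and noisy measurements can cross
it; observation levels outside a factor's fuzzy universe (the OFAT design
probes casamino acid down to 2 g/L, below the model's 5 g/L floor) are
excluded from induction with a warning. A dataset whose usable observations
activate fewer than two input terms cannot constrain a rule base and raises
an insufficient-coverage error.

## Synthetic OFAT generator

No machine-readable fermentation data are deposited, so the generator
emulates the study's dose–response structure with two two-parameter
families:

- **saturating** (casamino acid, GTP): Hill curve with fixed exponent 2,
  floor + span·L²/(L²+K²);
- **unimodal** (glycine, sodium acetate, which rise to an optimum near
  10 g/L and fall beyond): Gaussian bump,
  floor + span·exp(−(L−peak)²/(2w²)).

Measurement error is additive Gaussian noise (default σ = 3 µg/L against a
~60–80 µg/L dynamic range, consistent with mean ± SD replicate reporting),
with triplicates at the concentrations the OFAT campaign actually tested;
the seed is mandatory so every run replays exactly.

**Curve-parameter placement.** The output partition puts the max-membership
crossovers at 365 and 415 µg/L, and the induction round trip is only
well-conditioned when noiseless responses sit clear of those crossovers. A
Hill-2 curve attains at most 60% of its asymptotic span over a four-fold
concentration window (the g(L) = L²/(L²+K²) spread between the end levels
is maximised at K = geometric mean of the ends, giving 0.2 → 0.8), so the
saturating family uses asymptotes 340/440 µg/L with the half-point at the
middle membership peak: attained responses run exactly 360–420 µg/L,
leaving a 5 µg/L margin to each crossover. Under the default noise the
probability that a triplicate's winning vote lands on the wrong side of a
crossover is then ≈0.3% per induced rule (the winner is the observation
farthest from the crossover; a flip requires the largest positive noise
excursion to exceed the largest negative one), which keeps induced rule
bases identical to the noiseless ones in ≈99% of seeded trials — the
package tests assert ≥95% over 200 trials. The unimodal curves use floor
346 µg/L with ceilings 430 (sodium acetate — matching the observed
429–430 µg/L maximum of the optimised medium) and 425 µg/L (glycine),
peak 10 g/L, width 2.5 g/L.

What the generator does **not** emulate: growth kinetics, time/temperature/
pH effects, inter-factor interactions (each factor's curve is independent,
as the OFAT design assumes), non-Gaussian or heteroscedastic measurement
error, and batch effects. Passing round-trip tests therefore show that the
pipeline recovers the structure it assumes — not that real fermentations
satisfy those assumptions.

## Validation arithmetic

Percent variation is **(experimental − predicted)/experimental × 100**,
rounded half-up to two decimals; this is the only convention that
reproduces the published validation table (0.75, 0.29, 0.82, −0.61) from
its own printed inputs. The headline improvement, (optimized −
baseline)/baseline × 100, rounds half-up to an integer (346 → 429 µg/L
gives 24%). RMSE and Pearson's r are computed on whatever
(experimental, predicted) pairs the caller supplies; the published
whole-curve values (RMSE 2.1352, r 0.9985) were computed over full
dose–response point sets that are not printed numerically, so the package
makes no claim of reproducing them — over the four printed validation pairs
the recomputed values are RMSE ≈ 2.50 µg/L and r ≈ 0.967.

## Problem sizes

Defaults throughout are the sizes the analysis actually needs: 3 levels ×
3 replicates per factor for simulation; 1,001-point output grids;
property checks use 100–1,000 random draws and the stochastic induction
regression uses 200 seeded trials. Everything (tests plus the acceptance
script) completes in seconds on one CPU.

## Known limitations

- The true published rule base is unrecoverable from text; induced rules
  approximate it via the printed dose–response behaviour only, so the exact
  published per-level predictions (368, 398, 384, 402, 382, 383 µg/L) are
  not reproduction targets — the engine's properties are asserted instead.
- Whether the published per-factor predictions came from four single-input
  models or one joint model with baselines is unknowable; both builders are
  provided and agree exactly when rules constrain a single factor.
- Single-factor OFAT data cannot inform multi-antecedent rules; the joint
  model accepts them, but induction never produces them.
- The three-term output partition quantises predictions toward the three
  consequent centroids (≈356.7, 390, ≈423.3 µg/L); finer dose–response
  resolution would need more terms than the published design uses.
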