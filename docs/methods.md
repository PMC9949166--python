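# Methods

This note documents the models and procedures implemented in `prebioscreen`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Flux balance analysis core

A metabolic model is a stoichiometric matrix *S* (metabolites × reactions)
with flux bounds *lb ≤ v ≤ ub* (mmol/gDW/hr) and a biomass reaction whose
flux μ (1/hr) is the growth objective. Exchange reactions move a single
external-compartment metabolite across the boundary with coefficient −1;
negative exchange flux is uptake, positive is secretion. A medium maps
compounds to maximum availabilities; applying it sets each listed exchange's
lower bound to −availability and closes all unlisted exchanges, except for a
caller-supplied whitelist (water, protons, O₂ for aerobic conditions, metal
ions that should never be limiting) which keeps the model's own bounds. The
"influx increase by a dose" of a supplementation therefore always maps to a
decrease of the exchange lower bound.

- **FBA**: maximize Σ cⱼvⱼ subject to S·v = 0 and bounds.
- **Penalized (parsimonious-style) FBA**: maximize Σ cⱼvⱼ − λ Σ|v| in one LP,
  with |v| linearized by auxiliaries t ≥ v, t ≥ −v. λ defaults to 10⁻⁶ —
  small enough that the growth optimum is preserved to ~λ·Σ|v|, large enough
  to zero futile cycles and break ties deterministically.
- **Uptake test**: a species can take up compound *c* if min v₍EX_c₎ subject
  to steady state and bounds is < −10⁻⁶. Minimizing the exchange flux is
  maximizing uptake under the sign convention. No growth requirement is
  imposed by default; an optional `min_growth` argument adds one for
  sensitivity analyses (structural dead ends and co-uptake-blocked compounds
  are rejected either way).

Numerical zero is 10⁻⁶ throughout, consistent with the sixth-digit rounding
applied to all screen quantities before thresholding. Two LP backends sit
behind one interface: `scipy.optimize.linprog` (HiGHS, default) and GLPK via
`swiglpk`, which keeps a persistent problem per species and mutates only
bounds between solves (microsecond re-solves; used by the spatial
simulator). The test suite requires backend agreement within 10⁻⁶ and checks
objectives against an independently constructed cobrapy/GLPK solution.

## Unique-niche analysis

Uptake capability is a property of a species and its medium, independent of
the other community members, so profiles are computed once per species and
reused across all subcommunities. A compound is a unique uptake compound of
a species within a community if no other member's profile contains it; the
summary statistic is the fraction of members owning at least one. The
subsampling analysis draws, for each community size, a fixed number of
uniform random subsets (50 by default) and records that fraction;
enumeration over all subsets replaces sampling in the tests at small sizes.
Profiles are computed under the experiment's medium by default; a probe mode
(`probe_availability`) opens every exchange at a common flux to measure the
full repertoire instead — used for the synthetic pool, where the medium is
implicit.

## Community FBA

Member models are merged over one shared external compartment: internals are
species-prefixed; each member's former exchange becomes an unbounded
member↔pool transport; one community-level exchange per compound carries the
medium bound. There is no fixed community biomass composition — each member
keeps its biomass reaction and the objective is the unweighted sum of member
growth rates with the λ = 10⁻⁶ flux penalty. This objective deliberately
lets the most efficient converter of the medium dominate; with exactly
symmetric members the split is degenerate (the solver's choice is arbitrary
and a warning is logged). Normalized abundance is μᵢ/Σμ, undefined (flagged,
not NaN) when the community does not grow.

The screen's community arm reports the change in the target's normalized
abundance between the supplemented and baseline medium as its primary
"relative change" — the normalized quantities are what the community
analysis contrasts — with the raw per-member growth-ratio change
(μₛ − μ_b)/μ_b reported alongside. Both are rounded to six digits before the
strict > 0.01 selection cutoff.

## Individual-based spatial simulation

A deliberately minimal arena in the style of individual-based FBA
simulators; numeric agreement with any particular arena package is not a
goal. Individuals (initial biomass 5×10⁻⁷ gDW) live on a 30×30 grid of
cells holding substrate amounts in mmol, obtained from the medium
concentration (mM) after 1000-fold dilution via a 1 µL cell volume. Per
timestep (Δt = 1 h), in seeded-random order, each individual:

1. gets exchange uptake bounds from its cell: bound(c) = local amount /
   (biomass · Δt) — the maximum-available-amount rule applied locally;
2. solves penalized FBA; an infeasible solve means the individual idles;
3. grows linearly within the step, biomass ← biomass·(1 + μΔt);
4. debits/credits its cell by the realized exchange fluxes (cells are
   clamped at zero; the clamp tolerance is asserted < 10⁻⁶);
5. divides into two halves once biomass ≥ 2× the inoculation biomass, the
   daughter placed in a random neighboring cell;
6. random-walks to one of the 8 neighbors (or stays), reflecting at borders.

Substrate then diffuses by one conservative discrete-Laplacian pass
(pairwise flux form, rate 0.2 per neighbor pair; conserves each compound's
total exactly and cannot produce negative cells for rates ≤ 1). Δt, cell
volume, initial biomass, division rule, movement kernel, and diffusion rate
are modeling assumptions (marked as such in the run manifest), all
configurable and seeded.

Supplementation adds the dose (0.01 mM × cell volume) to every cell once at
t = 0, after dilution. Each supplemented replicate is paired with a control
replicate sharing the same derived seed (identical inoculation and initial
random stream), which removes most placement variance from the relative
final-biomass change ((B_suppl − B_ctrl)/B_ctrl at the final timestep,
rounded to six digits). The statistics arm then compares the two species'
15-replicate relative-change vectors with a two-sided Wilcoxon rank-sum test
per compound (exact for untied n ≤ 20, tie-corrected normal approximation
otherwise, p = 1 on fully tied data), adjusts across compounds with
Benjamini–Hochberg, and selects a compound when the target's median change
exceeds the competitor's and adjusted p < α. α = 0.05 is an adopted,
configurable default — the selection rule itself (median ordering plus FDR
significance) fixes no particular α.

## Screening, enrichment, host analysis

The screen intersects the per-arm selections; intersection members with a
positive Biolog call for the target (growth iff OD590 − OD750 > 0.1, strict)
form the confirmed set. Compounds not present on the plate are reported as
"not assayed", never coerced to negative. Class enrichment is a one-sided
Fisher exact test per annotation class of the candidate set against the
background of the target model's compounds, BH-corrected; one-sided because
the question is enrichment (two-sided is available).

The host analysis separates a supplement's effect on the diet from its
effect inside the host: the expected in-host target proportion under
supplementation is the supplemented lawn proportion multiplied by the
host-filtering ratio observed without supplementation (in-host/on-lawn),
clipped to [0, 1] with a warning. Observed colonization counts are compared
to this expectation with a Pearson chi-square (df = number of categories −
1). The colonization table shipped with the analysis scripts is synthetic
and clearly labelled as such; it illustrates the computation.

## Synthetic benchmark and what it shows

Toy species encode each uptake compound as exchange → transport → conversion,
with the conversion's stoichiometry into a single biomass precursor carrying
the yield, so FBA optima are analytic (μ = Σ yield·uptake) and every
generator claim is checkable. Yield 0 plants a consumable but growth-inert
compound; an exchange without transport plants a structural dead end.

The default two-species benchmark uses 20 uptake compounds — 17 shared, 2
target-private, 1 competitor-private (85%/10%/5%) — plus 2 dead-end inert
compounds. Eight shared compounds are planted prebiotics with a 1.5× yield
advantage for the target; the remaining shared compounds carry the same
advantage for the competitor, making it the stronger generalist so that
both members coexist at the community-FBA baseline and no selection decision
rests on a degenerate LP split. The Biolog table is positive exactly for the
planted set, negative for non-planted shared and inert compounds, and omits
the private compounds (not assayed). Batch availabilities default to
1 mmol/gDW/hr per compound; the spatial medium uses the same numbers as mM.
The community pool generator draws round(overlap·n) compounds per species
from an n-compound pool, so expected pairwise overlap equals the parameter
and chance uniqueness declines with community size.

Passing the benchmark shows the pipeline's logic is correct end to end —
planted differential-yield compounds, and only they, survive all three arms
plus confirmation. It does not show that real reconstructions are accurate:
toy networks have no internal pathway structure, no secretion cross-feeding
by default, no thermodynamics, and their yields are set, not inferred.
Selection counts on real model pairs depend on the reconstruction tool and
its version and are not comparable to the benchmark's counts.

## Problem sizes and determinism

Tests and the acceptance script run the spatial arm on a 10×10 grid (the
package default is 30×30) with the standard 15 replicates × 12 steps, which
keeps the full three-arm screen around half a minute per seed; the
acceptance checks cover five master seeds. All randomness flows from one
master seed through `numpy` SeedSequence spawning (per-replicate seeds kept
below 2³¹), making every stage bit-reproducible; the pipeline manifest
records config, assumption-valued fields, and per-output SHA-256 checksums,
and rerunning with the same seed reproduces them exactly.

## Known limitations

- Exchange-reaction namespaces are treated as opaque strings; reconciling
  ModelSEED/BiGG identifiers across models from different sources is the
  caller's job.
- The community merge assumes a shared external namespace and gives members
  unbounded pool transports; member-level uptake quotas are not modeled.
- The spatial simulator omits chemotaxis, pH/O₂ fields, lysis, and explicit
  volume exclusion; movement and division rules are simple defaults.
- The uptake test without a growth requirement can flag compounds whose
  uptake is stoichiometrically possible but useless for growth; use
  `min_growth` to tighten.
- Only two-species communities are supported by the three-arm screen
  orchestrator (the niche analysis and community FBA handle n species).
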