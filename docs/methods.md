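# Methods

## Scope and data model

One record per packaged product: a category from a 15-sub-category taxonomy
(11 food, 4 beverage), a physical form (solid/liquid), a nutrition panel
declared per 100 g (solids) or per 100 mL (liquids), optional ingredient
text, and an NIP-presence flag. The *form*, never the category, selects which
threshold column applies. Missing nutrient values are first-class (`None`)
and never coerced to zero: the proposed restrictive model's default-excessive
rule needs to know a value is absent. Canonical units are grams, sodium in
mg, energy in kJ (kcal converted at 4.184 kJ/kcal).

The taxonomy keeps *fruits & vegetables* and *vegetables* as distinct
sub-categories (as in the category-mean statistics, n = 196 and 510) and
defines a merged parent used in regulated-count rollups (n = 706), so both
reporting views are available.

## Threshold models

"Exceed" means **strictly greater than** the cut-point everywhere: a product
sitting exactly at a limit is compliant. This is centralized in one config
field (`comparison: gt`), so a ≥ dialect is a one-line change.

**CWO 2019.** Energy, total sugar, sodium, saturated fat per 100 g/100 mL.
The sugar criterion is gated by Chile's added-sugar qualifier so that foods
with only intrinsic sugar (fresh fruit, 100% juice) are not flagged. The
sugar/sodium/saturated-fat cut-points are the same values adopted for the SA
proposal; the energy cut-points (275 kcal/100 g, 70 kcal/100 mL, shipped in
`cwo2019.yaml`) are externally sourced from the Chilean regulation and
labelled as such in the config. Missing evaluated values require an explicit
policy (`error` / `excessive` / `lenient`); the default is to raise, so
callers choose deliberately.

**Proposed SA restrictive model.** Sodium > 400/100 mg, total sugar >
10/5 g, saturated fat > 4/3 g (solids/liquids), NSS on any presence, no
energy criterion. Each nutrient cut-point applies only when the product
contains the matching qualifying ingredient (free-sugar source, added sodium,
added saturated fat). Unknown qualifying criteria resolve to *qualified*
(conservative toward flagging); a missing value for a qualified nutrient is
assessed as excessive; the as-consumed panel is preferred when declared, with
as-packaged as the fallback. The sugar qualifier deliberately differs from
Chile's: juice, pulp and concentrate tokens count as free-sugar sources even
though they are not added sugar, which is exactly what closes the
fruit-juice gap in the octagon model.

**Qualifier derivation.** `derive_qualifying_criteria` infers the four
criteria from ingredient text by keyword lists (two sugar dialects: an
added-sugar list, and that list plus juice/pulp/concentrate tokens for the
free-sugar dialect). It is a transparent heuristic; callers with curated
flags can pass `QualifyingCriteria` directly.

## Scored model (SA HNC)

FSANZ-style points bands ship as opaque YAML (`sahnc_bands.yaml`), following
the public FSANZ nutrient profiling scoring criterion schedule (energy 335
kJ/point, saturated fat 1 g/point, sodium 90 mg/point, sugar bands ~4.5
g/point, each to 10 points; processed cheese/fats use extended 30-point
saturated-fat and sodium ladders): the exact tables mirrored by the draft
regulation are not public, so the bands are config, not code, and a verbatim
regulatory table can be dropped in. Points are the count of ascending band
thresholds strictly exceeded. Modifying points: protein (5 bands), fibre (5
bands), FVNL (1/2/5 points above 40/60/80%), with the protein cap — protein
points are ignored when the baseline is ≥ 13 unless maximum FVNL points are
scored. `final = baseline − modifying`; the baseline variant sets modifying
points to zero, which makes *final-compliant ⊇ baseline-compliant* a
structural guarantee, tested rather than assumed. Missing protein/fibre/FVNL
contribute no points (the resolution the source analysis left unstated);
missing baseline nutrients likewise score zero points, which is lenient —
callers wanting a strict stance should treat missing baseline values
upstream.

Compliance thresholds (strict `<`): beverages 1, processed cheese and fats
28, other foods 4.

**FVNL banding.** Percentage bands (0/25/50/75/100) from ingredient text:
negligible carriers (water, salt, acids) are dropped; concentrated FVNL forms
weigh double; the share of FVNL among remaining ingredients is halved when
the first substantive ingredient is not an FVNL; the result snaps to the
nearest band (ties upward). Non-eligible categories score 0; eligible
categories without text propagate unknown. This emulates a manual ordinal
procedure, so the defaults are a reasonable codification, not a reproduction
of any specific dietitian's decisions.

## Sugar guidelines

At the 8400 kJ reference intake, WHO shares (10% total / 5% free) give
anchors of 168 kJ per g total sugar and 336 kJ per g free sugar; a group's
mean energy density divided by the anchor is its aligned g/100 g(-mL) limit.
Percent-of-energy uses a sugar energy density of **17 kJ/g**. These two
constants are mutually inconsistent by design (168 kJ/g implies 16.8 kJ/g):
the source worked figures for the limits reproduce with the 168/336 anchors
and the percent-of-energy figures reproduce only with 17 kJ/g, so each
constant is used exactly where the original computation used it and both are
exposed on `SugarGuidelineConstants`.

Free-sugar estimation fills gaps only (declared values pass through) with
per-category rules: all-free (sodas and most processed foods), none-free,
fixed fraction, or ingredient-driven (all-free iff a free-sugar-source token
appears — the default for dairy, dairy drinks and canned fruit & vegetables,
where intrinsic lactose/fruit sugar dominates plain products). 100% juice
defaults to all-free, consistent with the free-sugar definition; note the
surveyed juice category reports a free-sugar mean (6.0 g) well below its
total (10.4 g), which no stated rule reproduces — a documented mismatch, not
a calibration target. Estimates are tagged `declared`/`estimated` and never
exceed total sugar.

Rounding on all reported percentages and limits is **half-up** (`decimal`),
not banker's rounding; one decimal place except where the convention is
integer percent (juice compliance).

## NSS detection

The term list (`nss_terms.yaml`) covers the intense sweeteners and polyols
named in the sweetener-class discussion plus standard INS/E additive codes,
with per-term class and synonyms; it is versioned config so an official
search-term list can replace it verbatim. Matching is case-folded with
word-boundary guards (no `polysaccharide` → `saccharin`), invariant to
ingredient order, and monotone in the term list. Empty text yields *unknown*,
not false; prevalence computations refuse unknowns rather than guess.

## Supply analysis

Category summaries report means over non-missing values with the divisor
recorded per nutrient; grand rows (food/beverage/overall) are pooled means
over products, never means of category means. Regulated counts report the
union of flags (`overall`), per-nutrient counts (a product may appear under
several), and `energy_only` (flagged for energy and nothing else). Products
without an NIP are excluded from model comparisons and counted in the run
manifest's coverage block.

## Whole-foods cut-point context

`distribution_summary` gives order statistics (numpy linear-interpolation
percentiles) over an included-flag-filtered composition extract;
`flag_rate_under_cutpoints` reports the share of whole foods each cut-point
would flag. The module evaluates candidate cut-points against natural foods;
it does not derive them, matching the design decision to adopt the Chilean
numbers as-is.

## Synthetic supply generator

Per category: `n`, target means for the seven surveyed nutrients, and an NSS
probability, defaulting to the published 2018 survey values
(`sa_supply_2018.yaml`). Amounts are log-normal (right-skewed, non-negative)
with CV 0.6 — a modeling choice, as the survey publishes only means — with
`sigma² = ln(1+cv²)`, `mu = ln(mean) − sigma²/2` so the target mean is exact
in expectation. Saturated/trans fat are total fat times the fixed mean
ratios, and free sugar is total sugar times `min(free_mean/total_mean, 1)`
(one surveyed category prints free > total, a rounding artefact the clip
absorbs), so the ordering invariants hold by construction. NSS flags are
independent Bernoulli draws realized as sweetener tokens in the synthesized
ingredient text. Protein and fibre means are **assumed** typical
food-composition magnitudes (not survey output — the survey covers only
nutrients of concern) so the scored model's modifying points are exercised;
they are defined in `synth.py` and overridable per config. A zero mean with
positive CV degenerates to a point mass at zero with a warning.

What the generator does *not* emulate: product-level correlations between
nutrients (beyond the ratio ties), within-category multimodality (diet vs
regular sodas), brand structure, or any relationship between ingredient text
and the drawn panel beyond NSS tokens. Passing tests on synthetic supplies
therefore demonstrate the pipeline's correctness and the models' structural
properties (monotonicity, nesting, boundary semantics), not the original
survey's compliance percentages, which require the unreleased product-level
dataset.

Hand-authored fixtures (`fixture_supply`): `table5_boundaries` (products at,
just above and just below every cut-point, plus an NSS-only product),
`energy_only_demo`, `leniency_demo` (a product compliant under the final but
not the baseline scored variant, and one bound by the protein cap), each
stored with frozen expected classifications.

## Problem sizes and determinism

The test suite and acceptance script use a 1000-product supply across 10
seeds for the nesting property and single categories of n = 10⁴ for
parameter recovery (3-standard-error bands), sizes at which sampling checks
are stable yet the whole run finishes in seconds. All stochastic code takes
explicit seeds (numpy `default_rng`); the CLI's `simulate` is byte-identical
across runs at the same seed.

## Known limitations

* NOVA assignment is a transparent marker-list heuristic over ingredient
  text, not the full published NOVA methodology; it supports supply
  characterization, and its marker lists are user config.
* Qualifying-criteria derivation and FVNL banding are keyword heuristics;
  curated flags should be preferred when available.
* The shipped free-sugar rules reproduce the verifiable category behaviours
  (sodas all-free; plain dairy/fruit intrinsic) but are not the unpublished
  estimation worksheet used in the original analysis.
* The SA HNC band tables follow the public FSANZ schedule; if the draft
  regulation's tables differ, replace `sahnc_bands.yaml`.
* Energy cut-points for CWO 2019 are externally sourced from the Chilean
  regulation, not restated in the SA policy documents.
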