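# Methods

## The matching model

A branded product's label carries eight nutrients per 100 g (energy kcal,
protein, fat, saturated fat, carbohydrate, total sugars, AOAC fibre in g,
sodium in mg); a generic reference food carries those plus a full
micronutrient panel. Mapping assumes that a branded product close to a
generic food on the four ranking macros — energy, fat, protein,
carbohydrate — will share its micronutrient profile closely enough for
dietary assessment. The score is the summed absolute percentage difference

    D(b, g) = Σ_k |100 · (g_k − b_k) / max(b_k, ε)|,   k ∈ {energy, fat, protein, carb}

ranked ascending. Design choices where the procedure was genuinely open:

- **Denominator.** The branded (label) value, floored at ε = 0.1 in the
  nutrient's unit. The score is deliberately asymmetric: it answers "how
  far is this candidate from *my* label". The sign convention
  (generic − branded)/branded makes reduced-energy products mapped to
  regular generics come out *positive*, which matches how per-group mean
  differences behave in practice (diet soft drinks drive a large positive
  group mean).
- **Cap.** Each nutrient's contribution is clamped to ±500 percentage
  points. Diet drinks with 1 kcal labels mapped to ~40 kcal generics
  produce several-thousand-percent energy ratios; without a cap one
  nutrient would swamp the other three and the ranking would degenerate to
  an energy-only sort for that whole product class. QC reporting
  (`energy_agreement_check`, `agreement_report`) uses an effectively
  uncapped difference so ">1000%" cases stay distinguishable.
- **Partial panels.** The score is the mean |percentage difference| over
  nutrients present in both panels, rescaled by the full ranking-nutrient
  count (×4). Fully populated panels therefore give the plain sum, and an
  item comparable on only one macro still scores on the same scale rather
  than getting a spuriously small "sum" over fewer terms.
- **Ties** break on generic code lexicographic order — deterministic, in
  place of a human coder's judgement.
- **Blends.** For composite foods, all pairs from two food-group lists are
  scored at splits p ∈ {0, 10, …, 100}. The degenerate splits p = 0 and
  p = 100 are the same candidate as a single food; they are deduplicated
  by canonical allocation key before ranking (lists of sizes 1×1 yield 11
  unique candidates from 11 evaluations; 2×3 yields 59 unique from 66).
  The step is configurable; 10% is the default grid.
- **Blending rule.** Micronutrients (and, for description-only mappings,
  macros) are filled by the allocation-weighted sum. A nutrient missing
  from any constituent is missing from the blend: a partial weighted sum
  would silently understate the true content.
- **Macros are never overwritten** for labelled items. The label is the
  legally accountable "average value"; the generic only donates
  micronutrients. Items with no usable label (classically alcoholic
  drinks, which need not carry one) are mapped by description-only token
  similarity (threshold 0.6 on [0, 1]) and take both macros and micros
  from the generic.

## Tolerances

`bopmap.tolerance` encodes the EU FIC tolerance table: banded ±absolute /
±percent intervals for the macros (e.g. fat < 10 g: ±1.5 g; 10–40 g:
±20%; > 40 g: ±8 g), asymmetric +50%/−35% for vitamins and +45%/−35% for
minerals, and the negligible-amount declarations. Boundary membership for
the printed ranges ("<10", "10–40", ">40") is: 10 and 40 both fall in the
percentage band. Sodium is checked on a gram basis. Two quirks are kept
exactly as the regulation guidance prints them: (1) the salt negligible
rule has threshold ≤ 0.0125 g but label "< 0.01 g" — an apparent
inconsistency we reproduce rather than repair; (2) the fat and salt/sodium
band schemes are *discontinuous* at their band boundaries (±1.5 g just
below 10 g is narrower than ±20% at 10 g), so the bounds are not globally
monotone in the declared value; the property holds only for the
±2 g/±20%/±8 g scheme and the pure-percentage vitamin/mineral rules, and
the tests assert it only there. The vitamin-C-in-liquids allowance for a
higher upper tolerance is an optional multiplier, off by default.

## Cleaning and QC

Cleaning is strictly non-mutating: it partitions catalogs (kept/removed
are disjoint and exhaustive, and a second pass is the identity) and emits
flags or suggestions. Global plausibility cut-offs (energy 900 kcal, carb
99.9 g, protein 89 g, sugars 100 g, fat 99.9 g, saturates 86 g, fibre
54 g, salt 39 g per 100 g) are inclusive upper limits — a value *at* the
cut-off passes. Decimal-shift suggestions fire when a value is outside its
food group's reference range but ×10 or ÷10 lands inside; salt/sodium swap
suggestions fire when the salt field numerically equals sodium-in-grams
while the 2.5× conversion disagrees by > 20% (salt_g = sodium_g × 2.5 is
the standard labelling conversion). Corrections are applied only through
the resolution workflow: keep (flag closed, value untouched), update
(value replaced), remove (item hidden; all its open flags close), with an
audit log conserving item counts.

Group-range QC builds per-(group, nutrient) min–max tables from the
reference catalog; branded groups without a direct reference equivalent
resolve through explicit group lists or description keywords (a "frozen
foods" group built from every reference item whose description contains
"frozen"). Values equal to a range bound are in-range. By construction the
reference catalog can never flag itself.

## Synthetic catalogs

The generator emulates the data a branded-FCDB build actually faces.
Defaults, chosen once as the study conditions: 8 food groups × 25 generics
(200 reference codes — desk-scale but enough for distinct group ranges),
500 branded items, and 5% multiplicative label noise on the four ranking
macros. Noise is log-normal (mean-corrected, σ = ln(1 + sd/100)): label
values are positive and label errors scale with magnitude. Group macro
profiles are drawn uniformly from per-group plausible ranges that echo a
retail taxonomy (soft drinks 1–55 kcal, snacks 350–550 kcal, …), all
inside the global cut-offs, with saturates/sugars clamped below fat/carb
for coherent panels. Injected pathologies — decimal shifts (×10 on one
nutrient), salt-field-holds-sodium swaps, dropped label nutrients,
multipacks (description gains "n pack", weight multiplies), and diet
variants (sugars zeroed, energy scaled to ≤ 5% of the parent) — are all
recorded in a truth table, so recovery and detection are measured against
known ground truth. One seeded NumPy generator drives every draw; a fixed
seed reproduces catalogs bit-for-bit.

What the generator does *not* emulate: real product-name text (a small
template vocabulary suffices for matching tests, so description-based
matching results say nothing about real retail text), brand market
structure, correlated within-brand reformulation, or reference-table
coverage gaps that force recipe decomposition. Passing tests demonstrate
the pipeline's internal correctness and its behaviour under the stated
noise model — not field accuracy on a commercial extract.

## Numerical choices

Catalog values serialize at 4 decimal places; comparisons use 1e-6
absolute tolerance; blend linearity holds to 1e-9. Allocation percents
must sum to 100 (±1e-6 for machine results; hand-coded recipes may be off
by up to ±0.5 before renormalization, absorbing label rounding). Missing
is never zero anywhere: blank cells parse to missing, missing values never
compare equal to 0, and operations on missing values return "incomparable"
sentinels rather than defaults.

## Problem sizes and measured behaviour

The acceptance script measures, at its own generated study conditions
(500 items, 200 generics): parent rank-1 recovery ≈ 98–99% and top-5
recovery 100% under 5% noise; exact (100%, zero-mean) recovery at zero
noise; 100% sensitivity for injected decimal shifts that exit their group
range; zero self-flags on the reference catalog; and the exact tolerance
and enumeration arithmetic above. These sizes keep the whole suite and
script in seconds while leaving every rate estimated from hundreds of
trials.

## Limitations

- The percentage-difference formula, ε, cap and tie-breaks are this
  package's own explicit choices; an interactive nutritionist-in-the-loop
  selection step (which the original database-building workflow relied
  on) is out of scope, as is NLP recipe decomposition from ingredient
  lists.
- Description matching uses token-set similarity over difflib ratios —
  adequate for curated synonym-free text, weaker than a trained matcher
  on raw retail descriptions.
- Tolerance coverage is the BOP nutrient set plus vitamins/minerals, not
  the full labelling regulation (no trans fats, polyols, kJ declarations).
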