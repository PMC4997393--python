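# bopmap

A toolkit for constructing branded food composition databases (FCDBs) from
"back of pack" (BOP) label data. Dietary-assessment tools need nutrient
tables that cover the branded products people actually buy, but food labels
carry only eight legally framed nutrients per 100 g — energy (kcal),
protein, fat, saturated fat, carbohydrate, total sugars, AOAC fibre (g) and
sodium (mg). bopmap fills in the missing micronutrients by matching each
branded item to one or more *generic* reference food codes (the McCance &
Widdowson style national tables) and blending their full panels, while
keeping the label macros authoritative. It is written for nutritional
informaticians and dietary-assessment researchers building or auditing such
databases.

## What it does

- **Cleaning** (`bopmap.cleaning`) — remove non-food and seasonal items,
  collapse multi-packs against their single-item twins, screen the whole
  catalog against global plausibility cut-offs (energy ≤ 900 kcal/100 g,
  protein ≤ 89 g, fibre ≤ 54 g, salt ≤ 39 g, …), and *suggest* — never
  auto-apply — corrections for two classic data-entry errors: misplaced
  decimal points and swapped salt/sodium fields.
- **Mapping** (`bopmap.mapping`) — the core matching algorithm. Each
  generic candidate `g` is scored against a branded item `b` by the summed
  absolute percentage difference over the four ranking macros
  (energy, fat, protein, carbohydrate):

      D(b, g) = Σ_k | 100 · (g_k − b_k) / max(b_k, ε) |

  with denominator floor ε = 0.1 and a per-nutrient cap of 500 percentage
  points; candidates are ranked ascending. Two-food blends
  `p%·a + (100−p)%·b` are enumerated over all pairs from two food-group
  lists in 10% steps from 0 to 100. Chosen allocations populate
  micronutrients by allocation-weighted blending; the 8 label macros are
  never overwritten (except for items that had no label and were mapped by
  description alone).
- **Label tolerances** (`bopmap.tolerance`) — EU Food Information to
  Consumers (FIC) tolerance intervals per nutrient and declared value
  (e.g. fat < 10 g/100 g: ±1.5 g; 10–40 g: ±20%; > 40 g: ±8 g; vitamins
  +50%/−35%) and negligible-amount declarations ("< 0.5 g", "0 g").
- **QC audit** (`bopmap.qc`) — post-mapping rounds: flag items whose
  blended generic energy disagrees with the label by more than 100%;
  flag nutrient values outside the min–max range of their food group in
  the reference catalog; apply human keep/update/remove verdicts with full
  bookkeeping; and produce the per-group agreement report (count, share,
  mean signed % energy difference).
- **Portions** (`bopmap.portions`) — merge serving-size sources by
  priority, derive whole-pack and per-item portions, attach the
  seven-image portion-photograph keys per food type.
- **Synthetic catalogs** (`bopmap.simulate`) — a seeded generator of
  generic + branded catalog pairs with known ground truth and injected
  pathologies (decimal shifts, salt/sodium swaps, missing label panels,
  multipacks, "diet" variants), so the entire pipeline is testable without
  proprietary retailer data.

## Worked example

```python
import bopmap as bm

cfg = bm.SimulationConfig(seed=1, n_branded=500, noise_sd_pct=5.0)
generics, branded, _, truth = bm.generate_catalogs(cfg)

item = branded[0]
for cand in bm.rank_single(item, generics, top_k=3):
    print(cand.rank, cand.allocations[0].generic_code, round(cand.distance, 1))
```

prints

```
1 G00001 11.1
2 G00020 34.3
3 G00010 46.6
```

— the best candidate (`G00001`, summed four-macro percentage difference
11.1) is this item's true parent generic; the runner-up is three times
further away. Applying the chosen mapping copies the generic's
micronutrients onto the branded item while its label macros stay untouched:

```python
chosen = [bm.rank_single(it, generics, top_k=1)[0] for it in branded]
enriched = bm.apply_mappings(branded, chosen, generics)
table, share = bm.agreement_report(enriched.catalog, chosen, generics)
print(f"{share:.1f}% of items within 10% energy agreement")
```

```
95.8% of items within 10% energy agreement
```

A CLI mirrors the library: `bopmap simulate`, `bopmap clean`, `bopmap map`,
`bopmap apply`, `bopmap tolerance`, `bopmap qc ranges|energy|outliers|resolve|report`.

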