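# geckodiet

Stomach-content diet analysis for lizards, built around the workflow used
in field studies of the critically endangered black-eyed bent-toed gecko
(*Cyrtodactylus nigriocularis*): stomach-flushed prey items are measured,
their volumes estimated, and the diet summarised per prey category with
the index of relative importance, then compared between sex and age
groups.  The package is aimed at herpetologists and trophic ecologists
who want those computations reproducible and scriptable rather than done
in a spreadsheet.

## What it computes

For each prey item of maximum length `L` and width `W` (mm), the volume
is the prolate spheroid

```
V = (4π/3) · (L/2) · (W/2)²      [mm³]
```

Per prey category *i*, the composition table tallies the frequency of
occurrence `F_i` (stomachs containing the category), abundance `N_i`
(items) and total volume `V_i`, converts each to a percentage of its
column total, and scores importance as

```
IRI_i = (%F_i + %N_i + %V_i) / 3
```

Around this core the package provides:

- validated CSV/TSV I/O for specimen and prey-item tables
  (`geckodiet.data`),
- the composition table, IRI ranking, and prey-size descriptives
  (`geckodiet.composition`),
- Pearson/OLS, Kendall tau-b and Wilcoxon rank-sum (Mann–Whitney)
  comparisons with exact small-sample p-values (`geckodiet.stats`),
- uncorrected pairwise p-distances on aligned FASTA for barcode
  conspecificity checks (`geckodiet.divergence`),
- a seeded synthetic-data generator calibrated to the published group
  sizes, morphometrics, prey-count overdispersion and prey-size moments
  (`geckodiet.synthetic`),
- a CLI: `geckodiet simulate | compose | compare | seqdiv`.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Recompute the published composition table from its printed per-category
counts (embedded in `geckodiet.reference`) and rank the leading prey:

```python
import geckodiet as gd

table = gd.composition_from_aggregates(
    gd.reference.composition_counts_frame(), n_stomachs=gd.reference.N_STOMACHS
)
print(f"{len(table.rows)} prey categories, ΣF={table.total_F}, "
      f"ΣN={table.total_N}, ΣV={table.total_V:.2f} mm³")
for cat in gd.rank_by_iri(table, top_k=6, min_stomachs=2):
    row = table.row(cat)
    print(f"{cat:<15s} IRI = {gd.round_half_away(row.iri):5.2f} %")
```

prints

```
22 prey categories, ΣF=75, ΣN=407, ΣV=9492.55 mm³
Araneae         IRI = 24.33 %
Opiliones       IRI = 16.59 %
Achatinidae     IRI = 10.67 %
Blattidae       IRI =  8.77 %
Scolopendridae  IRI =  7.59 %
Acrididae       IRI =  4.20 %
```

i.e. spiders are the most important prey (IRI 24.33%), followed by
harvestmen, giant land snails, cockroaches, centipedes and grasshoppers.
`min_stomachs=2` sets aside categories found in a single stomach, whose
IRI can be inflated by one large item; the strict ranking
(`gd.rank_by_iri(table)`) places the single-stomach earthworms
(Lumbricidae, IRI 5.93%) sixth instead.

The same pipeline runs on generated data when no field data are at hand:

```python
ds = gd.compute_volumes(gd.generate_dataset(seed=1))
print("synthetic prey length:", gd.size_summary(ds, "length"))
res = gd.compare_groups(ds, grouping="sex", metrics=["item_length"])[0]
print(f"male vs female item length: W = {res.statistic:.1f}, "
      f"U = {res.extra['U']:.1f}, p = {res.p_value:.3f}")
```

```
synthetic prey length: 7.32 ± 5.98 (min–max: 0.60–56.80, n = 453)
male vs female item length: W = 30514.5, U = 19038.5, p = 0.237
```

The generated pooled length matches the study's 7.53 ± 6.55 mm up to
sampling noise at n ≈ 400, and the sex contrast is null by default
because the generator applies no group effects unless configured.

From the shell:

```
geckodiet simulate --seed 42 --out-dir sim/
geckodiet compose  --specimens sim/specimens.csv --prey sim/prey.csv --out-dir report/
geckodiet compare  --specimens sim/specimens.csv --prey sim/prey.csv --out-dir report/
geckodiet seqdiv   --fasta coi_alignment.fasta --out-dir report/
```

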