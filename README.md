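# dietscope

Gut-content analysis for multi-population fish diet studies: dietary
composition indices, niche overlap with permutation tests, and
size/population feeding models — built so an entire comparative study of
the kind run on invasive eastern mosquitofish (*Gambusia holbrooki*)
can be reproduced, stress-tested and extended from a single seeded
script, with no field data required.

## Who it is for

Trophic ecologists working with per-specimen gut-content tables (one row
per dissected fish: sex, standard length SL, gut length, gut fullness
GF, integer counts per prey category, detritus/unidentifiable flags) and
a per-site environment table. The package covers the full analysis arc
of such a study; a seeded synthetic-data generator emulating the study's
structure (9 populations, 163 fish, 86 F / 77 M, 17.8 % empty guts, 38 %
detritus/unidentifiable-only guts) makes every stage testable end to
end.

## What it computes

**Composition** — frequency of occurrence FO = 100·(guts with item)/n;
percent by number %N; index of relative importance (default Hyslop form
(%N + %V)·%FO with %V = 0 absent volume data; two other variants, always
recorded); Shannon–Wiener H = −Σ pᵢ ln pᵢ; per-specimen relative niche
width RNW = (k − 1)/(K − 1) for k of K = 11 food categories (detritus
counts as a category, unidentifiable material does not).

**Overlap** — Schoener C = Σ min(pᵢ, qᵢ) = 1 − ½Σ|pᵢ − qᵢ| and Pianka
O = Σpᵢqᵢ/√(Σpᵢ²Σqᵢ²) over pooled population diet proportions (detritus
excluded); values > 0.6 flagged as biologically significant; a Mantel
permutation test (exact enumeration for ≤ 7 populations, 10,000
permutations otherwise) relates overlap to great-circle distance.

**Models** — per-category binomial GLMs (logit) of presence on
SL + population + SL:population, with the interaction screened out at
p > 0.2 and the model refitted; gamma GLMs (log) for RGL (= gut
length/SL), GF and RNW; Tukey HSD population contrasts; a female-only
pregnancy post hoc; a permutation-based joint population statistic.

**Environment** — correlation-matrix PCA of site
environment/geography/climate retaining components to 90 % cumulative
variance, OLS of diet metrics on the retained scores, Pearson
correlations of prey totals and empty-gut proportions with each score.

See `docs/methods.md` for models, assumptions and parameter choices.

## Worked example

```python
from dietscope import MetricsConfig, summarize_population
from dietscope.diet_metrics import summaries_to_frame
from dietscope.synthetic import generate_records, get_preset

records = generate_records(get_preset("paper_like", seed=7))
df = summaries_to_frame(summarize_population(records, config=MetricsConfig()))
print(df[["population_id", "n_fish", "FO_CLA", "FO_DET", "shannon_H",
          "mean_RNW", "empty_percent"]].round(3).to_string(index=False))
```

prints (seed 7):

```
population_id  n_fish  FO_CLA  FO_DET  shannon_H  mean_RNW  empty_percent
           P1      16  25.000  37.500      0.357     0.008         18.750
           P2      19  36.842  57.895      0.371     0.050         15.789
           P3      19  47.368  63.158      0.604     0.075         15.789
           P4      23  34.783  78.261      0.331     0.038          8.696
           P5      18  27.778  72.222      0.000     0.020         16.667
           P6      20  25.000  50.000      0.274     0.019         20.000
           P7      20  20.000  55.000      0.398     0.018         15.000
           P8      16  62.500  43.750      0.334     0.047          0.000
           P9      12  41.667  58.333      0.307     0.064          8.333
```

FO columns are the percentage of guts containing Cladocera/detritus; H
is the Shannon diversity of each population's pooled prey counts (P5's
counted prey all fell in one category, hence 0); mean RNW averages
per-fish niche breadth over non-empty guts (0 = single category, 1 = all
eleven); and the empty percentages scatter around the generator's 17.8 %
study condition at these sample sizes.

The `examples/` directory holds one short script per capability
(`01_diet_summary.py`, `02_overlap_and_mantel.py`,
`03_size_population_glms.py`, `04_environment_pca.py`); each builds a
small input, runs the method and explains the numbers it prints. For
instance `02_overlap_and_mantel.py` builds the overlap-anchor scenario
and reports `Mantel (distance vs. overlap): r = -0.142, p = 0.833
[exact_enumeration, 24 relabelings]`.

The same operations are available from a thin CLI:

```bash
dietscope simulate --preset paper_like --seed 7 \
    --out-records records.csv --out-sites sites.csv
dietscope summarize --records records.csv --out table1.tsv
dietscope overlap --records records.csv --layout table2 --out table2.tsv
dietscope mantel --records records.csv --sites sites.csv --permutations 10000 --seed 42
dietscope run --preset paper_like --seed 7 --out-dir out/   # full bundle
```

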