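# palynores

Quantifies how decreasing pollen taxonomic resolution distorts anthropogenic
land-use signals in postglacial pollen records.

Palaeoecologists detect past farming from *anthropogenic pollen indicators*:
primary indicators (crops such as Cerealia-type or *Castanea*), adventive
weeds (non-native, introduced with agriculture, e.g. *Plantago
lanceolata*-type) and apophytes (native plants favoured by land use, e.g.
*Artemisia*). When records are harmonized to coarser taxonomic levels for
database-scale syntheses — hierarchical levels HL0 (finest light-microscopy
resolution) → HL1 → HL2 (genus/family groups) — indicator types merge with
wild congeners: Cerealia-type disappears into Poaceae, *P. lanceolata*-type
into *Plantago*. The merged type inherits the natural abundance of the wild
constituents while keeping a (downgraded, apophyte-level) indicator label,
so coarse-resolution records tend to overestimate land use and produce
false-positive signals before agriculture ever began. This package
implements the full analysis chain to measure that effect, and a synthetic
record generator with a known land-use history to validate every stage.

## What it computes

- **Harmonization** (`harmonization`): many-to-one HL0→HL1→HL2 merging of
  count tables with capacity downgrade rules (a merge mixing indicators with
  apophytes or wild taxa becomes APOPHYTE; an indicator-only mix keeps its
  weakest member) and indicator selection.
- **Indicator curves** (`abundance`): percentages of the terrestrial
  reference sum (trees + shrubs + upland herbs + terrestrial fern spores),
  summed per capacity category and per sample.
- **Sequence-slotting dissimilarity** (`slotting`): the psi statistic
  between two multivariate ordered series,

  ψ = ((AB_between − AB_within) / AB_within) + 1,

  where AB_between is the least-cost monotone path (right/down/diagonal
  moves) through the pairwise Euclidean distance matrix and AB_within the
  summed consecutive-sample distance within each series; ψ(a, a) = 0.
  Includes 500-yr binning (non-zero means) and leave-one-bin-out psi drops
  that attribute dissimilarity to time intervals.
- **Change points** (`changepoint`): greedy binary segmentation on the total
  indicator curve with a Gaussian mean+variance cost, a split accepted when
  Ω(whole) > Ω(left) + Ω(right) + β, at most 4 change points.
- **Level comparison** (`stats`): paired two-sided Wilcoxon signed-rank
  tests (exact for ≤ 25 untied pairs) and Gaussian KDEs with the
  Sheather–Jones solve-the-equation bandwidth.
- **Synthetic records** (`synthetic`): multinomial pollen counts (fixed
  500-grain sums) over a 12,000-year record with logistic ramps at an
  agriculture onset (7,500 cal BP) and an intensification (3,500 cal BP),
  plus wild "confuser" taxa sharing coarse groups with the indicators.
- **Pipeline + CLI** (`pipeline`, `cli`): per-site orchestration writing
  curves.csv, psi.csv, drops.csv, changepoints.csv, wilcoxon.csv and
  report.json.

## Worked example

```sh
palynores simulate --seed 42 --out counts.csv --table harmonization.csv
palynores run --counts counts.csv --table harmonization.csv --outdir out/
```

`out/psi.csv` (between-level dissimilarities of the indicator assemblages):

```
site,HL0-HL1,HL0-HL2,HL1-HL2
synthetic,0.737983,5.88752,5.6526
```

Coarsening to HL2 — where Cerealia-type merges into Poaceae and *Plantago
lanceolata*-type into *Plantago* — makes the indicator record about eight
times more dissimilar from the original (ψ 5.89 vs 0.74) than the milder
HL1 harmonization, which only merges the Brassicaceae types.

`out/changepoints.csv`:

```
site,level,cp_index,cp_age_calBP,segment_mean_before,segment_mean_after
synthetic,HL0,75,7450,17.6931,2.95375
synthetic,HL1,74,7350,19.5102,9.10434
synthetic,HL1,76,7550,9.10434,4.61724
synthetic,HL2,75,7450,49.8258,33.7463
```

Every level recovers the simulated agriculture onset (7,500 cal BP) to
within one sampling step; note the "before" (younger-side) mean at HL2 is
~34% of the reference sum even though the record contains no farming signal
before 7,500 cal BP — the false-positive apophyte inflation. In
`out/wilcoxon.csv` the adventive HL0–HL2 comparison is marked `no data`:
at HL2 all adventives have been re-assigned to the apophyte category.

The same operations are available as library functions
(`palynores.analyze_record`, `palynores.psi`, `palynores.binary_segmentation`,
...), and a bundled synthetic emulation of a realistic indicator
harmonization table is available via
`palynores.datasets.synthetic_indicator_table()`.

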