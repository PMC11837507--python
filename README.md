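# qsip15n

Quantitative stable isotope probing (qSIP) of microbial **nitrogen**
assimilation from ¹⁵N-labeled DNA density gradients, with a built-in
forward simulator and non-parametric method-comparison statistics.

## What it does

In a ¹⁵N qSIP experiment, soil (or another community) is incubated with a
¹⁵N-labeled substrate, DNA is separated on a CsCl density gradient, the
gradient is fractionated, and each fraction is quantified (16S qPCR) and
sequenced (16S amplicons). Taxa that assimilated ¹⁵N build denser DNA and
their abundance profile shifts toward heavier fractions. This package turns
those fraction tables into per-taxon enrichment estimates:

1. **Filtering** — ASVs are removed when they are rare *and* sparse
   (default: total < 200 reads **and** detected in < 20 fractions), then
   aggregated to genus on the full six-rank lineage (unresolved genera
   become `"<finest rank> gen."`). Genera are dropped when their mean
   copies-weighted relative abundance is below 10⁻⁴ or they appear in
   fewer than 5 plots at either site.
2. **WAD** — each genus's weighted average density per tube, weighting
   fraction densities by its absolute 16S copies (relative abundance ×
   qPCR total), over the analysis window 1.67–1.74 g/mL.
3. **Tube correction** — per-tube density calibration offsets are
   estimated as the median WAD shift of a 50-genus reference set (the
   genera with the smallest mean shifts) and subtracted.
4. **Enrichment** — the light (unlabeled) WAD gives each genus's GC
   content and molecular weight; the corrected WAD shift converts to the
   **excess atom fraction (EAF)** of ¹⁵N, with negatives clamped to zero.
5. **%N assimilated** — each genus's abundance-weighted share of the
   community's total ¹⁵N assimilation (relative abundance × EAF,
   normalized per sample).
6. **Method comparison** — Passing–Bablok regression (classical
   shifted-median or an axis-exchange-equivariant angle-median variant)
   with bootstrap confidence intervals compares two labeling approaches
   (e.g., field-incubated vs laboratory-incubated) genus by genus, and a
   per-genus one-way ANOVA tests field vs lab differences.

Scalar helpers cover the accompanying soil-N bookkeeping: net
nitrification and net immobilization rates from inorganic N pools, plant
¹⁵N recovery and uptake rates, and amendment unit conversions
(µmol N/g → µg N/g → kg N/ha).

The design is statsmodels-like: you construct a model object from data,
call `.fit()`, and get a results object with estimates, uncertainties,
and a `summary()`.

## Worked example

Simulate a paired study (2 sites × 7 plots, each with an unlabeled
pre-incubation control plus field- and lab-incubated labeled tubes), fit
the pipeline, and compare methods:

```python
from qsip15n import NitrogenQsip, SimulationConfig, simulate_study

tubes, counts, samples, truth = simulate_study(SimulationConfig(n_taxa=120, seed=7))
results = NitrogenQsip(tubes, counts, samples).fit()
print(results.summary())
```

```
15N-qSIP enrichment summary
============================================
genera retained        120
labeled samples        28
tubes dropped (window) 0
negative EAF clamped   703 of 3360 rows

median EAF by site and method:
  Ridge    field    0.1096
  Ridge    lab      0.1364
  Valley   field    0.1113
  Valley   lab      0.1403
```

```python
fit = results.compare_methods(metric="eaf", n_boot=999, seed=0)
print(fit.summary())
```

```
Passing-Bablok method comparison
============================================
estimator            equivariant
n pairs              120
slope                0.7691  (95% CI 0.7430, 0.7928)
intercept            0.0000  (95% CI 0.0000, 0.0033)
Pearson r            0.9787
proportional diff.   yes (slope CI excludes 1)
constant diff.       no
bootstrap            quantile, B=999
```

The simulator generated field enrichment as `0.81 × lab + 0.01` plus
taxon-level noise; the fitted slope below 1 correctly detects the
proportional difference between methods (the estimate sits slightly
under the generating 0.81 because the tube correction absorbs part of
the constant offset — see `docs/methods.md`).

The same analysis from the command line:

```sh
qsip simulate --out sim --seed 7 --config sim.yaml   # sim.yaml: "n_taxa: 120"
qsip run --fractions sim/fractions.tsv --counts sim/counts.tsv \
         --taxonomy sim/taxonomy.tsv --samples sim/samples.tsv \
         --out results --seed 0 --n-boot 999
qsip compare --eaf results/eaf.tsv --metric eaf --seed 0 --n-boot 999
qsip amendment --n-conc 3 --depth 15.24 --bulk-density 1.3
```

The last command prints:

```
42.02 µg N g^-1 soil
83.3 kg N ha^-1
```

`qsip run` writes `eaf.tsv` (one row per genus × labeled sample with GC,
WADs, shifts, EAF and %N), `wad.tsv`, `wad_shifts.tsv`, `light_wad.tsv`,
`filter_report.tsv`, `comparison.tsv`, `genus_tests.tsv`, a `run.log`,
and the resolved configuration as JSON.

## Input formats

Plain TSV/CSV tables (separator auto-detected), `#`-prefixed comment
headers allowed:

- **fractions**: `tube_id, sample_id, fraction_id, density, total_copies`
  — one row per gradient fraction with its buoyant density (g/mL) and
  total 16S copies from qPCR.
- **counts**: taxa × fractions ASV read-count matrix; **taxonomy**:
  `taxon_id, taxonomy` with semicolon-delimited `d__;p__;c__;o__;f__;g__`
  lineages.
- **samples**: `sample_id, site, method, plot, label` — `label` is
  `unlabeled` or `labeled`; each labeled sample is paired with the
  unlabeled control of its site and plot.

## Reproduction

All headline quantities are recomputed from scratch by:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which runs the amendment conversions and one full simulate → estimate →
compare cycle at the default geometry (300 taxa, default noise) and
writes, for example (seed 1):

| key | value |
| --- | --- |
| `amendment_ug_n_per_g` | 42.0201 |
| `amendment_kg_n_per_ha` | 83.2502 |
| `pb_slope_eaf` | 0.782 |
| `pb_intercept_eaf` | 0.0029 |
| `pb_slope_pct_n` | 0.965 |
| `pb_intercept_pct_n` | 1.4e-05 |
| `pearson_r_pct_n` | 0.993 |
| `median_abs_eaf_error` | 0.0115 |
| `lab_eaf_mean_excess_pct` | 23.4 |

The test suite (`python -m pytest -q tests/`) includes
`tests/test_acceptance.py`, whose checks cover the unit conversions, the
regression interpretation rules, noise-free and default-noise parameter
recovery against the simulator's truth tables, the tube-correction
property, estimator/oracle equivalence for Passing–Bablok, and %N
normalization. One acceptance test
(`test_reference_study_tables_reproduce`) requires an external study's
deposited processed tables under `data/reference_study/` and fails with
a clear message when they have not been downloaded.

See `docs/methods.md` for the model, its parameters and numerical
choices, and the limitations of both the estimator and the simulator.
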