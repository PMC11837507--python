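# Methods

This note documents the estimation model implemented by `qsip15n`, the
forward simulator used to validate it, the numerical choices that are not
obvious from the code, and the limitations of both.

## 1. The enrichment model

### Absolute abundance per fraction

Sequencing gives relative abundances per fraction; qPCR gives the total
16S copy number of each fraction. A taxon's absolute abundance in
fraction *k* of a tube is

```
copies_ik = rel_abund_ik × total_copies_k
```

Only fractions in the analysis window (closed interval 1.67–1.74 g/mL by
default) are used; a tube with fewer than three in-window fractions is
flagged unusable and dropped with a warning.

### Weighted average density (WAD)

Per taxon and tube:

```
WAD_i = Σ_k density_k · copies_ik / Σ_k copies_ik
```

undefined (NaN) when the taxon has zero copies in the window.

### Light WAD, GC and molecular weight

The light (unlabeled) WAD of a taxon is the mean of its WADs over **all**
unlabeled tubes. It determines GC content and molecular weights through
the empirical buoyant-density calibration:

```
GC       = (W_light − 1.646057) / 0.083506
M_light  = 0.496·GC + 307.691              (g/mol, natural abundance)
M_heavy,max = M_light + 3.517 + 0.5024·GC  (all N atoms ¹⁵N)
```

GC is clipped to [0, 1] with a log warning when the calibration is
extrapolated.

### WAD shift and tube correction

The raw shift of taxon *i* in labeled tube *t* is its WAD minus its WAD
in the *plot-paired* unlabeled control tube. Gradients carry tube-level
density calibration offsets; these are estimated from an internal
reference set — the 50 genera with the smallest global mean |raw shift|,
preferring genera observed in every labeled tube — as the per-tube median
raw shift of the reference genera, and subtracted:

```
corrected_shift_it = raw_shift_it − median_{j ∈ ref}(raw_shift_jt)
```

### Excess atom fraction (EAF)

With `W_lab = W_light + corrected_shift` (per labeled tube):

```
M_lab = M_light · (W_lab / W_light)
EAF   = (M_lab − M_light) / (M_heavy,max − M_light) · (1 − 0.003663)
```

where 0.003663 is the natural abundance of ¹⁵N. A worked value: with
`W_light = 1.70` and `W_lab = 1.71`, `GC = 0.64598` and `EAF = 0.46991`.
Negative raw EAFs (shifts below zero after correction) are clamped to 0
in a separate, counted step; the raw values are retained in the output.

### %N assimilated

Per labeled sample, each taxon's share of community N assimilation:

```
P_i = RA_i · EAF_i / Σ_j RA_j · EAF_j
```

with RA the copies-weighted in-window relative abundance of the taxon in
that sample. P sums to 1 per sample whenever any EAF > 0.

### Filters

- **ASV filter**: removed iff total reads < 200 **and** detected in < 20
  fractions (both conditions; a strict either-condition variant is
  available via `asv_require_both=False`).
- **Genus aggregation**: on the 6-rank lineage prefix; ASVs resolved only
  to a higher rank aggregate as `"<finest rank> gen."`; identical genus
  names under different parents stay distinct.
- **Genus filter**: removed if mean copies-weighted relative abundance
  < 10⁻⁴ across labeled samples, or detected in < 5 plots at either site.

### Method comparison

Genus-level medians (across plots, optionally per site) of EAF or %N for
each method feed a Passing–Bablok regression of field on lab. Two slope
estimators:

- **classical**: shifted median of pairwise slopes `S = Δy/Δx`, excluding
  `S = −1` and `Δx = 0` pairs, offset `K = #{S < −1}`; undefined (raises)
  when the shifted index leaves the list.
- **equivariant** (default): `tan(median θ)` with `θ = atan2(Δy, Δx)`
  folded to `(−π/2, π/2]`; `Δx = 0, Δy ≠ 0` pairs contribute `π/2`. This
  variant is exactly invariant under exchanging the axes for all-positive
  slopes and odd pair counts.

Intercept: `median(y − slope·x)`. Confidence intervals: quantile
bootstrap over pairs (B = 1999 default), degenerate resamples redrawn
(capped at 10·B). Interpretation uses closed intervals: slope CI not
containing 1 ⇒ proportional difference; intercept CI not containing 0 ⇒
constant difference.

Per-genus field-vs-lab tests are one-way fixed-effects ANOVAs (two
groups, n = plots per method), equivalent to the squared pooled-variance
t-test, with tier markers `.`/`*`/`**`/`***` at p ≤ 0.10/0.05/0.01/0.001.

### Biogeochemistry helpers

With inorganic pools in µg N/g soil and Δt in days:

```
net_nitrification  = ΔNO3 / Δt
net_immobilization = ((NH4+NO3)_initial + N_added − (NH4+NO3)_final) / Δt
recovery%          = 100 · excess ¹⁵N in plant / added ¹⁵N
uptake             = (atom% excess · total N) / (ref atom% excess · days)
µg N/g             = µmol N/g × 14.0067
kg N/ha            = µg N/g × depth(cm) × bulk density(g/cm³) × 10⁸ cm²/ha × 10⁻⁹ kg/µg
```

## 2. The forward simulator

`simulate_study` generates a full paired experiment: 2 sites × 7 plots ×
(pre-incubation control + field + lab) = 42 tubes by default.

Per taxon: GC ~ Beta(7, 3) scaled to [0.25, 0.75] (GC-rich soil
communities, mean ≈ 0.60); baseline abundance lognormal (σ = 1,
normalized); true lab EAF zero-inflated (P(0) = 0.2) with positive part
`0.6 × Beta(2, 3)`; true field EAF `max(0.81·lab + 0.01 + N(0, 0.02), 0)`.
The positive-part mean (≈ 0.19) was chosen analytically so that the
0.81/0.01 lab→field map implies a mean lab-over-field excess of ≈ 16%
at the *true* EAF level.

Per tube: each taxon's DNA bands at the density obtained by inverting the
EAF chain at its true enrichment, plus a tube offset ~ N(0, 0.002 g/mL);
its mass spreads over 25 equal bins on [1.61, 1.78] via a Gaussian kernel
(sd 0.006 g/mL). qPCR totals get multiplicative lognormal noise
(CV = 0.1); sequencing draws multinomial counts (10 000 reads per
in-window fraction; `seq_depth=None` emits exact expected proportions).
Everything is deterministic in the seed (`SeedSequence.spawn` per tube);
written files are byte-identical across runs.

### Parameters (defaults)

| parameter | default | unit | why |
| --- | --- | --- | --- |
| `n_taxa` | 300 | – | enough genera for stable medians and a 50-genus reference set |
| `gc_beta`, `gc_range` | (7, 3), (0.25, 0.75) | – | right-shifted GC typical of soil; keeps most bands inside the sequenced window |
| `eaf_zero_prob` | 0.2 | – | a fifth of taxa assimilate no label |
| `eaf_beta`, `eaf_max` | (2, 3), 0.6 | – | right-skewed enrichment, mean ≈ 0.19 of the positive part |
| `field_slope/intercept/noise` | 0.81 / 0.01 / 0.02 | – | lab→field map with taxon-level scatter |
| `fractions_per_tube`, `density_range` | 25, (1.61, 1.78) | –, g/mL | typical gradient fractionation |
| `analysis_window` | (1.67, 1.74) | g/mL | sequenced/analyzed fraction window |
| `kernel_sd` | 0.006 | g/mL | within-taxon band width |
| `tube_offset_sd` | 0.002 | g/mL | tube-to-tube calibration error |
| `qpcr_cv` | 0.1 | – | qPCR measurement noise |
| `seq_depth` | 10 000 | reads/fraction | realistic amplicon depth |

Problem sizes in the tests (50–300 taxa, 42 tubes, 25 fractions) are this
package's own choices, sized to run in seconds on one CPU.

## 3. Numerical choices

- **`apply_tube_correction` flag**: with zero injected offsets and a
  small, mostly enriched community, a 50-genus reference set necessarily
  contains enriched genera and subtracts real signal. Noise-free
  identifiability checks therefore disable the correction (there is
  nothing to correct); all realistic-noise analyses keep it on.
- **Window selection is a closed interval** and tubes keep their full
  fraction list until selection, so the window choice is reproducible
  from the saved configuration.
- **Light WAD uses all unlabeled tubes** (maximally precise GC/weight
  reference) while the **shift is computed against the plot-paired
  control**, so plot-level density idiosyncrasies cancel in the shift.
- **Clamping is separate from estimation**: raw EAFs are preserved and
  the number of clamped values is reported, so the truncation is
  auditable.
- **Bootstrap determinism**: all resampling uses an explicit seed;
  pipeline outputs are identical across reruns.
- **ANOVA guards**: equal constant groups return (F = 0, p = 1);
  separated constant groups return a large finite F (10¹²) instead of
  infinity so downstream tables stay numeric.

## 4. Limitations

- **Window truncation.** A taxon whose band sits within ~3 kernel sd
  (~0.018 g/mL) of a window edge has its WAD biased inward by kernel
  truncation; at the lower edge this inflates the light WAD and biases
  EAF downward. For the default kernel this means the noise-free
  per-taxon error bound (≤ 0.01) holds only for GC ≳ 0.5; low-GC or very
  highly enriched taxa near the edges carry an estimator-independent
  bias. The noise-free validation therefore simulates GC in
  [0.52, 0.75]; the default generator keeps the wider range, where the
  bias shows up in the tails of the error distribution.
- **Reference-set contamination.** At default noise, ranking genera by
  mean |raw shift| admits weakly enriched genera into the reference set
  with some probability; the resulting offset over-subtraction inflates
  EAF errors for some seeds. This is a property of the correction method
  itself, visible as occasional seed-level outliers in the recovery
  error.
- **Correction absorbs constant offsets.** A constant enrichment shared
  by all taxa (e.g., the simulator's field intercept of 0.01) is
  indistinguishable from a tube offset and is partially removed by the
  correction, which also pulls the fitted method-comparison slope
  slightly below the generating value.
- **Counting-noise floor.** Per-genus WAD shifts carry ~4×10⁻⁴ g/mL of
  multinomial + qPCR noise at default depth; aggregate error measures
  that average |shift| over genera are floored by this noise regardless
  of how well tube offsets are removed. Offset-removal quality is
  therefore assessed at the tube level (mean shift of an unenriched
  community per tube), where the correction removes 97–98% of the
  injected error.
- **Simulator scope.** Passing the recovery tests shows the estimation
  chain inverts this generator, not that it reproduces any particular
  real dataset: the simulator has a single community across sites and
  plots, Gaussian bands, no chimeras or contamination, no PCR bias, and
  site differences only through independent noise draws. Conclusions
  about real soils require real gradient data.
- **Calibration constants** (GC↔density, molecular weights, natural
  abundance) are fixed literature values via `IsotopeConstants`; users
  with other amplicons or isotopes must supply their own.
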