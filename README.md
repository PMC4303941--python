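# somportrait

SOM expression portraits for binary time-course proteomics.

`somportrait` re-implements, as a tested pipeline, the analysis of weekly
urine-proteomics presence/absence data from a long-duration isolation
study: six volunteers sampled weekly before, during and after ~15 weeks of
isolation under a controlled, stepwise-reduced NaCl diet, with ~2000
protein species scored 1/0 per sample. The package is aimed at anyone who
wants to apply self-organizing-map (SOM) portraiture to short, noisy,
binary time-course omics data — and at anyone who wants to test such a
pipeline against planted ground truth, which the built-in cohort simulator
provides.

## What it computes

Starting from per-volunteer binary matrices (proteins x weeks), the
pipeline:

1. **Mean-volunteer assembly** — cell value = fraction of volunteers with a
   sample that week detecting the protein; **centralization** subtracts each
   profile's mean, giving differential detection dE (over-/under-presence).
2. **SOM portraits** — batch training distributes the N protein profiles
   over a 40x40 grid of K = 1600 prototype profiles ("meta-features") by
   Euclidean similarity; the K values at one week, drawn on the grid, are
   that sample's portrait (red = over-, blue = under-expressed).
3. **Spot modules** — per week the top/bottom 2-percentile of meta-feature
   values are selected; the per-week selections are unioned and split into
   8-connected grid regions ("spots"), each a candidate co-expression
   module with a mean dE profile, a phase φ̂ (argmax week) and a
   reference-phase class (early ≤ week 6 / intermediate 7–11 / late ≥ 12).
   Correlation-seeded and K-means segmentation are available alternatives.
4. **Trajectories** — samples are projected into 2-D similarity space by a
   second-level SOM over the sample state vectors (and by FastICA); k-means
   segmentation of the trajectory is scored against the reference phases by
   adjusted Rand index.
5. **Networks & significance** — spot–spot weighted topological overlap
   (wTO) in separate positive/negative correlation channels,

       ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

   with a_ij = max(±r_ij, 0); and the beta coherence test per spot,

       β = (Σ_i r(c̄, x_i))² / (Σ_i Σ_j r(x_i, x_j)) ∈ [0, 1],

   over the spot's meta profiles x_i with mean profile c̄, with a
   map-resampling permutation p-value and Benjamini–Hochberg adjustment.
6. **Enrichment** — Fisher hypergeometric test and a GSZ score (overlap
   z-score combined with the members' mean-dE z-score) over GMT gene sets;
   gene-set density maps and set abundance profiles.
7. **Pathway signal flow (PSF)** — signed KGML-subset pathway DAGs; node
   fold changes (mean member fold change, 1 if unmeasured) modulate a
   signal propagated from sources to sinks (× FC across activation, ÷ FC
   across inhibition, parents averaged); sink time profiles are matched to
   spot profiles by Pearson r.
8. **Total abundance** — on a map trained with non-centralized values, the
   per-week variance of the meta-feature landscape tracks overall abundance
   amplitude; local maxima mark abundance peaks.

The cohort simulator plants ten wave-like modules (cosine or single-peak
detection-probability waves differing in phase and period) among invariant
and single-spiked background proteins, so every stage can be scored
against ground truth.

## Worked example

Run the numbered drivers in order (they share `results/run/`):

```
cd analysis
python 01_simulate_cohort.py
python 02_mean_volunteer.py
python 03_train_som.py
python 04_spot_modules.py
...
```

Abridged output at seed 1:

```
cohort written: 6 volunteer matrices, 2000 proteins
background: 250 invariant-high, 550 invariant-low, 250 single-spiked (52.5% outside modules)

map: 1600 meta-features x 23 weeks
quantization error 0.6293 -> 0.4211

6 over-expression and 6 under-expression spots
spot  n_nodes  n_members  phase_week  phase_class
   A      106        175           2        early
   B       95        140          10 intermediate
   C       76         94          16         late
   ...

beta test: 9/12 spots significantly coherent (BH p < 0.05)

spot         set  overlap  n_set         p_adj       gsz
   A planted:M02       88     95  1.250995e-93 16.262428
   B planted:M01       95     95  3.568749e-99 30.075728

variance profile over 23 weeks; detected peaks at weeks [-3, 1, 7, 15]
```

Reading this: the portrait map absorbs the 2000 binary profiles at a
quantization error of 0.42 detection-fraction units; the percentile spots
pick up co-expression modules whose phases walk from early isolation to
the post-isolation weeks; the beta test confirms within-spot coherence;
enrichment against the planted labels rediscovers which module feeds which
spot (e.g. spot B contains all 95 proteins of planted module M01); and the
total-abundance landscape shows four variance peaks spaced 4–8 weeks
apart. Equivalent functionality is available from the CLI
(`somportrait simulate|run|stage|report`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch at the given seed (simulation
through total abundance, ~15 s) and writes the target-value JSON; the run
directory next to it holds every stage artifact plus a manifest with
SHA-256 hashes of the tables.

## Layout

- `src/somportrait/` — library: `io`, `cohort`, `som`, `spots`,
  `trajectories`, `netstats`, `enrichment`, `psf`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model, parameter and design notes.
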