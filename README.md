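# slicksurvey

Statistical toolkit for **paired slick/ambient neuston tow surveys** — for
plankton ecologists asking how strongly surface convergence slicks
concentrate larval fish, zooplankton prey, and floating debris, and what
that concentration means at regional scale.

Surface slicks are bands of smooth water formed by convergent flow (often
internal waves) that accumulate buoyant material. A survey tows a neuston
net inside slicks and in nearby ambient water, counts organisms per tow,
and standardizes counts to densities (individuals m⁻³) using the volume of
water filtered. `slicksurvey` implements the full inferential chain on top
of such tables, plus a synthetic survey generator with known ground truth
so every estimator has a parameter-recovery test.

## The statistics

For each taxon or group with slick densities d and ambient densities d′:

* **Bootstrap response ratio** — per bootstrap replicate *i* (resampling
  tows with replacement within each habitat), the ratio
  d̄_slick(i)/d̄_ambient(i); reported as mean and 2.5–97.5 percentile
  interval of 10,000 replicates. When any ambient replicate mean resamples
  to zero, every numerator is instead divided by the grand mean of all
  ambient replicate means (flagged `corrected`).
* **Permutation probability** P(d̄_slick > d̄_ambient) — the proportion of
  habitat-label permutations whose mean difference falls below the observed
  difference (ties half-counted); capped at 1 − 1/nperm, printed
  "≥ 0.9999" at 10,000 permutations.
* **Community ordination** — Bray–Curtis distances on log-transformed
  family densities, partial distance-based redundancy analysis (dbRDA):
  principal-coordinate embedding (positive eigenvalues), site partialled
  out, habitat as the single constraint, pseudo-F tested by reduced-model
  residual permutation. Shannon H′ and richness S are contrasted with the
  same bootstrap/permutation machinery.
* **Size-dependent occurrence** — per 5-mm length bin, the slick share
  p = d̄_slick/(d̄_slick + d̄_ambient) from bootstrapped means, fitted by a
  beta regression with logit mean link (slope in logit units per mm).
* **Regional scaling** — if slicks cover areal fraction *a* of the sea
  surface and hold *r*-fold densities, they contain
  P(a, r) = a·r / (a·r + (1 − a)) of the regional standing stock;
  uncertainty propagates through bootstrap replicates and across
  remote-sensing scenes (mean ± SD).

Rarity filter (groups present in ≥ 4 tows), the slick-associated
classification (ratio ≥ 2 or slick-exclusive), debris regressions, and
ANOVA/ANCOVA confound screens for survey design factors are included.

## Input tables

Four headered CSVs (UTF-8, comma-separated):

| file | required columns |
|---|---|
| `tows.csv` | `tow_id, habitat (slick/ambient), site, volume_filtered_m3` (+ optional `pair_id, year, day, gear, minutes_from_solar_noon, sampling_order, tow_length_m, distance_to_shore_m`) |
| `counts.csv` | `tow_id, taxon_id, count` (+ optional `life_stage, total_length_mm`) |
| `taxa.csv` | `taxon_id, family, natal_habitat, functional_group` (+ optional `rank, fishery_flag`) |
| `debris.csv` | `tow_id, category (plastic/organic), dry_weight_mg` |

## Worked example

```python
import slicksurvey as ss

survey, truth = ss.simulate_survey(ss.default_config(seed=1))
dens = ss.compute_densities(survey, grouping="functional_group")
table = ss.ratio_summary_table(dens, nboot=2000, nperm=2000, seed=1)
print(table[["ratio_mean", "bi_low", "bi_high"]].round(2))
```

prints

```
                    ratio_mean  bi_low  bi_high
group
egg                       3.10    1.96     4.86
fish                      6.86    6.28     7.48
holozooplankton           3.99    3.12     5.01
insect                   21.09   13.83    31.33
invertebrate_larva        5.94    5.14     6.84
```

Each row says how many times denser that group is inside slicks (with its
95% bootstrap interval); the generating enrichments for this seed were
3.1 (eggs), ~7 (fish, density-weighted), 4.0-ish (holozooplankton), 26.6
(insects), and 2–10 (invertebrate larvae) — all recovered within their
intervals. Regional scaling of a 7.2× fish ratio at 8.3% slick cover:

```python
>>> ss.percent_in_slicks(0.083, 7.2)
39.46...
```

i.e. ~39% of all neustonic larval fish in the region are inside slicks
despite slicks covering one-twelfth of the surface. The scripts in
`examples/` walk through each capability (simulation, enrichment ratios,
ordination, size-occurrence modelling, scaling, confound screens).

A thin CLI mirrors the library:

```sh
slicksurvey simulate --seed 1 --out survey/
slicksurvey compare survey/ --nboot 10000 --seed 1 --out compare.csv
slicksurvey report --seed 1 --out run/      # full pipeline + manifest
```

## Layout

- `src/slicksurvey/` — `data_model` (tables, densities, filters),
  `simulate` (synthetic surveys), `resampling` (bootstrap/permutation),
  `community` (diversity, Bray–Curtis, dbRDA, Spearman screens),
  `size_debris` (histograms, beta regression, debris models, confounds),
  `scaling` (regional percentages), `pipeline` + `cli`.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
- `examples/` — narrative scripts, one per capability.
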