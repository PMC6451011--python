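# somnotype

Accelerometer-based sleep phenotyping and downstream genetic-epidemiology
utilities, exercised end-to-end on synthetic wrist-accelerometer cohorts with
known ground truth:

* **`synthetic_cohort`** — generates epoch-level recordings (z-angle, ENMO
  magnitude, wear mask) with a ground-truth diary of sleep windows, episodes,
  naps and non-wear gaps, calibrated to a 7.30 h mean nightly sleep duration
  and a 27.32 h least-active-5-h (L5) midpoint.
* **`signal_features`** — z-angle from tri-axial means, absolute successive
  change, centred 5-min rolling-median change metric, raw-to-epoch
  aggregation, epoch-CSV I/O.
* **`sleep_detection`** — the sleep-period-time-window heuristic
  (adaptive 10th-percentile threshold, ≥30-min inactivity bouts, <60-min
  merging, longest block) and ≤5°/≥5-min sleep-episode detection.
* **`phenotypes`** — the eight per-individual sleep measures (duration and
  its SD, efficiency, episode count, sleep midpoint, L5/M10 midpoints,
  diurnal inactivity), the sequential exclusion cascade (device flags,
  Q3 + 1.5 × IQR counters, 3–12 h duration bounds, 5–30 episode bounds),
  rank-based inverse-normal transform and OLS residualisation.
* **`gwas_post`** — summary-statistic parsing and accounting, allele
  alignment, per-locus variance explained (2 f (1−f) β²), exact binomial
  sign tests, inverse-variance meta-analysis, combined lead-SNP effects and
  the genomic-control lambda.  A transcribed 47-row association table ships
  as a packaged fixture (`somnotype/data/table3.tsv`).
* **`mr`** — two-sample Mendelian-randomisation estimators (IVW with
  multiplicative random effects, MR-Egger, weighted and penalised weighted
  median with parametric-bootstrap SEs), Cochran's-Q diagnostics with
  iterative Bonferroni pruning, and allele harmonisation.

## CLI

```bash
somnotype simulate --config cohort.yaml --out DIR --seed 7      # synthetic cohort + truth.tsv
somnotype detect   --epochs DIR --out nights.tsv                # SPT windows + episodes per night
somnotype derive   --epochs DIR --out phenotypes.tsv \
                   --exclusion-log exclusions.tsv               # eight phenotypes + cascade
somnotype gwas-post count --threshold 8e-10 [--trait "L5 timing"]
somnotype gwas-post ve --trait "Sleep midpoint"
somnotype gwas-post signtest -k 18 -n 20
somnotype mr run --instruments inst.tsv --methods ivw,egger,wm,pwm --prune
```

`cohort.yaml` keys mirror `GeneratorConfig` fields (e.g. `n_individuals`,
`n_days`, `nap_probability`); detection constants (threshold multiplier,
floor/cap, window lengths) come from a YAML mapped onto `DetectionParams`.

## Conventions worth knowing

* Days are split noon-to-noon so one nocturnal sleep bout is never cut; all
  timings are hours since the *previous* midnight (2 a.m. = 26).
* The rolling median is centred with shrinking edge windows; percentiles and
  quartiles use linear interpolation (type 7).  Both conventions are fixed
  and bit-exactly tested against brute-force oracles.
* Sleep-episode runs break on changes strictly larger than 5°; inactivity
  bouts need ≥ 30 min; blocks merge across gaps strictly shorter than 60 min.
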