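# fixverse

Multiverse analysis of eye-movement data-cleaning pipelines for sentence
reading. The package implements, as a tested and reusable toolchain:

* a **synthetic data generator** for fixation-level reading datasets —
  counterbalanced high-/low-frequency target words with calibrated Zipf and
  word-length statistics, ex-Gaussian single fixation durations with crossed
  subject/item random intercepts, a frequency effect loading on both the
  mean and the tail, and injected artifact fixations (very short fixations
  near or far from longer hosts, overly long fixations, near-empty trials);
* a **four-stage fixation cleaning function** with every threshold
  parameterized (merge < 80 ms within 0.5°, merge < 40 ms within 1.25°,
  collapse runs of ≥ 3 sub-140 ms same-interest-area fixations, remove
  durations outside [140, 800] ms, optional outside-interest-area deletion)
  plus a 14-entry configuration catalog;
* **preprocessing**: minimum-fixation trial filtering, single fixation
  duration (SFD) extraction via a first-pass run definition, and SD-based
  outlier trimming against grand / per-subject / per-subject-by-condition
  means;
* **three mixed-model families** on the SFD table — identity LMM, log LMM,
  and an identity-link Gamma GLMM — with crossed subject/item random
  intercepts, Wald significance, and a back-transformed effect in ms;
* a **multiverse engine** that enumerates universes (cleaning × filter ×
  outlier rule × model), executes every pipeline, assembles the
  specification curve and decision dashboard, and runs the shuffled-label
  **permutation test** of the significant-universe count;
* **reporting**: specification-curve / dashboard / removal-vs-effect tables
  and plots, plus a run manifest.

## Command line

```bash
# generate a synthetic dataset (fixations.tsv, items.tsv, interest_areas.tsv)
fixverse simulate --config cfg.yaml --out run/ --seed 1

# apply one cleaning configuration
fixverse clean --in run/fixations.tsv --cleaning-id stage4_min80_max800 \
    --out cleaned.tsv --stats stats.json

# trial filter + SFD extraction + outlier trimming
fixverse preprocess --in cleaned.tsv --targets run/items.tsv \
    --min-fixations 3 --outlier-scope subject --outlier-k 2.5 --out obs.tsv

# fit one model family
fixverse fit --family lmm_log --in obs.tsv --out result.json

# full multiverse + permutation test
fixverse run --data run/fixations.tsv --items run/items.tsv \
    --out results/ --seed 1 --n-perm 500

# plots from the universes table
fixverse report --universes results/universes.tsv --out plots/
```

The YAML run configuration has sections `synthetic`, `cleaning_catalog`,
`filters`, `outliers`, `models`, `permutation`; omitted sections fall back
to the replication defaults (14-entry catalog, filters 0/3/5, seven outlier
rules, all three model families).

## File formats

Fixation report (TSV, UTF-8, `.` decimal; `ia_index` empty when the
fixation is outside every word box):

```text
subject_id	trial_id	item_id	condition	fix_index	x_px	y_px	duration_ms	ia_index
s001	s001_i001	1	high	1	121.520	299.343	213.001	1
s001	s001_i001	1	high	2	214.377	301.172	186.214	2
s001	s001_i001	1	high	3	288.504	297.341	254.880	4
s001	s001_i001	1	high	4	342.612	300.129	48.710	
s001	s001_i001	1	high	5	401.300	302.150	232.330	5
```

Interest-area table (one row per word box, half-open `[min, max)` pixel
bounds, 1-based `ia_index`):

```text
item_id	ia_index	x_min_px	x_max_px	y_min_px	y_max_px
1	1	100.000	148.000	280.000	320.000
1	2	148.000	232.000	280.000	320.000
1	3	232.000	316.000	280.000	320.000
1	4	316.000	376.000	280.000	320.000
1	5	376.000	448.000	280.000	320.000
```

Observations table: `subject_id  item_id  condition  sfd_ms`.

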