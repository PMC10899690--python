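# somnorisk

Personalized online-learning pipeline for detecting **insomnia risk** from
longitudinal smart-bed sleep sessions.

Consumer "nearables" such as smart beds record months of nightly sleep and
cardio-respiratory summaries without the sleeper wearing anything. A natural
question for sleep epidemiology is whether those session records can flag
individuals whose Insomnia Severity Index (ISI) — a 7-item questionnaire,
items scored 0–4, total 0–28 — has crossed a clinically meaningful cutoff.
The twist is that insomnia expresses itself *individually*: one person's
"bad" night looks like another person's ordinary night, so a single
population-level (generic) classifier performs at chance, while a model
given even a handful of sessions from the target person discriminates well.
`somnorisk` implements and tests that whole argument end to end:

1. **synthetic cohort** (`somnorisk.cohort`) — a generative model of a
   longitudinal study: subjects with latent ISI-scale severity following a
   per-wave random walk, four questionnaire waves six weeks apart with
   nonresponse, per-night bed-presence intervals (split nights, naps,
   skipped nights) and nightly physiology
   `x_ij = mu + u_i + lambda * (s_ij + a_i - mu_ISI) + eps_ij`,
   where the subject offset `a_i` along the severity loading `lambda` hides
   each subject's severity *level* from a pooled model while leaving
   within-subject severity *changes* fully expressed.
2. **session processing** (`somnorisk.sessions`) — merges presence intervals
   separated by ≤ 2 h into one session (each re-entry = one bed exit), keeps
   the longest session per day, computes sleep debt
   `max(0, goal − sleep duration)` and a Sleep Regularity Index
   `SRI = −100 + 200 · P(same sleep/wake state at clock times 24 h apart)`
   over a trailing 14-day window of 1-minute epochs, and assembles the
   canonical 14-component feature vector (age, bed exits, breathing rate,
   gender, heart rate, HRV, percent motion, restful duration, session
   duration, sleep debt, sleep duration, quality score, SRI, time to fall
   asleep). Cohort inclusion: ≥ 3 answered waves and ≥ 120 retained sessions.
3. **ISI labeling** (`somnorisk.labeling`) — scores the ISI, assigns every
   session the ISI of the most recent answered wave (carry-forward, with
   backfill before the first answered wave), and binarizes at thresholds
   8 / 10 / 15 (label = 1 iff ISI ≥ threshold).
4. **passive-aggressive classifier** (`somnorisk.pa`) — a from-scratch
   online linear classifier with hinge loss
   `ℓ = max(0, 1 − y(w·x + b))` and PA-I update
   `τ = min(C, ℓ / (‖x‖² + 1))`, `w ← w + τyx`, `b ← b + τy`
   (PA-II available). Passive when a sample is classified with margin ≥ 1,
   aggressive otherwise; the aggressiveness cap `C` defaults to 1. Features
   are z-scored with statistics frozen on the generic training stream. The
   generic fit reports the final-epoch trajectory average of the states
   (online-to-batch conversion); fine-tuning is a single chronological pass
   of raw PA updates over the target subject's first *k* sessions.
5. **evaluation** (`somnorisk.evaluate`, `somnorisk.metrics`) —
   leave-one-subject-out personalization sweep over thresholds × intervals
   {0, 1, 5, 10, 20, 30, 40, 50, 60}; accuracy/precision/recall aggregated
   across subjects (mean ± SD), F1 and rank-based AUC (Mann–Whitney, ties ½)
   pooled over all left-out predictions; incremental AUC
   `iAUC(k_i) = AUC(k_i) − AUC(k_{i−1})` with a structural zero at k = 0;
   a chronology-randomized control; paired t-tests between iAUC curves.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
60-subject cohort (seed 11) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_build_sessions.py
python analysis/03_label_sessions.py
python analysis/04_personalization_sweep.py
python analysis/05_chronology_control.py
python analysis/06_threshold_comparison.py
```

`04_personalization_sweep.py` prints:

```
pooled AUC by threshold and personalization interval:
threshold     8      10     15
interval
0          0.456  0.527  0.530
1          0.588  0.624  0.634
5          0.825  0.825  0.830
10         0.829  0.828  0.863
20         0.820  0.803  0.837
30         0.802  0.779  0.831
40         0.809  0.783  0.829
50         0.843  0.887  0.888
60         0.822  0.863  0.875
```

Read the first column top to bottom: the generic model, which has never seen
the evaluated subject, ranks their nights at chance (AUC ≈ 0.46–0.53);
fine-tuning on just five of their sessions lifts pooled AUC above 0.82 at
every ISI threshold; and almost nothing is gained beyond ten sessions. The
chronology-randomized control (`05`) shows no mid-interval degradation
(worst change vs k = 5 is +0.004), so the mild dip around k = 30 in the main
sweep is a property of the data's chronology, not of the learner. The
threshold comparison (`06`) finds no significant difference between the
iAUC curves of the three cutoffs (all p > 0.75).

The same pipeline is scriptable via the CLI
(`somnorisk simulate|prepare|label|evaluate|randomize|report|run`, each with
`--config <yaml> --seed <int> --out-dir <dir>`), and every run emits a
`run_manifest.yaml` from which it can be reproduced bit-identically.

## Layout

```
src/somnorisk/     library: cohort, sessions, labeling, pa, metrics,
                   evaluate, io, pipeline, cli
analysis/          numbered study drivers (thin wrappers over the library)
tests/             pytest suite (unit, property-based, end-to-end)
scripts/           acceptance script
docs/methods.md    model, assumptions, parameter choices, limitations
```
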