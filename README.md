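# foragekit

Sequential target-foraging choice models: simulation of a timed 15-target
harvesting task, a cost/softmax choice model with N-step look-ahead,
maximum-likelihood fitting with BIC model comparison, a rate-maximizing
planner, and diagnostic summaries.

## What it does

A trial presents 15 circular targets (radii 5/8/11 mm, values 10/12/15
points) on a jittered 3×5 grid; an agent has 3.25 s to harvest as many
points as possible, one target at a time. The package provides:

- **`foragekit.environment`** — conditions (`size`, `value`, `small_high`,
  `small_low`), randomized display generation, distance matrices, and the
  constrained-task (non-increasing value order) legality rule.
- **`foragekit.movement`** — per-radius linear movement-time regressions
  (`duration = intercept + slope · distance`) fitted by OLS, with
  hand-like (1.0 s/m, 0.2 s) and eye-like (0.9 s/m, 0.3 s) defaults.
- **`foragekit.choice`** — the step cost
  `c_ij = −v_j/t_ij + w1·d_ij^γ − w2·s_j`, exact look-ahead costs
  `C_j = min over ordered continuations of c_ij + Σ λ_t·c(step t+1)`
  (depths 1–5), softmax choice probabilities with precision β, and the
  pooled session log-likelihood over harvests 2–8 of every trial
  (vectorized `SessionLikelihood` cache for fitting).
- **`foragekit.fitting`** — Nelder-Mead maximum likelihood with random
  restarts (β, γ log-transformed), `BIC = −2 lnL + k lnN`, submodel and
  look-ahead-depth comparison grids, normalized look-ahead weights.
- **`foragekit.agents`** — model / uniform / greedy / planner agents under
  the trial clock, full-session simulation (4 × 50 free trials, 3 × 50
  constrained), the exhaustive 5-deep rate-maximizing planner (re-planned
  every harvest), and efficiency ratios versus the planner.
- **`foragekit.summaries`** — model-vs-data selection diagnostics
  (top-target hit rate, taken-target probability and rank, chance level
  `1/(16−h)`), tier selection proportions by harvest, distance
  histograms, and the constrained-task 120-permutation path ranking.
- **`foragekit.session_io` / `foragekit.pipeline` / `foragekit.cli`** —
  JSONL and paired-CSV session formats (mm units on disk, meters in
  memory), a seeded simulate→fit→compare→summarize pipeline with a
  hash manifest, and a `foragekit` console command.

## CLI

```bash
foragekit simulate --agent model --trials 50 --seed 1 --noise-sd 0.05 --out session.jsonl
foragekit fit-mt session.jsonl --out movement_time.json
foragekit fit session.jsonl --lookahead 1 --restarts 10 --seed 1 --out fit.json
foragekit compare session.jsonl --mode lookaheads --depths 1,2,3 --out depths.csv
foragekit plan session.jsonl --out efficiency.json
foragekit summarize session.jsonl --fit-json fit.json --out-dir summaries/
foragekit demo --out-dir demo_out --seed 0      # small end-to-end run
foragekit run --config pipeline.yaml            # YAML-configured pipeline
```

Every stage derives its seed deterministically from the global seed, and
`manifest.json` lists each artifact with a SHA-256 hash; rerunning the same
configuration reproduces identical files.

## Session file schema (JSONL)

Line 1 header:
`{"schema": "foragekit-session", "version": 1, "units": "mm", "effector": ...,
"constrained": ..., "movement_model": {...}}` — then one object per trial:
`trial_id`, `condition`, `start_mm`, `targets`
(15 × `{id, x_mm, y_mm, radius_mm, value}`), `harvests`
(`{harvest_index, chosen, origin, dt_s}` with `origin = -1` for the start
position). The paired-CSV format writes `<base>.displays.csv`,
`<base>.harvests.csv` and `<base>.meta.json` with the same content. Files
declaring `"units": "m"` are converted on read.

## Notes

- Units are SI internally (meters, seconds, points); `w1` and `w2` are
  therefore unit-bound (per m^γ and per meter of radius).
- When fewer targets remain than the look-ahead depth, the horizon
  truncates to the remaining count.
- In the `no_reward_rate` submodel β is fixed at 1 (only β·w1 and β·w2
  would be identified), giving the documented free-parameter counts
  (full: n+3; no_size / no_reward_rate: n+2; no_distance: n+1).
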