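# emonet

Personalized emotion-network analysis of ecological momentary assessment
(EMA) time series.

For each participant, a lag-1 vector-autoregressive (VAR) model is fitted
to a 5-node subset of affect items: each item at slot *t* is regressed
(OLS, intercept, no penalization) on all subset items at slot *t−1*. The
5×5 coefficient matrix is the **directed network** (diagonal =
autoregression/inertia); the partial correlations of the regression
residuals form the symmetric **contemporaneous network**. Each network is
summarized by its **connectivity** — the signed sum of its edges.

On top of this core, the package provides:

- **Exhaustive subnetwork enumeration** — all C(n, 5) item subsets (4,368
  for a 16-item pool; 462 for 11 items), with per-participant connectivity
  in every subnetwork, per-person average connectivity, and per-subset
  cross-participant correlations with an outcome (per-analysis 3-SD
  outlier removal, two-sided p-values).
- **Outcome models** — connectivity vs. baseline depression, week-8
  depression, and the SD of weekly depression sum scores; control
  regressions (standardized OLS); a held-out-item proxy SD for designs
  without repeated questionnaires; and the node-valence analysis
  (negative-item count vs. association strength).
- **Stability** — case-dropping bootstrap CS coefficients (participants or
  assessment slots as the dropped unit) and cross-sample edge-vector
  correlations of exemplar (edge-averaged) networks.
- **Temporal analysis** — weekly contemporaneous connectivity from
  week-partitioned residuals, and pooled lagged regressions testing whether
  connectivity precedes or follows weekly depression.
- **Synthetic cohorts** — stationary per-person VAR(1) generators with a
  between-person connectivity gradient (γ), valence-structured couplings,
  MCAR missingness, Likert/VAS/continuous scales, and weekly depression
  scores driven by negative affect, so every stage is testable end to end
  without any real data.
- **Inclusion filtering** — ≥75% assessment completion and ≥7 of 9 weekly
  questionnaires (both configurable), plus per-item detrending/z-scoring.

## Test

```sh
python -m pytest -q tests/
```

The suite includes an acceptance module (`tests/test_acceptance.py`)
checking combinatorial counts, oracle equivalence of the estimators,
parameter recovery, null calibration of the subnetwork association
machinery, headline-direction recovery on a γ-gradient cohort, and
stability behavior.

## Command line

Every pipeline stage is a subcommand of `emonet`:

```sh
emonet simulate --n-participants 50 --n-items 16 --design neureka \
    --base-coupling 0.05 --seed 1 --out data/

emonet preprocess --ema data/ema.csv --depression data/depression.csv \
    --valence data/valence.json --out filtered/

emonet fit --ema data/ema.csv --valence data/valence.json \
    --participant p0001 --subset neg01,neg02,neg03,pos01,pos02 --out fit.json

emonet enumerate --ema data/ema.csv --depression data/depression.csv \
    --valence data/valence.json --outcome sd_depression --out enum.json

emonet stability --ema data/ema.csv --valence data/valence.json \
    --subset neg01,neg02,neg03,pos01,pos02 -B 500 --out stab.json

emonet analyze --ema data/ema.csv --depression data/depression.csv \
    --valence data/valence.json --out analysis.json

emonet temporal --ema data/ema.csv --depression data/depression.csv \
    --valence data/valence.json --out temporal.json
```

EMA data travel as long-format CSV (`participant, assessment_index, item,
value`), depression scores as `participant, week, score` (week 0 =
baseline), and the item→valence map as JSON. Results are written as JSON
with full double precision.

## Layout

| Module | Role |
| --- | --- |
| `emonet.model` | `EmaPanel`, `DepressionSeries`, `Cohort` containers |
| `emonet.io` | long-format CSV readers/writers, JSON results |
| `emonet.simulate` | generative VAR(1) cohort simulator |
| `emonet.preprocess` | inclusion rules, detrend/standardize |
| `emonet.networks` | VAR fit, directed + contemporaneous networks |
| `emonet.enumeration` | subset enumeration, connectivity matrix, associations |
| `emonet.stability` | case-dropping bootstrap CS, cross-sample correlation |
| `emonet.outcomes` | outcome table, correlations, control regressions |
| `emonet.temporal` | weekly connectivity, before/after lagged models |
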