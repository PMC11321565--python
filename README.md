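# hivetrax

Analysis toolkit for RFID hive-entrance monitoring of honeybees
(*Apis mellifera*), built for studies that tag drones and worker bees with
passive UHF transponders and log every passage through a dual-antenna tunnel
reader at the hive entrance.  It was written for a comparison of native dark
bees (*A. m. mellifera*, "Mel") and hybrid Buckfast ("Buck") colonies over
one Swedish mating season, but the machinery is generic.

## What it does

* **Event processing** (`hivetrax.events_io`) — parse registration logs,
  infer movement direction from raw antenna reads (outer→inner = arrival,
  inner→outer = departure, lone read = unknown), convert UTC timestamps to
  local civil time, label the four diurnal intervals (MORNING 06–11,
  MIDDAY 11–16, EVENING 16–21, NIGHT 21–06), and build the zero-filled
  per-hive hourly count table with hourly weather covariates.
* **Flights** (`hivetrax.flights`) — pair each departure with its subsequent
  arrival (at any hive; drift is flagged) and classify durations into the
  behaviour categories <3, 3–10, 10–30, 30–60 and >60 minutes.
* **Survival** (`hivetrax.survival`) — operational lifespans (tagging date to
  last registration), Kaplan–Meier product-limit curves with Greenwood
  variance, the k-sample log-rank test, and cohort summary tables.
* **Classic statistics** (`hivetrax.classic_stats`) — Mann–Whitney rank test
  (exact by enumeration for small samples, tie-corrected normal
  approximation otherwise), Spearman correlation on midranks, per-day
  count-vs-weather correlations, and Type-II-sum-of-squares factorial ANOVA
  with Tukey HSD.
* **Count model** (`hivetrax.zinb_glmm`) — the core of the package: a
  zero-inflated negative-binomial (NB1) mixed model for hourly entrance
  counts,

  ```
  counts ~ Age + Temperature + Light + Wind + Timeinterval + Subspecies
           + Subspecies:Age + Subspecies:Temperature + Subspecies:Light
           + Subspecies:Wind + Temperature:Light - 1
           + (1 | Colony) + (1 | Season),     ziformula: ~ Hour - 1
  ```

  with `Var(y|u) = φ·μ` (`φ ≥ 1`), structural-zero probability
  `logit p = γ·hour`, and crossed colony/season random intercepts integrated
  out by a joint Laplace approximation.  Includes VIF screening, backward
  AIC model selection, Wald inference with Satterthwaite effective degrees
  of freedom, and effect grids.
* **Simulator** (`hivetrax.synthetic_data`) — a full generative twin of the
  study: roster over two tagging cohorts, gamma lifespans, weather-driven
  afternoon-peaked activity, drift, and a dual-antenna detection model whose
  miss probability grows with entrance traffic (the mechanism behind the
  zero inflation).  Ground truth accompanies every output.
* **Pipeline & CLI** (`hivetrax.pipeline`, `hivetrax` command) — one
  deterministic run from raw files to a directory of tidy CSV report tables.

## Worked example

```bash
hivetrax demo --out demo --seed 42
cat demo/report/summary.txt
```

which prints (abridged; a simulated 2022-05-02 → 2022-07-15 study):

```
registrations parsed: 32050 (0 malformed lines)
drones: 147/180 registered (81.7%), mean lifespan 21.6 d (max 59)
workers: 119/160 registered (74.4%), mean lifespan 14.7 d (max 57)
log-rank drone spring vs summer: Chisq = 23.1, p = 1.51e-06
log-rank drone Buck vs Mel (summer): Chisq = 0.0, p = 0.959
Mann-Whitney drone first activity spring vs summer: W = 2597.0, p = 0.9
flights reconstructed: 8279
drone Buck daily rho(temperature): median 0.91
GLMM chosen model: drone-final (AIC 13977.5); zero-inflation hour slope -0.449; phi 1.98
```

Reading the numbers: 81.7% of tagged drones were ever detected; spring-tagged
drones outlive summer-tagged ones (the log-rank χ² on the Kaplan–Meier
curves); daily activity tracks temperature (median per-day Spearman ρ of
0.91); and the fitted count model picks the specification with the
temperature × light interaction and estimates a negative hour slope in the
zero-inflation part — busy afternoon hours are the ones in which the reader
misses whole hours of traffic.  Full tables (KM curves, ANOVA + Tukey,
flight categories, coefficient/deviance/effect tables) are written as CSV
next to `summary.txt`.

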