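# reciprosim

Seeded simulation and analysis of a dyadic perceptual advice-taking
experiment: a synthetic human participant and a stochastically controlled
partner agent (framed as either a computer or a humanoid robot) jointly
estimate visual lengths, revise their answers after seeing each other's
responses, and the pipeline recomputes all behavioral indices and
statistical contrasts from the resulting trial logs.

The package contains:

- `reciprosim.design` — deterministic trial/block/turn schedules for the
  three tasks (66 solo trials; 66 joint decision trials; 176 reciprocal
  trials with alternating decision/observation turns, a transition block
  and a final block), plus counterbalanced cohort construction.
- `reciprosim.stimuli` — the 11-length stimulus grid (8–16 cm, step
  0.8 cm, design mean 12 cm) and balanced shuffled sequences.
- `reciprosim.agent` — the partner's behavior: Gaussian perceptual
  estimates (SD 1.52 cm) with a proximity resampling rule,
  condition-specific influence mixtures (Susceptible / Unsusceptible),
  the fixed 11-interval transition schedule, and linear final decisions.
- `reciprosim.participant` — the generative human model: a
  central-tendency observer (Weber-scaled sensory noise, running prior)
  and a logit-linear influence policy with distance, condition and
  final-block effects, plus a performance-rating generator.
- `reciprosim.metrics` — influence index, relative estimation error,
  regression index, underestimation, normalized response distance, and
  the standardized-distance influence binning.
- `reciprosim.stats` — Wilcoxon signed-rank / rank-sum with r and η²
  effect sizes (exact below n=10), Spearman correlation (permutation p
  for small n), Bonferroni decisions, and participant-level
  random-intercept linear models with Wald z inference.
- `reciprosim.pipeline` — cohort simulation, the full analysis report
  (aggregates, distance-bin tables, models 1–6), and calibration of the
  generative parameters toward target group statistics.

## CLI

```sh
# Simulate a cohort with the shipped calibrated defaults
reciprosim simulate --seed 1 --out runs/demo

# Analyze a trial log (CSV in, CSV/JSON report out)
reciprosim analyze --log runs/demo --out runs/demo/report

# Print headline statistics
reciprosim report --log runs/demo

# Re-calibrate generative parameters toward target statistics
reciprosim calibrate --seed 0 --out calibrated_config.yaml
```

Simulation is a pure function of the YAML config (see
`reciprosim.config.RunConfig`); per-participant random substreams are
spawned from the master seed, so results are reproducible and stable
under cohort-size changes.

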