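# schemabg

Schema selection with basal-ganglia arbitration on two rule-induction tasks:
the Wisconsin Card Sorting Test (WCST) and a circular-layout Brixton Spatial
Anticipation Test (BRXT).

The package provides:

- **`schemabg.tasks`** — deterministic task environments: the 64-card
  factorial WCST deck with four fixed target piles and rule switches after
  every run of six correct sorts; a 9-position circular BRXT with five
  sequential covert rules, ten trials each.
- **`schemabg.scoring`** — the error taxonomies: WCST total errors (TE),
  Heaton-style perseverative errors (PE), three-correct set-loss errors
  (SL3) and categories achieved (CA); BRXT total errors plus stimulus,
  response, and rule perseverations (PSTIM / PRESP / PRULE); mean RT
  conditioned on previous-trial feedback.
- **`schemabg.model`** — the neurocomputational model: per-schema
  cortico-striato-thalamic loops (CTX, striatum D1/D2, STN, GPe, GPi,
  thalamus) of logistic units implementing selective disinhibition, with
  conflict-driven sensorimotor gain adaptation and reward-prediction-error
  learning of striatal thresholds. Four free parameters: mismatch reward
  sensitivity `w_neg`, memory for negative feedback `m_r`, striatal learning
  rate `eps_str`, sensorimotor learning rate `eps_sma`. The inner cycle loop
  is numba-JIT compiled when numba is available (a full 64-trial session
  runs in ~10 ms).
- **`schemabg.fitting`** — simulated-annealing fits of the free parameters
  to published group summary statistics (z-norm objective with a JZS
  Bayes-factor tiebreak), group-swap cross-fits, and full-range
  `w_neg x eps_str x eps_sma` grid scans per `m_r` plane.
- **`schemabg.stats`** — the experimental statistics battery: Mann-Whitney
  W on the `[0, n_x*n_y]` scale, uncorrected Pearson chi-square, two-sample
  JZS Bayes factors (Cauchy prior, scale 1/2), log-RT 2x2 mixed ANOVA,
  Pearson and partial correlations, and the normative regression for BRXT
  total errors.
- **`schemabg.synth`** — synthetic stochastic-agent cohorts (tunable lapse /
  perseveration / stimulus- and response-pull propensities, group
  demographics) so every downstream stage is testable without any data
  download. The agent is deliberately independent of the dynamical model.

## Command line

The console script `schemabg` exposes the main workflows:

```sh
# synthetic two-group cohort: trial logs + score tables
schemabg synth --task both --n 25 --profile younger --profile older --seed 1 --out cohort/

# simulate a 25-run group at given parameters
schemabg simulate --task wcst --w-neg 0.2 --eps-str 0.6 --eps-sma 0.4 --n 25 --seed 1

# fit free parameters to a group's published summary statistics
schemabg fit --task wcst --group younger --seed 1 --iters 150 --out fit.json

# full-range parameter grid scan (long-format CSV, one slice per w_neg)
schemabg scan --task brxt --mr 0.0,0.1,0.2,0.3 --step 0.1 --runs 25 --seed 1 --out grid.csv

# score existing trial-log CSVs
schemabg score --task wcst cohort/younger_001_wcst.csv
```

Trial logs are plain CSV (`participant_id, task, trial, stimulus, response,
correct, feedback, active_rule, rt`); model parameters and agent profiles
round-trip through JSON/YAML.

## Notes

- Fixed dynamics constants (inter-nucleus weights, gains, selection
  thresholds, noise scales) are not published for the original model; the
  defaults in `schemabg.model.Dynamics` were chosen so that the selection
  invariants hold. Absolute cycle counts are therefore implementation
  relative; only orderings and fitted-error statistics are meaningful.
- `run_session` / `run_group` / `gen_cohort` are deterministic given a seed
  at every level.
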