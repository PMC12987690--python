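# mstp

Sparse **m**ulti-**s**tage stationary **t**reatment **p**olicies from
micro-randomized-trial data: doubly robust (AIPW) policy search with an L1
penalty on the unit ball, and valid per-coefficient inference via
decorrelated-score one-step estimators with trajectory-bootstrap confidence
intervals.

## What it does

Given longitudinal trajectories — per subject and stage: a feature vector, a
binary action in {−1, +1}, a reward, and the known behavior-policy
probability of the taken action — the package:

1. evaluates any sigmoid policy `pi(a|x) = sigmoid(a(θ0 + xᵀθ)/τ)` through a
   self-normalized, stage-wise importance-weighted AIPW loss;
2. fits stage-wise augmentation (Q) models: none (`m=0`),
   backward-recursive penalized regression (`m=1`), or a
   variance-minimizing weighted regression (`m=2`);
3. finds a sparse policy by proximal coordinate descent under
   `‖θ‖₂ ≤ 1` with cross-validated penalties, multi-start, and a
   trust-region refit on the selected support;
4. produces per-coordinate one-step estimates (Dantzig-selector
   decorrelation via linear programming, numeric symmetric-difference
   gradients/Hessians) and bootstrap percentile confidence intervals, with
   plug-in normal intervals as a secondary output;
5. regenerates the two synthetic scenarios (EWMA dynamics, Gaussian
   innovations, uniform behavior policy) so the whole pipeline is testable
   without external data, including on-policy Monte-Carlo evaluation,
   normalized-IPW evaluation on held-out data, and sphere grid search for
   the optimal restricted policy.

## CLI

All commands read a YAML config (one block per command; unknown keys are
rejected) and write CSV/JSON under `--out`:

```bash
mstp simulate --config config.yaml --seed 1 --out runs/
mstp fit      --config config.yaml --seed 1 --out runs/
mstp infer    --config config.yaml --seed 1 --out runs/
mstp evaluate --config config.yaml --out runs/
```

Example config:

```yaml
simulate:
  scenario: 2        # 1 or 2
  n: 400
  T: 5
  d: 20
  seed: 1
fit:
  data: runs/dataset.csv
  tau: 0.2
  method: 1          # augmentation: 0, 1 (backward), 2 (variance-minimizing)
infer:
  data: runs/dataset.csv
  method: 1
  B: 100             # bootstrap samples
  alpha: 0.05
evaluate:
  policy: runs/fit.json
  estimators: [on_policy, ipw]
  data: runs/dataset.csv
  scenario_config: {scenario: 2, n: 1, T: 5, d: 20, seed: 2}
```

## Layout

```
src/mstp/
  data_model.py   trajectory container, CSV I/O, trajectory bootstrap
  policy.py       sigmoid policy class, sampling, importance weights
  nuisance.py     basis features and the three augmentation estimators
  objective.py    AIPW loss, batched evaluation, numeric derivatives
  optimizer.py    proximal CD, multi-start, support refit, lambda tuning
  inference.py    Dantzig decorrelation, one-step estimates, bootstrap CIs
  simulation.py   scenario generators, policy evaluation, grid search
  cli.py          simulate / fit / infer / evaluate commands
```
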