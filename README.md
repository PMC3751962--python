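# trackmodes

Inferring what a moving forager is *doing* from where it *is*: given a
trajectory of timestamped positions, reconstruct the sequence of latent
behavioural modes (here: **cruising**, **searching**, **fishing** for
anchovy purse-seiners tracked by a Vessel Monitoring System at roughly one
position per hour).  The package is an analysis stack for comparing, under
a supervised protocol, the three families of models used for this task in
movement ecology:

- **HMM** — a first-order hidden Markov model at the *step* scale:
  initial probabilities π, step transition matrix `a_ij`, and
  state-conditional emission densities `b_i(y)` with the observed
  variables mutually independent given the state.  Self-transitions imply
  geometric mode durations.
- **HSMM** — a hidden *semi*-Markov model at the *segment* scale: an
  explicit continuous duration density `d_j(u)` per mode, transitions only
  between distinct modes, and a survival term `S_j(u) = P(U ≥ u)` for the
  right-censored final segment of a trip.  Global decoding is by a
  forward–backward Viterbi dynamic programme over (step, mode, segment
  length).
- **Discriminative baselines** — random forest, Gaussian-kernel SVM and a
  one-hidden-layer perceptron, predicting each step independently, tuned
  by classification accuracy on a held-out share of the training rows.

Because the groundtruthed VMS/observer dataset these methods were built
for is confidential, the package ships a first-class **semi-Markov
trajectory simulator** that emulates it (trips start cruising, fishing
lasts ~2 h on average with lognormal durations, searching segments can be
as short as 30 min), so every stage — feature extraction, distribution
fitting with Cramér–von Mises goodness-of-fit and AIC selection,
supervised training, decoding, and segment-scale evaluation — is testable
end to end.

## Layout

```
src/trackmodes/     the library
  features.py         positions -> speed, heading, speed/turn changes per step
  dists.py            the univariate families (GEV, GPD, mixtures, wrapped
                      Cauchy, Kumaraswamy, ...), ML fits, CvM GOF, AIC selection
  markov_models.py    HMM + HSMM training, joint log-likelihoods, Viterbi and
                      duration-explicit Viterbi decoders
  discriminative.py   RF / SVM / ANN with accuracy-driven grid tuning
  evaluation.py       step & segment metrics, trip-level cross-validation,
                      randomization tests, the sampling-rate experiment
  synthetic_data.py   the semi-Markov trip simulator and default scenarios
analysis/           numbered drivers writing tables under results/
scripts/acceptance.py   recomputes the headline simulation numbers
tests/              pytest suite incl. decoder-vs-enumeration oracles
```

## Worked example

Simulate a labelled fleet, train both Markovian models on half of it, and
decode the other half:

```python
import warnings
import numpy as np
from trackmodes.synthetic_data import make_fishery_scenario, simulate_trips
from trackmodes import markov_models as mm
from trackmodes.evaluation import compute_metrics
from trackmodes.features import VARIABLES

cfg = make_fishery_scenario(seed=1)
trips = [t.features for t in simulate_trips(cfg, 40, seed=5)]
train, val = trips[:20], trips[20:]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")          # small-sample fit warnings
    hsmm = mm.train_hsmm(train, VARIABLES)

pairs = []
for feats in val:
    decoded = mm.decode_hsmm_viterbi(hsmm, feats)
    truth = mm.StateSequence(feats["mode"].tolist(), feats["dt"].to_numpy())
    pairs.append((truth, decoded))
report = compute_metrics(pairs)
print(f"accuracy {report.accuracy:.1f}%  mean accuracy {report.mean_acc:.1f}%")
print({m: round(v['f1'], 1) for m, v in report.per_mode.items()})
```

On this seed the run prints

```
accuracy 84.2%  mean accuracy 75.1%
{'cruising': 96.7, 'fishing': 87.0, 'searching': 57.2}
```

i.e. about 84% of hourly steps get the correct mode; cruising segments
are recovered almost perfectly, fishing well, and searching — short
segments with speeds overlapping both neighbours — is the hard mode, with
a segment-level F1 near 57%.  The fitted model also records the selected
distribution family per mode and variable (for fishing durations the
lognormal and its close cousins win, depending on the simulated sample).

The numbered drivers reproduce the full comparisons:

```
python analysis/01_simulate_fishery.py          # write the synthetic fleet
python analysis/02_distribution_selection.py    # family selection table
python analysis/03_model_comparison.py          # 5-model cross-validation
python analysis/04_resolution_experiment.py     # accuracy vs step size
```

On the default scenario the cross-validation ranks the models
HSMM ≥ HMM > RF/SVM/ANN on mean segment F1, and the step-independent
classifiers show the characteristic *over-segmentation*: an excess of
very short inferred segments relative to both the truth and the
duration-explicit model.

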