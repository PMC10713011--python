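# stablefc

Stable estimation of time-varying functional connectivity (FC) states
from multichannel neural time series.

## The problem

A hidden Markov model with zero-mean Gaussian states is a standard
descriptor of time-varying FC: given recordings `X` (time points x
channels, concatenated across sessions and subjects), each hidden state
k is a Gaussian `N(0, Sigma_k)` whose full covariance `Sigma_k` is one
recurring connectivity pattern, and the posterior state probabilities
`Gamma` (time x states) say when each pattern is active:

    X_t | S_t = k ~ N(0, Sigma_k)
    P(S_t = k1 | S_t-1 = k2) = theta_k1k2,  P(S_0 = k) = eta_k

The model is fit by variational inference, which minimizes the free
energy F (model fit plus complexity) from a random initialization —
so different runs on the *same* data can return different states.
`stablefc` implements the full inference plus two ensemble procedures
that tame this variability:

* **BR (best-ranked)** — run the inference R times, keep the run with
  the lowest free energy;
* **HC (hierarchical-clustered consensus)** — stack all M = R x K state
  time series, cluster them with Ward linkage on the correlation
  distance `D = 1 - P`, and aggregate each cluster into one consensus
  state (averaged, rescaled series; occupancy-weighted covariance).

Runs are compared after optimally pairing their states (Hungarian
algorithm on summed joint probabilities); the similarity
`1 - cost/max_cost` lies in [0, 1].  A synthetic generator with a
ground-truth state sequence and a tunable state-overlap dial stands in
for fMRI/MEG inputs, and a stability-evaluation suite (pairwise
similarity histograms, free-energy-sorted similarity matrices,
repetition-stability curves over R, per-state dynamics) quantifies how
reproducible each procedure is.

Intended users: anyone fitting state-based models of brain dynamics
(fMRI parcel time series, MEG power envelopes) who needs estimates
stable enough to relate to behavior.

## Worked example

```python
import numpy as np
from stablefc import (simulate, standardize, run_ensemble, select_best,
                      hc_hmm, align_states)
from stablefc.stability import pairwise_similarities, state_metrics

# four connectivity states, ten channels, four sessions
ts, truth = simulate(K=4, P=10, session_lengths=[2000]*4,
                     stay_prob=0.95, separation=2.0, seed=7)
ts = standardize(ts)

ens = run_ensemble(ts, K=4, R=10, base_seed=0)
print(f"mean between-run similarity: {np.mean(pairwise_similarities(ens)):.3f}")

best = select_best(ens)                      # BR-HMM
res = align_states(best.gamma, truth.indicator_series())
acc = np.mean(res.permutation[best.gamma.argmax(1)] == truth.true_path)
print(f"hard-path accuracy vs truth: {acc:.3f}")

model = hc_hmm(ens)                          # HC-HMM
print(f"consensus cluster sizes: {model.cluster_sizes.tolist()}")

m = state_metrics(best.gamma, ts.sessions)
print(f"occupancies: {np.round(m.fractional_occupancy, 3).tolist()}")
```

prints

```
mean between-run similarity: 0.901
hard-path accuracy vs truth: 0.992
consensus cluster sizes: [10, 8, 12, 10]
occupancies: [0.252, 0.246, 0.222, 0.28]
```

Reading: the ten runs agree well but not perfectly (0.901 — a couple of
runs settled in local optima), yet the best-ranked run recovers 99.2%
of the hidden state path.  The consensus clusters contain one state
from most runs each (sizes near R = 10); the deviant runs' states are
absorbed into the nearest family without corrupting the consensus.
Occupancies are near-uniform by construction of the generator.

The same pipeline is scriptable from the shell:

```sh
stablefc simulate --k 4 --channels 10 --sessions 4x2000 --separation 2.0 \
    --seed 7 --out data/
stablefc br --data data/data.csv --sessions data/sessions.txt \
    --k 4 --runs 10 --seed 0 --out br_out/
stablefc hc --data data/data.csv --sessions data/sessions.txt \
    --k 4 --runs 10 --seed 0 --out hc_out/
stablefc align --a br_out/state_series.csv --b hc_out/cluster_series.csv
```

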