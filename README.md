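# ddnet — EEG functional networks for auditory word/pseudoword cohorts

`ddnet` is a Python package for sensor-space EEG functional-network
analysis in two-group developmental studies — typically children with
developmental dyslexia versus typically reading controls performing
auditory discrimination of words and pseudowords. It covers the full
chain from band-limited epochs to group inference:

* **Connectivity** — the weighted Phase Lag Index (wPLI) per sensor pair,
  band and trial:
  `wPLI = |E[Im S]| / E[|Im S|]` for cross-spectra `S = X_a·conj(X_b)`,
  a phase-synchronization measure in [0, 1] that ignores zero-lag
  (volume-conduction) coupling.
* **Network topology** — Onnela weighted clustering `C`, characteristic
  path length `L` on `1/w` costs, and Small-World Propensity
  `ϕ = 1 − sqrt((ΔC² + ΔL²)/2)` with
  `ΔC = (C_latt − C_obs)/(C_latt − C_rand)` and
  `ΔL = (L_obs − L_rand)/(L_latt − L_rand)` against lattice and
  degree-preserving random surrogates built from the observed weights;
  node strength and Brandes betweenness centrality with 1-SD hub and
  important-edge rules.
* **Inference** — Kruskal–Wallis tests, label-shuffling permutation tests
  for the global measures, cluster-mass permutation tests on the sensor
  neighbourhood graph (FWER-controlled by the maximum-cluster-mass
  distribution), Bonferroni (α/3 ≈ 0.0167, α/2 = 0.025) and
  Benjamini–Hochberg corrections, hemispheric median comparisons.
* **Behaviour** — the Inverse Efficiency Score
  `IES = mean correct RT / proportion correct` and robust (Huber)
  regressions of IES on ϕ.
* **Synthetic cohorts** — a generator of phase-coupled oscillator EEG
  over planted Watts–Strogatz-style networks, with per-edge nonzero
  phase lags, stimulus-locked evoked components, artifacts and
  behavioural records, so that every stage above can be validated
  against a known ground truth without access to restricted clinical
  recordings.

The preprocessing stage mirrors the standard event-related workflow:
1–70 Hz broadband conditioning with a 50 Hz notch, seven zero-phase
Butterworth bands (δ, θ, α, β1, β2, γ1, γ2), ±200 µV artifact rejection,
a per-sensor SNR criterion, incorrect-response removal, and epoch-count
balancing across groups.

## Worked example

Simulate a small two-group cohort, preprocess one subject, estimate a
θ-band wPLI network and its small-world summary, then run the
end-to-end planted-deficit recovery experiment:

```python
from ddnet import (CANONICAL_BANDS, CHANNELS_40, default_cohort_truth,
                   simulate_cohort_epochs, reject_trials, filter_bands,
                   wpli_epochs, small_world_propensity)
from ddnet.graphs import threshold_proportional
from ddnet.pipeline import clustering_recovery_experiment

theta = CANONICAL_BANDS[1]
truth = default_cohort_truth(
    seed=42, bands=(theta,), montage_labels=CHANNELS_40[:24],
    n_subjects={"control": 4, "dd": 4},
    epochs_per_subject={"control": (20, 0), "dd": (20, 0)})
epochs = simulate_cohort_epochs(truth)

es = epochs["control"]["control00"]["word"]
kept, report = reject_trials(es)
print(f"subject control00: kept {kept.n_trials}/{es.n_trials} trials "
      f"({report.counts()['amplitude_rejected']} amplitude-rejected)")

banded = filter_bands(kept, (theta,))["theta"]
adj = wpli_epochs(banded, band="theta", mode="trials", debias=True)[0]
sparse = threshold_proportional(adj.values, 0.25)
res = small_world_propensity(sparse, n_random=30, seed=7)
print(f"theta-band SWP: phi={res.phi:.3f}  dC={res.delta_c:.3f}  "
      f"dL={res.delta_l:.3f}")

out = clustering_recovery_experiment(seed=42)
print(f"cohort recovery: dC control={out['delta_c_control']:.3f}  "
      f"dyslexic={out['delta_c_dd']:.3f}  p={out['p_value']:.4f}")
```

prints

```
subject control00: kept 20/20 trials (0 amplitude-rejected)
theta-band SWP: phi=0.693  dC=0.399  dL=0.171
cohort recovery: dC control=0.498  dyslexic=0.868  p=0.0010
```

The subject's θ network is a clear small world (ϕ ≈ 0.7: clustering much
nearer the lattice surrogate than the random one, path length near the
random surrogate). The recovery experiment simulates a 12 + 12 cohort
whose dyslexic-group networks carry a planted clustering deficit
(rewiring 0.5 vs. 0.1); the pipeline finds the deficit as a larger
clustering deviation ΔC in the dyslexic group — their networks sit
further from the lattice regime — significant at p = 0.001 under a
one-sided label-permutation test.

## Command line

```bash
ddnet simulate --config cohort.yaml --out cohort_dir   # epochs + truth
ddnet run      --config run.yaml                       # full analysis
ddnet report   <output_dir>                            # formatted summary
```

`ddnet run` writes tidy TSV/JSON tables: per-band global measures with
group means ± s.e., χ² and permutation p (Bonferroni and FDR flags), hub
and important-edge tables per band/condition/metric, cluster-mass
results, per-subject IES and robust efficiency fits, a trial-rejection
report, and a provenance record (config hash, seeds, versions). Runs
are pure functions of (config, seed): repeating one reproduces every
output byte-for-byte.

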