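# avcond

Analysis pipeline for **implicit audio–visual statistical learning in EEG**:
a sensory-conditioning paradigm in which two pure tones (A1, A2) are followed
by a Gabor patch with opposite conditional probabilities — P(V1|A1) = 0.9,
P(V2|A2) = 0.1 — while participants perform an unrelated target-detection
task. Over a 400-trial session the tones become implicit predictors of visual
stimulus presence or absence, and the package quantifies the neural
signatures of that learning:

* **ROI ERPs** — attenuation of evoked responses between the initial and
  final thirds of conditioning (expectation suppression) over frontal,
  temporo-parietal and parieto-occipital channel groups;
* **time-resolved decoding** — per-timepoint LDA (Ledoit–Wolf shrinkage,
  stratified 5-fold CV, AUC, permuted-label empirical chance) of A1 vs A2,
  with the activation-pattern (Haufe) transform for interpretable topographies;
* **pattern similarity** — the cross-validated Mahalanobis distance (cvMD)
  between audio-period (200–650 ms) and post-audio-period (0–550 ms)
  multichannel patterns, an unbiased dissimilarity whose decrease over
  learning indicates that the tone response comes to resemble the expected
  visual response;
* **hierarchical Gaussian filter (HGF)** — a 3-level binary Bayesian
  ideal-observer model of trial-wise learning. Outcomes follow
  x1 ~ Bernoulli(s(x2)); the log-odds tendency x2 performs a Gaussian random
  walk with step variance exp(κ·x3 + ω); the log-volatility x3 performs a
  random walk with variance ϑ. Inversion yields the level-2
  precision-weighted prediction error (pwPE)

      μ2(t) = μ2(t−1) + σ2(t) · (u(t) − s(μ2(t−1)))

  whose increment ε2 = σ2·δ1 is the single-trial learning signal.
  Bayes-optimal parameters minimise accumulated Bayesian surprise
  (BFGS from the prior means);
* **pwPE→EEG coupling** — mass-univariate OLS of single-trial amplitude on
  the pwPE trajectory (R² per channel–timepoint, ROI-averaged, against the
  pre-visual baseline, with an optional confound-partialling hook);
* **cluster statistics** — paired sign-flip permutation tests with maxsum
  cluster correction, Cohen's d and the JZS Bayes factor (Cauchy prior,
  scale √2/2) at cluster peaks.

Because no recordings of this paradigm are publicly available, the package
ships a first-class synthetic-data generator (`avcond.simulate`) that plants
each of these effects — amplitude attenuation, audio→visual pattern
convergence, pwPE-coupled post-stimulus amplitude — in 27-channel evoked
responses over spatially correlated 1/f noise, so the entire chain is
testable end to end.

## Worked example

```python
import numpy as np
import avcond as av

# a 400-trial conditioning schedule and its ideal-observer pwPE trajectories
schedule = av.generate_schedule(av.DesignConfig(seed=0))
pwpe = av.pwpe_per_condition(schedule)
tbl = pwpe["A1"]
print(f"A1 trials: {len(tbl)}, empirical P(V1|A1) = {tbl['u'].mean():.3f}")
print(f"mean |pwPE| on omissions (V0|A1):   {tbl.loc[tbl.u == 0, 'pwpe'].mean():.3f}")
print(f"mean |pwPE| on occurrences (V1|A1): {tbl.loc[tbl.u == 1, 'pwpe'].mean():.3f}")

# one synthetic participant: simulate, preprocess, decode the audio period
sub = av.simulate_subject(0)
ep = sub.epochs
nt = ep.meta["trial_type"].isin(["A1-trial", "A2-trial"]).to_numpy()
audio = ep.time_mask(0.0, 650.0)
data = ep.data[np.ix_(np.nonzero(nt)[0], np.arange(27), np.nonzero(audio)[0])]
res = av.decode_timecourse(data, ep.meta.loc[nt, "trial_type"].to_numpy(), seed=0)
t = ep.times[audio]
peak = res.auc.argmax()
print(f"peak A1-vs-A2 decoding AUC = {res.auc[peak]:.3f} at {t[peak]:.0f} ms")
print(f"mean AUC before the injection window (0-200 ms): {res.auc[t < 200].mean():.3f}")
```

prints

```
A1 trials: 180, empirical P(V1|A1) = 0.911
mean |pwPE| on omissions (V0|A1):   0.305
mean |pwPE| on occurrences (V1|A1): 0.044
peak A1-vs-A2 decoding AUC = 0.718 at 316 ms
mean AUC before the injection window (0-200 ms): 0.507
```

The rare visual omissions carry ~7× the prediction error of the expected
occurrences; the tones are decodable only after the audio-period pattern
begins to carry predictive (visual-like) information, and are at chance
before it. Group-level runs (`av.simulate_cohort` + `av.analyze_cohort`)
apply the full cluster-corrected statistics to a 21-subject cohort.

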