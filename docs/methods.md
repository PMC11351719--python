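# Methods

## Paradigm and schedule generation

A session is 400 trials in 10 blocks. Each block contains 4 perceptual
targets (randomly audio or visual, inserted at random positions) and 36
non-target trials split exactly evenly between the A1 and A2 tones and
shuffled. Visual outcomes are drawn i.i.d. per trial with P(V1|A1) = 0.9 and
P(V2|A2) = 0.1 (the remaining probability mass is stimulus absence, V0);
i.i.d. sampling is the simplest process consistent with a stated percentage
contingency. Trial timing: 100 ms fixation, tone onset 500 ms after fixation
offset, 600 ms tone, 50 ms gap, 500 ms visual interval, then an inter-trial
interval drawn uniformly in 2500 ± 500 ms (the distribution of the jitter is
a design choice; uniform is assumed). All onsets in the schedule are absolute
session times; V0 trials keep a nominal visual onset marking where the
stimulus would have appeared. Generation is bit-reproducible given the seed.

Learning phases ("initial"/"final") are chronological thirds within each
condition, earliest third largest when sizes differ. With 180 A1 trials of
which ~162 are V1|A1, a phase holds ~54 trials of the frequent outcome,
matching the session arithmetic. Phase size is determined by the data rather
than hard-coded.

## Channel layout

The 27 electrode sites use standard 10–5 positions (via MNE's template
montage). Only relative geometry matters: the 2-D coordinates are an
azimuthal-equidistant projection used for topographies, and the neighbour
graph connects channels within 1.75× the median nearest-neighbour distance —
on this sparse montage that leaves every channel ≥ 2 neighbours and the
vertex 4, which is what bad-channel detection needs.

## Synthetic EEG generator

The generator is the package's study-conditions definition, not a
convenience fixture. Evoked responses are rank-one templates
(spatial profile × waveform):

* auditory: fronto-central profile (Gaussian around Cz), biphasic
  N1/P2-like waveform, −4 µV at 100 ms and +2.5 µV at 200 ms;
* visual: occipital profile (around Oz), +4 µV at 120 ms and −2 µV at
  250 ms.

Three learning effects are planted, each with an explicit magnitude:

* **Attenuation** (default rate 0.3): a linear amplitude factor over
  normalised trial position, parameterised so the factor averages exactly 1
  over the first third of trials and 1 − rate over the last third — the
  phase-contrast semantics the ERP analysis measures.
* **Similarity injection** (default gain 0.6): on A1 trials a copy of the
  visual template, scaled by gain × position, is added to the audio period
  starting 200 ms after tone onset and truncated at the end of the tone+gap.
  This is the only source of A1/A2 decodability, so the decoding analysis
  has a known planted window (200–650 ms), and it drives the cvMD decrease
  between the audio-period and visual-period patterns.
* **pwPE coupling** (default 15 µV per unit pwPE): the supplied per-trial
  pwPE value, times an occipital spatial profile, is added uniformly over
  250–550 ms after the visual onset. The profile is spatially structured
  because a spatially uniform component would be annihilated by
  common-average referencing.

Noise is spatially correlated pink noise (per-channel 1/f sources mixed
through a Gaussian spatial kernel with 0.12 m length scale, chosen so
neighbour correlations sit in the 0.9–0.98 range typical of EEG and above
the 0.85 bad-channel threshold), plus white sensor noise and an optional
50 Hz line component with a front-to-back amplitude gradient (a common-mode
line would be removed by re-referencing alone). Defaults: pink 6 µV, white
1.5 µV per sample.

What the generator does **not** emulate: eye/muscle artifacts (ICA-based
cleaning is out of scope), between-subject topographic variability beyond a
global gain (default SD 0.1), volume-conduction forward modelling, and
latency jitter of evoked components. Passing tests therefore demonstrate
correctness of the analysis chain under the planted model, not robustness to
every property of real recordings.

## Preprocessing

Order: band-pass → line-noise removal → resample → re-reference → baseline →
bad-channel handling → amplitude rejection, mirroring the acquisition
narrative. Filters are order-2 Butterworth applied forward–backward
(zero-phase), high-pass 0.1 Hz then low-pass 80 Hz. The 0.1 Hz high-pass has
an impulse response much longer than a 1.6 s epoch, so edge handling matters:
Gustafsson's initial-condition method keeps passband amplitudes within ~1%
where default padding distorts them by several percent. Line noise (50 Hz
and harmonics up to 200 Hz) is removed by projecting out exact sine/cosine
pairs per channel and trial — for stationary line contamination this
attenuates the line bins by ≫ 20 dB while provably leaving other frequencies
untouched, unlike a notch. Resampling to 250 Hz is polyphase with built-in
anti-aliasing; the −300…1300 ms epoch then has exactly 400 samples
(half-open end). Re-referencing is common-average; baseline is the mean of
−300…0 ms per trial and channel.

Bad channels are those whose mean correlation with their neighbours (over
trial-concatenated data) falls below 0.85, flagged iteratively worst-first
so a single dead channel does not condemn its neighbours; zero-variance
channels are flagged unconditionally. Interpolation is spherical-spline (via
MNE) with good channels left byte-identical. The ±500 threshold for
amplitude rejection is read as absolute µV on filtered data (peak-to-peak
was the plausible alternative; absolute is implemented and documented).

## Decoding

Per timepoint, trials × channels features; z-scoring uses training-fold
statistics only (fitting the scaler on all trials would leak test
information; this is the conservative reading of "z-scoring across samples
per timepoint"). LDA uses the lsqr solver with Ledoit–Wolf shrinkage — with
27 features and on the order of a hundred trials per class in a training
fold, an unregularised covariance estimate is noisy enough to need it. Folds are stratified with a fixed seed. AUC is computed
from held-out discriminant scores and averaged over folds. The empirical
chance level re-runs the identical analysis on permuted labels (two
independent permutations averaged, configurable). Weights are converted to
activation patterns by multiplication with the training-fold feature
covariance, so suppressor channels show ~0 pattern weight.

## Pattern similarity (cvMD)

For trials of one condition, the pattern at audio time t_a and the pattern
at post-audio time t_v are treated as the two "conditions" of a crossnobis
distance: per fold, Δ_train = mean difference on training trials, Δ_test on
test trials, Σ_train the Ledoit–Wolf covariance of training residuals around
the two period means, and cvMD = Δ_trainᵀ Σ_train⁻¹ Δ_test, averaged over
folds (averaging vs summing is scale-equivalent for contrasts). Because the
two factors come from independent trials the estimator is unbiased under the
null and may go negative. One fold assignment is shared across all grid
cells of a dissimilarity matrix so cells are comparable. The grid spans
200–650 ms (audio) × 0–550 ms (post-visual) at the epoch rate, with an
optional decimation step for tractable cohort runs.

## Hierarchical Gaussian filter

Generative model: x3 random walk (variance ϑ), x2 random walk (variance
exp(κ·x3 + ω)), outcome Bernoulli(s(x2)). The filter implements the standard
variational trial updates for the binary 3-level model: the level-1
prediction is s(μ2 prior); the level-2 posterior precision adds the
Bernoulli observation precision μ̂1(1−μ̂1); the level-2 mean moves by
σ2·(u − μ̂1), which is the pwPE identity verified to machine precision at
every trial; level 3 is updated with the volatility prediction error δ2 and
weight w2 = v/(σ2+v), and a non-positive level-3 posterior precision raises
a diagnostic error (model misfit for that parameter set). The update
equations were validated against an exact grid-based Bayesian filter
(dense discretisation of x2 × x3, numerical propagation of the random walks,
Bernoulli updates): predictive probabilities agree within 0.05 on 20-trial
sequences — rather than trusting transcription.

Defaults: κ = 1 (fixed unless estimated), ω = −3, ϑ = 0.005, initial beliefs
μ2 = 0 (no outcome bias, so the first prediction is 0.5), σ2 = 1, μ3 = 1,
σ3 = 1. Bayes-optimal inversion minimises Σ −ln p(u_t | μ̂1_t) plus Gaussian
prior penalties on (ω, log ϑ) — priors N(−3, 4²) and N(−6, 4²), wide enough
to be weakly informative while keeping the optimiser in the stable region —
by BFGS started at the prior means; unstable parameter sets receive a large
finite objective. The per-condition pwPE regressor is |ε2| by default (the
unsigned surprise magnitude; a signed option is exposed since the sign
convention is not fixed by the design).

## pwPE GLM

Ordinary least squares of single-trial amplitude on intercept + pwPE per
channel–timepoint; R² = squared correlation, computed vectorised. R² is
invariant to affine rescaling of the regressor, so nothing is standardised.
ROI averages use the three channel groups; the baseline is the mean R² over
all samples before the visual onset. Trials rejected during preprocessing
are dropped from both sides (listwise). `fit` accepts an optional confound
matrix that is projected out of amplitude and regressor first (partial R²).
The cohort analysis uses this hook with stimulus presence as the confound:
the ideal-observer pwPE is necessarily largest on rare omission trials, so
without partialling, R² is genuinely elevated wherever presence itself
modulates amplitude (the visual-evoked latencies), and the planted direct
coupling could not be isolated. Attenuation similarly induces a small shared
trend between audio-period amplitude and pwPE, which can push the pre-visual
baseline up; consequently "exceeds baseline" claims concern positive
clusters.

## Cluster statistics

Paired differences (subjects × points, or subjects × 2-D grid) are tested
with pointwise paired t statistics; cluster forming at the two-tailed t
critical value for α = 0.05 (the common default of the framework; the
forming threshold is configurable through α); adjacency is contiguity in 1-D
and 4-connectivity in 2-D; the cluster statistic is maxsum (summed t). The
null is the maximum absolute maxsum over random whole-subject sign flips;
corrected p = (1 + #{null ≥ observed})/(n_perm + 1), never exactly zero and
invariant to permutation order given the seed. Effect sizes are reported at
the peak-|t| point inside each cluster (max-|t|, not max-d): Cohen's d =
mean/SD (n−1), and the JZS Bayes factor computed by numerical integration of
the noncentral-t likelihood against a Cauchy(0, √2/2) prior on the
standardised effect, with the integration axis split around the likelihood
peak so extreme t values cannot defeat the quadrature. Permutation t maps
are computed blockwise by matrix algebra (sign flips leave Σx² unchanged),
which keeps 1,000-permutation tests at ~0.1 s for typical map sizes.

## Cohort runs and problem sizes

`simulate_cohort`/`analyze_cohort` run the full chain on a 21-subject
synthetic cohort: per subject, a fresh schedule, ideal-observer pwPE from
that schedule, simulation at 500 Hz raw rate (sufficient for the 80 Hz
band and the 200 Hz line harmonic), preprocessing to 250 Hz, and the four
group analyses. For tractable single-CPU runs the decoding time axis is
decimated by 2 (8 ms resolution) and the cvMD grid by 5 (20 ms); both are
parameters, and neither changes which effects are detectable. Group tests
use 1,000 permutations in the cohort runs; the test statistic and p-value
construction are identical at 10,000.

## Known limitations

* The generator's rank-one templates make spatial patterns time-invariant
  within a component; analyses that rely on within-component topographic
  dynamics are not exercised.
* Bayes-optimal HGF inversion fixes κ by default; with 360 binary
  observations, κ and ω are only weakly jointly identifiable.
* The cvMD cohort analysis uses a decimated grid; very small clusters
  (< ~20 ms extent) would be missed at the default step.
* Continuous-recording ingestion (BrainVision/EDF) is limited to
  channels × time arrays plus a schedule; vendor readers exist in MNE and
  can feed `epoch_and_baseline` directly.
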