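# Methods

`cfcausal` analyses interactions between a frontal (F) sensor group dominated
by a 6 Hz theta rhythm and a parieto-occipital (PO) group dominated by an
upper-alpha rhythm (alpha2, 10–13 Hz) during a working-memory arithmetic
task with five cognitive workload levels (CWLs) and correct/wrong response
labels. Because no recordings of this kind are publicly deposited, the
package ships a synthetic coupled-oscillator generator with full ground
truth; every estimator is validated against that ground truth and against
independent brute-force oracles.

## Estimators

**Phase locking value (PLV).** For two sensors, the modulus of the complex
mean of the instantaneous phase difference, averaged jointly over time
samples and wavelet scales (the scale average happens inside the complex
mean, not over per-scale PLVs). Phases come from a Morlet wavelet transform
with 7 cycles per wavelet (sigma_t = 7/(2 pi f)); theta uses 2 scales
spanning 5–6 Hz, alpha2 uses 4 scales spanning 10–13 Hz, linearly spaced.

**2:1 cross-frequency PLV.** The same construction on the difference
`2 * phi_theta - phi_alpha2`, locking two theta cycles to one alpha2 cycle.
The argument roles are ordered (theta first); when the two bands use
different scale grids the complex mean runs over the Cartesian product of
scale pairs.

**Rayleigh filtering.** Edge significance uses the Rayleigh test with the
standard finite-n correction, `Z = n_eff * PLV^2`. Phases sampled at 256 Hz
are heavily oversampled relative to the band dynamics, so `n_eff` divides
the sample count by `fs / (2 * band_high)` (two independent samples per
fastest cycle); the naive count would grossly inflate significance. The
per-edge significance level defaults to 0.05.

**Functional connectivity graph.** Block-structured: F×F edges carry
theta-band PLV, PO×PO edges alpha2-band PLV, and the F×PO cross block the
2:1 cross-frequency PLV, masked by the Rayleigh test. Subgraph strength is
the sum of significant edge weights over a region's edge set (each
undirected edge counted once).

**Directed phase lag index (dPLI).** The mean Heaviside step of the wrapped
phase difference, with H(0) = 0.5 — this convention keeps the antisymmetry
`dPLI(A,B) + dPLI(B,A) = 1` exact. Values above 0.5 mean the first signal
leads. The cross-frequency variant compares the doubled theta phase with the
alpha2 phase.

**Phase-to-amplitude coupling (PAC).** The alpha2 envelope is band-pass
filtered within the theta range, its Hilbert phase extracted, and the PLV
between that modulation phase and the driver theta phase taken as the
coupling index. Two numerical points matter here:

* *Sideband bandwidth.* Amplitude modulation of an 11.5 Hz carrier by a
  6 Hz phase puts sidebands at roughly 5.5 and 17.5 Hz — outside a 10–13 Hz
  extraction band. The envelope for PAC analysis is therefore extracted from
  a wider band (default 8–20 Hz) so that the upper modulation sideband
  survives; a band that cannot carry the sidebands makes PAC undetectable in
  principle, regardless of the estimator.
* *Surrogate processing symmetry.* Surrogates circularly shift the raw
  envelope **before** the slow-band filtering, and samples within one filter
  half-width of the wrap point are masked out of the surrogate PLV.
  Without these two steps the observed value (transient-free, edge-aligned)
  is systematically favoured over the surrogates and the empirical p-value
  is anticonservative.

**Delayed symbolic transfer entropy (dSTE).** The central estimator:
strength, net direction and delay of coupling between two series. Both
series are first differenced (symbols then encode local increment shape,
not absolute level, which de-emphasizes the narrowband rhythm) and reduced
to symbols either by ordinal patterns (alphabet m!) or by neural-gas vector
quantization (default K = 8 prototypes, embedding m = 3, tau = 1) trained on
the embedded vectors of both series pooled, with per-vector unit
normalization so the codebook quantizes shape. The transfer entropy

    STE(d) = I( Y_{t+d} ; X_t | Y_{t+d - m*tau} )

is scanned over candidate delays (default 0–250 ms in 1-sample steps at
256 Hz). Conditioning on the target symbol one embedding span behind the
*predicted* symbol — rather than on `Y_t` as in the single-delay textbook
form, which `ste()` retains — has two effects that the delay scan needs:
every delay on the grid, including d = 0, is evaluated with an identically
structured conditioning set, and the slow narrowband self-predictability of
oscillatory signals (which otherwise produces a delay-independent
predictability plateau and period-spaced sidelobes) is conditioned away.
All delays are evaluated on a common sample count so the plug-in bias does
not tilt the argmax. Ties at the argmax resolve toward the smallest delay.
The direction is the sign of `delta dSTE = STE_fwd(d*) - STE_rev(d*)`.
Note that selecting d* as the forward argmax biases the raw asymmetry
positive even for uncoupled series; direction calls are therefore only
interpreted for pairs whose time-shift surrogate test passes (default 100
circular shifts of at least 1 s, one-sided empirical p). A pair is flagged
zero-lag when the estimated delay is at most 1 sample and the surrogate
test passes; at the group level the flag aggregates the delays of
surrogate-significant estimates (their delays are the reliable ones).

**Envelope cross-correlation lag.** The signed lag at the peak of the
normalized cross-correlation of two mean-removed instantaneous-amplitude
series, positive when the first series leads. The pipeline feeds it
wideband (2–45 Hz) envelopes high-passed at 8 Hz: the slow co-modulation
shared by all channels carries no usable timing and only broadens the
correlation peak.

**Why the causal path is wideband.** Band-limiting a series to a B-Hz band
caps the timing information at roughly 1/B seconds; a 1 Hz-wide theta band
cannot support per-sample (4 ms) delay estimates at realistic trial
lengths, no matter the estimator. The delay estimators therefore operate on
generously band-passed series (2–45 Hz, optional alpha2 notch available
when narrowband sidelobes are a concern), while frequency-specific claims
rest on the phase estimators, which are narrowband by construction.

## Group statistics

Two-sided Wilcoxon rank-sum tests (exact null distribution for group sizes
up to 25 without ties, tie-corrected normal approximation otherwise),
Bonferroni correction (`p < alpha/k`), and Benjamini–Hochberg FDR (step-up
with rejection at the boundary). The unit of FDR correction is configurable
(`per_cwl`, `per_trial`, `global`; default per CWL — correcting across the
sensor-pair hypotheses within one workload level). Group summaries use the
two-step average: trials averaged within subject first, subjects weighted
equally regardless of trial counts.

## Classification

Correct-vs-wrong trials are classified per CWL with trials pooled over
subjects (a group-unified binary classifier), under stratified 10-fold
cross-validation with min-max normalization fit on training folds only.
Power/reaction-time features (theta power, alpha2 power and their ratio per
sensor, plus trial duration) are screened by the Laplacian score
(k-nearest-neighbour heat-kernel graph, k = 5, kernel width = median
neighbour distance; best 10 features kept). Connectivity matrices go
through tensor subspace analysis (TSA): a bilinear projection `U' W V`
optimized alternately to preserve heat-kernel neighbourhood affinity
(neighbour candidates restricted to the same class when labels are given),
identity initialization, at most 10 rounds, tolerance 1e-6, ridge-
regularized generalized eigenproblems. Matrix entries are centred and
scaled across trials before the bilinear optimization — without this the
objective is dominated by entry means and arbitrary units (delay features in
milliseconds versus strengths in bits) rather than by trial-to-trial
structure. The dSTE representation stacks per-pair (strength, delta dSTE,
delay) blocks into one matrix per trial. The final predictor is k-NN
(k = 5; odd k avoids voting ties in the binary problem).

## The synthetic generator

Each trial simulates the montage channels (default: the 25-sensor F/PO
montage; 13 frontal, 12 parieto-occipital, with P6, P8, PO8, PO4 and O2
forming the right-PO subset) at 256 Hz. One frontal source drives all F
channels: a 6 Hz theta oscillation with white per-sample frequency jitter
(SD 1 Hz — spectrally narrow but carrying the per-sample phase innovations
that delay estimators need), a slowly fluctuating envelope (2.5 Hz
bandwidth, depth 0.5), and an amplitude-co-modulated broadband background
(2–45 Hz, alpha2 band notched out, relative amplitude 0.6). PO channels
combine:

* an intrinsic alpha2 oscillation (centre 11.5 Hz, own jitter and
  envelope);
* a driven alpha2 component whose phase follows twice the **delayed**
  driver theta phase (2:1 phase–phase coupling, weight =
  `nm_phase_locking`), with its own phase noise tied to the locking level
  (`E[exp(i eta)] = lambda`, capped at 1.2 rad) — the noise both makes the
  measured locking track the parameter and keeps the driven rhythm from
  being long-range predictable from the driver, which would otherwise
  flatten the transfer-entropy delay curve;
* phase-to-amplitude coupling: the whole alpha2 envelope is modulated by
  `1 + pac_depth * cos(delayed theta phase)`;
* a fixed-power broadband **afferent** background: a delayed copy of the
  transmitted frontal signal (weight = `coupling_strength`) plus an
  independent theta-carrier process (weight = sqrt(1 - c^2), scaled to the
  carrier's power share). The transmitted signal carries the full broadband
  background but an attenuated theta carrier (weight 0.4), keeping PO
  alpha2-dominant. The construction makes total power, theta-band power and
  alpha2-band content of every PO channel invariant to the coupling
  strength: only the causal, lag-carrying pathway differs between
  conditions, mirroring the study design in which power and phase-coupling
  measures did not separate correct from wrong trials while the causal
  estimator did.

1/f background noise (exponent 1) is added per channel at SNR 5 (signal
variance over noise variance). Trial durations grow with workload level
(level mean = 2 s + 1 s per level, +-0.5 s jitter), and a per-level
amplitude gain (10 % per level) reproduces the increasing power trend with
difficulty. Default class sizes reproduce the study's wrong-trial counts
per level (42/53/59/62/61; 277 wrong in total) with 100 correct trials per
level across 16 cyclically assigned subjects.

The **correct-trial preset** uses a 120 ms coupling lag on all F->PO
pathways. The **wrong-trial preset** multiplies the causal coupling
strength by 0.4 on all pairs and sets the causal-transmission lag of
bilateral-F -> right-PO pairs to 0 ms. The zero-lag anomaly is deliberately
restricted to the causal pathway (phase-phase and phase-amplitude couplings
keep the nominal lag in both presets): a lag change in the phase pathways
would leak hemisphere-dependent phase relationships into the undirected
phase estimators, contradicting the finding that those estimators carry no
response information. The magnitudes of the wrong-trial contrast are
synthetic choices — the study reports the direction of the effects but no
effect sizes — picked once to be comfortably detectable.

### What the generator does not emulate

Volume conduction and field spread, eye/muscle/cardiac artifacts, inter-
subject variability beyond random channel gains, non-stationarity across
the session, and any realistic source geometry (channels are abstract
sensors, not dipole projections). Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated generative model,
not their robustness to real-EEG confounds.

## Numerical choices

* Band-pass filters: zero-phase forward-backward FIR (Hamming firwin),
  nominal transition width 1 Hz (2 Hz for the wideband causal path); the
  kernel length is capped at a third of the trial so short trials remain
  filterable, and the cutoffs are placed outside the nominal passband so a
  tone at a band edge passes at full amplitude. Samples within one
  filter/wavelet half-support of a trial edge are excluded from averaged
  estimators.
* Trial segmentation: a trial ends at the last local maximum of the
  theta-filtered reference channel (FZ by default) strictly before the
  response sample; a peak exactly at the response is excluded. Intervals
  are half-open, sample indices 0-based.
* Surrogate counts: granularity of the empirical p is 1/(M+1); tests that
  assert a null use M chosen so the achievable type-I error sits at or
  below the nominal level (e.g. M = 30 gives 1/31 ~ 0.032, M = 99 gives
  5/101 ~ 0.0495).
* Determinism: every stochastic component takes a seed or Generator;
  identical configuration and seed reproduce byte-identical trials and
  tables. Neural-gas fits subsample at most 3000 embedded vectors and use
  15 batch iterations.

## Problem sizes used by the test suite

Simulation-backed tests run scaled-down versions of the study conditions: a
10-channel sub-montage (5 F, 5 PO including three right-PO sensors), 10–12
trials per (CWL, response) cell, and trial durations around 4–5 s; the
parameter-recovery checks use 50 trials per lag at 6 s duration, c = 0.6,
SNR = 5; the estimator-comparison check averages 20 seeds per arm with the
ordinal symbolization scheme and a 2-sample delay grid. Calibration checks
use 1000–2000 replicates.

## Known limitations

* The time-shift surrogate test is mildly anticonservative for trials
  shorter than about 4 s: the minimum shift of 1 s then excludes a large
  arc of the circle, and the slow envelope structure makes surrogate
  statistics at nearby shifts correlated. With trials of 4.5 s or longer
  the empirical type-I error is at the nominal level.
* dSTE delay estimates assume the coupled dynamics carry broadband
  innovations; purely narrowband coupling supports only coarse delay
  estimates (see "Why the causal path is wideband").
* The raw `delta dSTE` at the selected delay is positively biased under
  independence (argmax selection); only surrogate-filtered direction calls
  are meaningful.
* TSA on small samples (tens of trials) is sensitive to the affinity graph;
  the per-fold fits can lose accuracy relative to plain k-NN on the
  flattened features. It is retained as the graph-classification front end
  by design.
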