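# Methods

This note documents the models, conventions and defaults behind `bandnet`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real recordings.

## Signal model and band decomposition

The unit of analysis is a channels × samples matrix (source-level signals,
e.g. beamformed MEG virtual sensors) with sampling rate, channel region tags
(anterior/posterior), subject and group identity.  Analysis windows default
to 30 s.  Six bands are used: δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–80 and
ripple 80–250 Hz.  Bands are half-open `[low, high)` so shared edges belong
to exactly one band (4 Hz is θ, not δ) — the edge-ownership convention is
arbitrary but must be fixed for the band powers to partition the spectrum.

Filtering is zero-phase throughout: a 4th-order Butterworth band-pass (8
poles after the band transform) and a Q = 50 IIR notch at 50 Hz, both applied
forward–backward (`filtfilt`), which squares the magnitude response and
cancels group delay.  Measured on probe sinusoids, the forward–backward
band-pass is flat to < 1 dB in-band and ≥ 20 dB down one octave outside the
edges; the notch removes > 24 dB at 50 Hz while staying within 1 dB outside
50 ± 2 Hz.  Butterworth was chosen for its monotone passband (no ripple to
modulate correlation estimates); the order trades transition width against
edge transients in 30-s windows.  An integer-factor decimator (anti-aliased,
zero-phase) is available but off by default; all bands are analyzed at the
native rate.  Manual artifact-segment rejection is replaced by an
annotation-driven mask (`mask_segments`) that excises intervals and re-times
events; there is no automatic artifact detection.

## Connectivity and the edge threshold

Connectivity is the zero-lag Pearson correlation of each band-filtered
channel pair over the window: `R = cov(Xa, Xb) / (S_Xa S_Xb)`.  Covariance is
the only reading of the numerator under which R is a correlation bounded by
1, and it is what the implementation computes.  Constant channels have no
defined correlation; their pairs are marked undefined and excluded from the
network rather than coerced to zero.

Edges are thresholded by the correlation t statistic
`Tp = R √(K−2) / √(1−R²)` with K the number of samples in the window,
compared two-sided against Student's t with K − 2 degrees of freedom at
α = .05.  Equivalently |R| must exceed `r* = t_c / √(K−2+t_c²)`; the package
tests verify the two formulations retain identical edge sets and that edge
sets are nested in α.  The test is two-sided because negative (inhibitory)
edges are retained with their sign; metrics later use |w|.

Two caveats are deliberate, faithful to common practice with this statistic,
and exposed as options rather than silently "fixed":

* **K is the raw sample count.**  Band-limited signals are strongly
  autocorrelated, so K overstates the information content of the window by
  roughly `fs / 2B` for a band of width B; at 1000 Hz a θ-band (4 Hz wide)
  window of 30 s has ~240 effective samples, not 30,000.  The practical
  consequence is a permissive threshold: many null edges with |R| of a few
  hundredths survive.  `effective_samples(K, fs, band)` implements the
  `K_eff ≈ 2·B·T` correction and `build_network(..., use_effective_k=True)`
  applies it; it is OFF by default.  The same quantity sets the honest
  Fisher-z standard error `1/√(K_eff − 3)` used to judge recovery of planted
  couplings in the tests.
* **No correction across pairs.**  The α = .05 threshold is per pair;
  `bonferroni_pairs=True` divides α by the number of pairs for analysts who
  want family-wise control at the network level.

## Graph metrics

Metrics operate on the magnitude network (|w| of the signed thresholded
weights) since `1/w` edge lengths and cube roots are ill-defined for negative
weights.  Conventions, exactly as the analysis defines them:

* degree `d_i` = incident edge count; `DA` = mean.
* strength `S_i = (1/N) Σ_j w_ij`; `SA` = mean.  The 1/N prefactor is
  nonstandard (the usual strength is the plain sum) but is implemented as
  defined; `strength_sum` provides the conventional variant.  The two differ
  only by the constant factor N, so group contrasts are unaffected.
* path length: shortest-path distances on edge lengths `1/w` (Dijkstra via
  `scipy.sparse.csgraph`); `L_ij = 0` for unreachable pairs and the diagonal;
  `LA = Σ L_ij / (N(N−1))` over ordered pairs.  The zero-for-unreachable rule
  means fragmentation *lowers* LA — a counterintuitive but intended property
  of this definition; `path_length_harmonic` offers an efficiency-style
  alternative that penalizes fragmentation.
* clustering: Onnela-type geometric-mean triangle intensity,
  `C_i = Σ_{j≠k} (w_ij w_jk w_ki)^{1/3} / (d_i(d_i−1))` over ordered neighbor
  pairs, with `C_i = 0` when `d_i < 2` (the denominator would be 0/0).
  Weights are normalized by the network maximum first so `C_i ∈ [0, 1]`;
  for correlation weights (|R| ≤ 1) this is a mild monotone rescaling.

All four implementations are checked against independent brute-force oracles
(Floyd–Warshall on 1/w, exhaustive triangle enumeration) to 1e−10 on random
graphs, and against closed forms on complete unit-weight graphs
(DA = N−1, SA = (N−1)/N, LA = 1, CA = 1).

## Statistics

Group comparison gates on assumptions per group: ANOVA only when every group
passes Shapiro–Wilk and the set passes Levene (median-centered — a robust
default; the homogeneity test is otherwise unspecified) at α = .05, else
Kruskal–Wallis.  Note that stacking four α = .05 gates means truly Gaussian
data selects ANOVA only ~81 % of the time; the gate is a policy, not an
inference.  Pairwise follow-ups match the omnibus family (t vs Mann–Whitney)
and are Bonferroni-corrected over the number of pairs — three groups give a
corrected threshold of 0.05/3 ≈ .0167.  Raw and corrected p values are both
reported so either significance policy can be applied downstream.  No
correction is applied across the bands × metrics family by default.
Calibration on null simulations (three Gaussian groups, n = 15 each) puts the
family-wise false-alarm rate of the corrected pairwise tests near 4 %, and
power for a d = 1.5 shift at n = 15 above 90 %.

Metric–score correlations (cognitive indices FSIQ/VCI/PRI/WMI/PSI) use
Pearson when both variables pass Shapiro–Wilk at .05, Spearman otherwise;
constant inputs return R = 0, p = 1 rather than an undefined coefficient.
Regional network patterns are compared by Fisher's exact test on
anterior–posterior vs within-region edge counts.

## The synthetic cohort generator

Per band, each channel is a mixture of unit-variance Gaussian sources
spectrally confined to the band by an exact rFFT mask and mixed through the
Cholesky factor of the target correlation matrix (coupling + identity).
Because every component of a channel shares the band's flat spectrum, any
linear filter downstream rescales all components equally and the planted
pairwise correlation survives band-pass filtering unchanged — this is what
makes the ground truth directly comparable to the estimator's output.
Jointly infeasible coupling sets (non-positive-definite matrices) are
rejected.  Band mixtures are summed and white sensor noise added at
`noise_sd` × signal RMS (default 0.1; in-band dilution of planted
correlations is then of order 10⁻⁴ and negligible against sampling error).

Spike-wave transients emulate interictal discharges: a fixed template — a
biphasic sharp transient of ~70 ms followed by a ~200 ms slow wave — with
±10 % uniform jitter in amplitude and width, injected at Poisson counts per
window (default mean 10 for the IED group, 0 otherwise) on random channels at
8 × the channel RMS.  The waveform is a modeling choice; no published
parameterization is assumed.  Injected events are returned as ground truth.

Cohort defaults mirror the study design the pipeline targets: three groups
(IED / non-IED / HC) of 15 subjects, 30 channels (first half tagged anterior,
second posterior), 30 s windows at 1000 Hz.  1000 Hz (not a hardware-grade
6000 Hz) keeps desk-scale compute while leaving 2× margin over the ripple
band's 250 Hz edge.  Group couplings are anterior/posterior block models:
HC keeps moderate long-range (cross-region) coupling (0.25) in every band;
IED loses it in β and ripple (0.05) and couples θ more diffusely; non-IED is
intermediate — reduced ripple long-range coupling (0.12) and stronger γ
coupling (shorter weighted path lengths).  The non-IED profile is a modeling
choice (the group is defined clinically, not electrophysiologically); nothing
in the package depends on it beyond the defaults.  Synthetic cognitive scores
are drawn from per-group normal distributions matching published group means
and SDs for the five indices, rounded to integer points.

Subject seeds are spawned deterministically from the master seed
(`numpy.random.SeedSequence`), so a spec plus seed reproduces a cohort
bit-identically; the pipeline manifest records the config hash and seed.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: 1/f background spectra (bands are equal-power and
flat), volume conduction / field spread (no common instantaneous leakage
between channels beyond the planted coupling), nonstationarity within a
window, physiological artifacts (cardiac, ocular, muscle), realistic sensor
geometry or anatomy, and any biophysical source model.  Results on synthetic
cohorts validate the *estimator chain*, not the neurophysiology.

## Numerical choices and degenerate inputs

* Correlation matrices are clipped to [−1, 1] against floating-point
  overshoot; diagonals forced to 1.
* Constant channels → NaN correlations, excluded from networks (not zero).
* Empty networks → all metrics 0 with a logged warning.
* Identical constant groups → degenerate flag, omnibus and pairwise p = 1.
* Kruskal–Wallis on fully tied data (which scipy rejects) → p = 1.
* Spike templates are placed entirely within the window (no truncation), so
  injection never changes duration or channel count.
* Filter edge effects are avoided in response measurements by trimming 1–2 s
  margins; pipeline estimates use full windows, where the transient fraction
  is ≪ 1 % for 30-s windows.

## Problem sizes

Validation uses problem sizes chosen to make sampling error small relative to
the tolerances while keeping the full suite fast: 200 random graphs for the
metric oracles, 200 replicates per planted coupling level (K = 10,000 samples
each), 1000 null / 100 effect replicates for statistical calibration, and a
scaled cohort (3 × 3–4 subjects, 8–10 channels, 5 s) for byte-identical
end-to-end determinism checks.  The full default cohort (45 subjects, 30
channels, 30 s, six bands) runs in well under a minute on one CPU and is
exercised via `bandnet run-all`.

## Known limitations

* Zero-lag correlation only — no coherence, phase-locking or lagged
  connectivity; shared inputs and field spread inflate zero-lag estimates on
  real sensor-space data.
* The default threshold's K ignores autocorrelation (see above); with long
  windows the networks are near-complete and group contrasts ride on edge
  *weights* more than edge *presence*.
* The printed strength (1/N) and zero-for-unreachable path-length conventions
  are kept for fidelity; both differ from the usual graph-theory definitions
  and should be stated when comparing against other toolboxes.
* No covariate adjustment, mixed-effects modeling, or correction across the
  band × metric family.
* Source reconstruction (beamforming), artifact detection and expert event
  marking are out of scope: the pipeline starts from source-level signals and
  trusts provided annotations.
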