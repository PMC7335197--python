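# Methods

This note documents the models and numerical choices behind `axoncal`: the
forward model of the synthetic-session generator, each analysis stage and
its assumptions, and the places where the design was genuinely open.

## Task and acquisition model

Sessions follow a head-fixed two-whisker go/no-go design. A trial is a 9 s
acquisition sweep at 30 Hz (270 frames): a 2 s quiet window, then a 200 ms
whisker stimulus (five contiguous single-period 40 ms sine pulses on the
piezo command) at the start of a 2 s response window. Stimuli are C2
(rewarded on lick), B2 (lick → timeout) or absent; 80% of trials carry a
stimulus, split evenly between the whiskers. Sweep starts are separated by
at least the trial duration plus a 4.5 s gap, so stimulus onsets are never
closer than 13.5 s; the scheduler uses the minimum gap by default
(`intertrial_jitter` adds uniform slack when wanted), which makes the
minimum inter-onset interval exactly 13.5 s. Recorded traces are
trial-concatenated: no inter-sweep frames exist, and all frame indices are
0-based with half-open windows `[start, end)`.

Licks occur only in the response window. Per condition, the lick flag is
Bernoulli (defaults 0.85 / 0.30 / 0.10 for C2 / B2 / none, which puts
typical session performance near 0.78, comfortably above the 0.6 inclusion
bound) and the first-lick reaction time is normal(0.29 s, 0.18 s) truncated
to `(rt_min, response_window]`. `rt_min` defaults to 0; analyses that need
lick movement to start strictly after the 0.266 s early window (the
class-contrast studies) raise it to 0.29 s, mirroring the rationale that
reaction times measured at movement initiation rarely undercut the early
window.

Outcomes are labeled hit / miss / false-alarm / correct-rejection /
no-stim-lick / no-stim-quiet, and session performance is
(hits + correct rejections) / stimulus trials, with strict `> 0.6`
inclusion.

## Axon classes and the fluorescence forward model

Three generative classes mimic the lemniscal/paralemniscal phenomenology:

| class | tuning (true WSI) | latency | lick transients | lick gain |
|---|---|---|---|---|
| VPM-like | ±uniform(0.8, 1) | 50 ms | peak 3 σ at reaction time | ×1.0 |
| POm-FO-like | ±uniform(0.3, 0.9) | 150 ms | none | ×1.5 |
| POm-HO-like | N(0, 0.2) clipped | 200 ms | none | ×1.5 |

The tuned VPM-like axons are placed in two disjoint spatial clusters by
preferred whisker (SD 14 px around centers 128 px apart in a 256×256
field); POm-like axons are scattered uniformly, so their C2- and
B2-preferring members intermingle.

Evoked amplitudes follow `A_C2 = A(1 + w)/2`, `A_B2 = A(1 − w)/2` with
`A = 5` noise-SD by default, so the WSI recomputed from noiseless
amplitudes equals the true `w` exactly and recovery tests are sharp. Every
event amplitude is multiplied by a per-trial lognormal gain (mean 1,
CV 0.5). This both models real trial-to-trial response variability and
keeps stimulus-locked signal from correlating different axons above the
0.8 merge threshold: independent gains cap the cross-axon correlation of
the shared evoked component well below it. Spontaneous transients occur at
0.02 Hz (not a value taken from data; chosen as a low, realistic rate).

Events are convolved with a peak-normalized double-exponential kernel
`(1 − e^(−t/0.18 s)) · e^(−t/1.8 s)` matching published GCaMP6s kinetics
(both constants configurable). The kernel is **frame-integrated**: each
30 Hz sample is the average of the continuous kernel over its frame
interval, as a scanning acquisition integrates photons across the frame.
Point sampling (available via a flag) puts an exact zero in the event
frame and delays threshold-based latency detection by an extra bin.

Each axon adds slow drift (a random cubic over the session, range-scaled
to 0.5–2 noise-SD, plus a 50–150 unit baseline offset) and shared Gaussian
noise of variance `ρ σ²` with `ρ = 0.9`. Each segment then adds
independent noise of variance `(1 − ρ) σ²` — so within-axon segment
correlation from the noise alone is ρ, above the 0.8 merge threshold by
construction — plus the session-wide neuropil trace (offset 20, slow
fluctuation of SD 0.3 σ) scaled by its coefficient (uniform 0.6–0.8).
Amplitudes are expressed in units of σ (default 1.0 fluorescence unit);
with `σ = 0` the fluorescence scale degenerates to 1 for noiseless
analyses.

## Segment merging

Pairwise Pearson correlation of **raw** traces (the stage at which an
upstream extraction toolbox emits them, before neuropil subtraction; the
choice is an interpretation, as is using the full session) defines a graph
with edges above the threshold; connected components (single linkage) are
the putative axons. Zero-variance traces have undefined correlation and
are excluded with a warning. Merged raw and neuropil traces are
pixel-count-weighted means, with each segment's neuropil scaled by its own
coefficient before weighting; coefficients are inputs, never estimated
here. Raising the threshold can only shrink clusters; permuting segments
changes nothing but labels.

## Baseline, noise, z-scoring

The baseline is estimated from the signal mode piecewise: the trace is cut
into `round(n/3000)` near-equal segments, the **half-sample mode** of each
segment is taken (robust and parameter-free, unlike histogram modes whose
result depends on bin width), and a least-squares polynomial of order 5
through the (segment center, mode) points — order capped at points − 1
with a warning — is evaluated at every frame, extrapolating beyond the
outermost centers. Fitting uses a scaled-domain polynomial basis for
conditioning.

Two practical limits are worth knowing. First, on a *noiseless* smooth
trend the value-domain mode of a monotone segment sits at the flat end,
not the center, so the baseline tracks a clean polynomial only to ~10% of
its range; with symmetric noise present (the real regime) this bias
vanishes, and on the standard validation simulation (drift + 5% sparse
transients + unit noise over 1e5 frames) the RMSE against the true drift
is ≈ 0.11 σ. Second, the polynomial needs enough mode points: on short
sessions (≲ 20k frames, ≤ 7 points) the order-5 fit is nearly
interpolating and amplifies mode noise. The defaults are meant for
session-scale traces of ~1e5 frames.

The noise SD is the RMS of the **negative** residuals (equivalently the SD
of the mirrored set {x, −x : x < 0}); under a centered Gaussian noise
model E[x²|x<0] = σ², and positive-going transients cannot contaminate the
estimate. It errs if no negative residuals exist and warns below 100. When
transients are sparse (≲ 10% of frames carrying signal) ground-truth σ is
recovered within ~5%; at 80% stimulus density the 1.8 s decay tails occupy
most frames, lift the baseline and bias σ high (tens of percent on short
dense sessions) — a property of the method itself, shared with its use on
real data, and the reason validation uses sparse sessions.

Trial tensors are built per (condition × lick) group: windows from
−0.5 s to the sweep end around stimulus onset (or `[−1 s, 3 s)` around
the first lick for lick-aligned analyses, whose z statistics still come
from the pre-stimulus quiet window). The 0.5 s quiet-window samples are
pooled **across the group's trials** and their mean/SD z-score every bin;
per-trial normalization was rejected as unstable for 15-frame windows.
A zero pooled SD marks the group invalid. Note the pooled SD absorbs
whatever happens in quiet windows — including large spontaneous
transients, which can inflate it several-fold and proportionally deflate
every z value for that group; the power validation therefore disables
spontaneous events so the nominal amplitude-to-noise ratio holds exactly.

## Response statistics

Values being z-scored, each bin's trial mean m over n trials is tested
against N(0, 1/n): statistic m√n, one-sided upper-tail p computed through
the log survival function, so −log₁₀(p) is exact far beyond the underflow
of p (a t-test would be wrong here: the null variance is 1 by
construction). Significance needs −log₁₀(p) > 10 in ≥ 3 consecutive bins
of the 2 s response window — with per-bin false-positive probability
1e−10, three in a row is essentially impossible under the null (0 calls in
10,000 simulated null axons) while the slow indicator guarantees genuine
responses span many bins. Latency is the first response-window bin above
−log₁₀(p) = 5 (0-based, × bin period); at 5 σ evoked amplitude and ~30
trials the median recovery error is one 33 ms bin, the unavoidable
rise-time lag of a threshold detector on a slow indicator.

Windowed amplitudes are means over trials × bins. WSI floors negative
amplitudes at 0 before the ratio so it stays in [−1, 1] (the undefined
0/0 case excludes the axon); the headline WSI uses no-lick trials
(responses "in the absence of licking"), with `wsi_lick` computed from
lick trials for the erosion analyses. |WSI| ≥ 0.75 is "tuned". The
early-window comparison takes mean z over `[0, 0.266 s)` — one frame short
of the mean reaction time — for lick vs no-lick trials of a condition and
applies a paired two-sided Wilcoxon over axons (p = 1 by convention when
all differences vanish); 0.2 s and 0.4 s windows are exposed for
robustness checks.

## Spatial overlap

Every pixel of a merged axon inherits the axon's windowed condition
amplitudes and WSI; pixels claimed by several axons are excluded (rare,
avoids double counting). Pixels with WSI beyond ±0.75 form the C2 and B2
clouds. The confidence ellipse is the Mahalanobis level set of the cloud's
mean and **covariance** at the χ²(2 df) quantile of 0.9 — semi-axes
√(λᵢ q), area π s₁ s₂. (A correlation matrix would discard scale and leave
"area" undefined; this substitution of covariance for correlation is a
recorded interpretation.) Intersection areas use matched 512-vertex
inscribed polygons clipped with shapely; the inscribed-polygon shrinkage
(~2.5e−5 relative at 512 vertices) cancels in the index, which makes the
concentric-circles case (areas A and 4A → index 0.4) exact to floating
point. The polygon route agrees with a rejection-sampling Monte-Carlo
estimate over the bounding-box intersection to well under 1% on random
overlapping pairs, and fitted ellipses contain 90% ± 1% of Gaussian
samples.

## Lick timing

Single-trial latency is read from the cumulative signal: over a 3 s window
starting at the response-window onset, z values are floored at 0 (a
cumulative distribution needs nonnegative mass; raw-z cumulation is
available behind a switch), and the latency is the first bin whose running
sum reaches half the window total, ties toward earlier bins. Trials with
no mass are excluded. Latencies are paired with reaction times on lick
trials of the non-rewarded whisker (B2) — no reward-delivery confound, and
a homogeneous lick pattern across trials — requiring ≥ 3 finite pairs and
nonzero variance; Pearson r with its two-sided p flags axons at p < 0.05.
On stimulus-locked nulls the flag rate is the nominal ~5%. Event-triggered
averages (mean ± s.e.m. around supplied event times) serve the
spontaneous-lick analyses; lick-bout structure has no data-derived
default and is left to the caller's event list.

## Validation scale and what it shows

The shipped validation uses desk-scale problem sizes chosen to make the
statistics decisive: 75-trial passive sessions with 200 axons for
WSI/latency recovery and 100 axons at exactly 5 σ per condition for power;
200-trial behavioral sessions with 60 clustered or 100 intermingled axons
for the class contrasts; 10,000 tensor-level null axons for the
false-positive bound; 1e5-frame simulations for baseline/noise recovery;
100 random ellipse pairs at 1e6 Monte-Carlo points each. Passing these
shows the estimators recover the generator's ground truth under its
assumptions — Gaussian noise, linear neuropil mixing, known kernel,
frame-quantized events. Real recordings add motion artifacts, nonlinear
indicator saturation, correlated network activity and imperfect neuropil
coefficients, none of which the generator emulates; the headline
population numbers of any real dataset are therefore not targets here,
only the directional contrasts are.

## Known limitations

- Pooled quiet-window SD is not robust to rare large spontaneous events
  (documented above).
- The noise estimator assumes transient-sparse traces; dense stimulation
  with a slow indicator biases it upward.
- Correlation clustering with single linkage can chain distinct axons
  through intermediates if their signals correlate strongly; the generator's
  trial-gain variability keeps cross-axon correlations low, but on real
  data the published workflow required manual inspection at this step.
- Neuropil coefficients are trusted inputs; no estimation or validation of
  them is attempted.
- No spike inference: all statistics operate on normalized fluorescence.
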