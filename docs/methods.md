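# Methods

This note documents the models, estimators, numerical choices, and
limitations behind each module, and what the synthetic generators do and
do not emulate.

## Bilateral calcium activity (`neural`)

**Signal model.** Each region of interest (ROI) records fluorescence
F(t) = baseline + drift + Σ events + noise at 10 frames/s for ~60 s.
ΔF = F(t) − F0 with F0 either a user-supplied constant ("manual" baseline)
or a centered rolling percentile (default: 10th percentile over a 20 s
window). The rolling percentile tracks slow drift while sitting below
sparse transients; a manual value reproduces hand-picked baselines exactly.
Relative intensity is 100·ΔF/mean(ΔF) (output mean is exactly 100).

**Event detection.** Manual event picking is replaced by a deterministic
rule. The robust noise SD σ is 1.4826·MAD of the first differences of ΔF
divided by √2 — first differences suppress the slow calcium transients, so
σ estimates frame noise even in event-dense traces. Events are local maxima
of a boxcar-smoothed ΔF (default 0.3 s, roughly matched to the transient
width) that exceed the median level by k·σ/√w (default k = 3, w the smoothing
window) with at least the same prominence, separated by a refractory
interval (default 0.5 s; the larger peak wins). The prominence requirement
stops noise ripples on a slow decay from splitting one transient into
several events. Each event is timed at its *onset* — the last sub-threshold
sample before the peak — because the fast calcium rise localizes to about
one frame while the flat transient top does not; an event riding on the
previous transient's tail is timed at the inter-peak minimum. Thresholding
relative to the median makes detection invariant to constant offsets in
F(t) under the percentile baseline.

**Alternation index.** Events detected separately on the summed left-side
and summed right-side activities are merged into one train; left/right
events with onsets within a coincidence window (default 0.2 s) merge into a
single `bilateral` event. The index is (# consecutive pairs on opposite
sides)/(n − 1); pairs involving a bilateral event count as not-opposite,
because synchronous bilateral activation is precisely the discoordination
phenotype, and no tie rule is otherwise established. The index can also be
computed per matched left/right ROI pair (`mode="by_pair"`); the default is
the merged per-side train, matching quantification of total left- and
right-side activity. Per-side frequency is event count divided by the
recording duration. "Total signal" is operationalized as the trapezoidal
time-integral of ΔF per ROI (ΔF·s); no closed formula for it is established
elsewhere, so the integral — the natural scale-covariant choice — is used.

## Curvature morphometrics (`morpho`)

θ is computed from an ordered head→tail midline: the vertex is the interior
point of maximal perpendicular distance from the head-tail chord, and
θ = 180° − the interior angle at the vertex between the vertex→head and
vertex→tail vectors. This Cobb-like construction returns 0 for straight
bodies, is invariant under rotation, translation, reflection, uniform
scaling, and reversal, and has a closed-form oracle: for a circular-arc
midline with central angle 2θ₀ the inscribed-angle theorem gives exactly
θ = θ₀. Noisy midlines are smoothed with a 3-point moving average (interior
points only) before vertex selection, because the vertex choice is unstable
under pixel noise; polylines with fewer than 7 points are used as-is, since
smoothing a minimal polyline (e.g. an explicit head-vertex-tail triangle)
would displace the vertex itself. Whether midlines come from dorsal or
lateral views is irrelevant to the estimator; the construction is a
declared convention on coordinates.

A fish is "curved" iff θ ≥ 10° (boundary inclusive). Penetrance is
100·n_curved/n_total; computation keeps full precision and a 3-significant-
figure display convention is provided separately (so printed-style values
like 11.9% and 1.769% are formatting, not data). Group comparisons use the
unpaired Student's t test for two groups and one-way ANOVA for more.

## Surface EMG (`semg`)

Recordings are four named channels — left/right paraspinal recording pair
and left/right upper-thoracic reference pair — at fs = 2000 Hz, hardware
gain 1000, analog band 15–1000 Hz. Preprocessing applies a zero-phase
4th-order Butterworth band-pass (the filter family/order is a choice; only
the band is given by the acquisition) and removes each channel's mean. At
fs = 2000 Hz the nominal 1000 Hz upper edge equals Nyquist, so the edge is
clipped to 0.45·fs for a realizable filter.

ECG removal is reference-guided template subtraction: beats are detected on
the reference channel (prominent peaks with a ≥ 0.4 s RR interval); if
fewer than 3 beats are found or RR intervals vary by more than 25% CV, no
reliable periodicity exists and the input is returned unchanged with a
flag. Otherwise the template is the beat-locked mean segment of the
*reference* (where EMG contamination is low), each beat's lag in the signal
is refined by maximizing correlation with the template (detection jitter of
a few samples would otherwise smear the subtraction), and a per-beat
least-squares-scaled copy is subtracted, with windows truncated at the
recording edges. The scalar fit can only reduce each segment's energy, so
template-free signals are never inflated.

Bending normalization divides each standing channel by the RMS of the same
channel during trunk bending toward that channel's side (left channels by
the left-bend recording, right by right-bend), giving dimensionless values
invariant to common gain. The per-side-RMS convention is declared; no
formula is established elsewhere. Burst metrics (windowed RMS, burst =
window exceeding k× the median window RMS, default 0.25 s windows and
k = 3) are explicitly exploratory descriptors of "irregular bursts" versus
stationary activity, with no claim of clinical validity.

## Cohort statistics (`cohort`)

Allele frequencies are proportions over allele counts (2 per diploid
subject). Association on the 2×2 allele table uses the two-sided Fisher's
exact test — the standard for rare variants; the test behind the published
p-value is unnamed, so the printed 2.39×10⁻⁶ is treated as an
order-of-magnitude consistency check, not an exact target (our Fisher p on
the same counts is 2.20×10⁻⁶). The odds ratio is the cross-product, with a
Haldane–Anscombe 0.5 correction only when a cell is zero (flagged in the
result). Plasma-glycine comparisons use the unpaired Student's t test,
optionally within one age stratum; the adolescent stratum is the
informative contrast since AIS manifests during the pubertal growth spurt.

## Uptake assays (`uptake`)

Rates are quantity/(time·protein) in nmol/min/mg. An optional helper
converts scintillation DPM to nmol via the 60 Ci/mmol specific activity and
a declared counting efficiency. Percent-of-WT divides by the mean WT rate
(WT mean = 100% by construction); membrane normalization divides
percent-of-WT by each genotype's relative cytomembrane level (WT = 1) — a
variant whose uptake deficit is fully explained by reduced surface
presentation returns to parity with WT. Group comparison is one-way ANOVA
with per-variant contrasts against WT; the adjustment (Dunnett many-to-one
by default, Holm or none as alternatives) is recorded in the output because
only "one-way ANOVA" is specified upstream.

## Enrichment (`enrichment`)

For query genes against GMT annotation sets: p = P(X ≥ k) with
X ~ Hypergeom(N, K, n), where N is the universe size, K the set size, n the
number of query genes mapped to ≥ 1 set, and k the overlap;
GeneRatio = k/n. The universe defaults to the union of all annotation-set
members (the common tool default) and is overridable; unmapped query genes
are reported but excluded from n, matching the GeneRatio denominator
convention. Benjamini–Hochberg adjustment is applied across sets. No
ontology or SNP→gene mapping is bundled.

## Synthetic generators (`synthetic`)

All generators draw every random quantity from one explicit seed; equal
seeds give bit-identical outputs.

- **Bilateral traces.** Event times follow a renewal process with a
  refractory gap (default 1 s) plus an exponential tail whose mean is set so
  the realized rate equals `event_rate` (default 0.2 events/s per fish over
  60 s at 10 fps, chosen for testability — empirical event statistics of
  real recordings are not published). Sides follow a Bernoulli switching
  process: each event switches sides with probability `switch_prob`, so the
  expected alternation index of the ground truth equals `switch_prob`,
  giving an analytic recovery target. Transients are unit-peak
  double-exponential kernels (rise 0.2 s, decay 1.5 s) scaled by Gaussian
  amplitudes, added to baseline + linear drift + i.i.d. Gaussian noise;
  ground-truth times mark transient onsets. Not emulated: ROI segmentation,
  photobleaching, correlated noise, or any biophysical CPG circuit — so
  passing recovery tests validates the estimators, not a neural model.
- **Midlines** are circular arcs of central angle 2θ and fixed arc length
  (default 4 mm, a larval body length) with optional Gaussian coordinate
  noise; θ = 0 degenerates to a straight segment.
- **Cohorts** draw binomial variant-allele counts at stated frequencies
  (defaults: the published cohort sizes and frequencies).
- **sEMG** mixes a stylized periodic PQRST template (unit R peak, 1.25 Hz)
  into band-limited Gaussian EMG noise on all four channels, with lower EMG
  on the reference pair (ECG-dominated upper-thoracic sites; default ECG
  amplitude 8× the recording-pair EMG SD) and optional one-sided
  Hann-enveloped bursts. Heart-rate variability, electrode motion, and
  powerline interference are not modeled.
- **Uptake plates** set each well to rate·time·protein·(1 + CV·noise).

## Problem sizes and tolerances

The pipeline-recovery analyses use a single 600 s recording at 0.4 events/s
(~240 events), which bounds the binomial standard error of the alternation
index near 0.026 — comfortably inside the ±0.05 recovery tolerance; the
equiprobable-switching check uses 10,000 events (±0.02). θ recovery is
tested on 101-point noise-free arcs at 0.5° tolerance (observed error
< 0.02°). Fisher and hypergeometric p-values are checked against exhaustive
enumeration on all tables/universes small enough to enumerate exactly.
ECG-removal performance is scored as residual injected-template energy
after subtraction (< 10% required; ~6% typical at the default conditions).

## Known limitations

- The event detector's onset timing degrades for transients overlapping
  within less than the refractory interval and for transients truncated by
  the end of a recording.
- The θ construction reports the single dominant curve; S-shaped midlines
  with two apices are summarized by the larger deviation only.
- Fisher's exact on allele counts assumes allele independence
  (Hardy-Weinberg); carrier-level tables can be supplied where that is in
  doubt.
- Burst metrics and the sEMG generator are exploratory constructs; no
  labeled clinical recordings exist here to validate them against.
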