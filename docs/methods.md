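# Methods

## Signal model and segmentation procedure

The analysis treats a rapid isometric contraction as an excitation-driven
rise of force. In an unimpaired pulse a single drive burst produces one
acceleration lobe followed by one deceleration lobe in F″(t), hence exactly
one zero crossing before the force peak and one segment. Each additional
drive burst adds a deceleration–acceleration pair, i.e. two crossings, so
the segment count on an interval with Z crossings is (Z + 1)/2, rounded up.
The ceiling resolves the half-integer case (even Z): an interval that ends
mid-acceleration — typical when counting to F90, which is reached *during*
the final segment — counts the segment in progress. Segment boundaries
follow the geometry of F″: a segment ends at the F″ minimum between a
falling and the next rising crossing (deepest deceleration), and a later
segment begins at the F″ maximum between a rising and the next falling
crossing (strongest re-acceleration); the first segment begins at force
initiation. Slowing periods are the gaps between consecutive segments, so
segments and slowing periods interleave and exactly tile the span from
first segment start to last segment end.

### Derivative estimation

Both derivatives are windowed least-squares slopes: the slope of a straight
line fitted to a centered window, with F″ the moving slope of the RFD
series using the same window. The window is `round(window_ms·fs/1000)`
samples forced odd (11 samples = 50 ms at 200 Hz); a centered window needs
odd length. At the edges the full-width window is shifted to stay in
bounds; since a fitted line's slope does not depend on the evaluation
position, output length equals input length and linear signals are
differentiated exactly everywhere. No smoothing beyond the two slope passes
is applied: the 50 Hz low-pass is an acquisition property, emulated by the
simulator, not re-applied by the analysis. The slope estimator attenuates
high frequencies by the analytic factor `Σ 2k·sin(kθ) / (θ·Σ 2k²)`
(θ = 2πf/fs, k = 1..5): under 1.2% below 2 Hz, ~7% at 5 Hz. This is the
price of the noise suppression the 50 ms window buys and is shared by any
implementation of the same estimator.

### Pulse detection

Candidate peaks are local force maxima of at least 10 %MVC (`min_peak`)
separated by at least 1.0 s (`min_separation`); both are quality gates for
cueing protocols with 3–5 s spacing and 20–60 %MVC targets, configurable
and logged. Onset is located by scanning backward from the peak while
either RFD ≥ 20 %MVC/s or force remains above 5% of the pulse peak
(`baseline_frac`); the onset is the sample after the last baseline sample
so reached. The force condition is what lets the scan cross slowing
periods — where RFD dips below threshold while force stays elevated —
without chaining across sub-threshold baseline noise, a failure mode of
purely RFD-based backward scans at realistic noise. The offset is the
sample immediately before RFD first returns above −20 %MVC/s after having
dropped below it during relaxation; relaxation is not analyzed further.
Pulses whose scans collide with a neighbor are flagged `merged_pulses`
(excluded by default), and detection anomalies are flagged rather than
silently repaired; a manual-override CSV can force keep/drop per pulse,
replacing the visual confirmation step of a laboratory workflow.

Numerical conventions: F″ samples that are exactly zero inherit the
previous non-zero sign (no phantom crossings on plateaus); a crossing is
recorded at the first sample of the new sign; F90 is the first sample
≥ 0.9·peak with no interpolation (worst-case bias 5 ms at 200 Hz); the RFD
argmax takes the earliest index on ties; an RFD argmax falling inside a
slowing period is attributed to the nearer adjacent segment, earlier on an
exact tie (geometrically the argmax lies at a falling F″ crossing inside a
segment, so ties are degenerate).

## Subject aggregation

Eligible pulses peak in [20, 60] %MVC (inclusive) and are not QC-dropped.
41 are drawn uniformly without replacement — an odd count keeps integer
metrics' medians integer; with fewer than 41 eligible all are used with a
warning. The draw is keyed on pulses sorted by onset time and uses a
per-subject seed derived by a stable hash of (master seed, subject id), so
results are independent of file processing order. Medians use the standard
midpoint convention for even counts. Ordinal segment/slowing duration
medians (positions 1–5) use only pulses that possess that ordinal, so later
ordinals summarize shrinking subsets. A PD subject with median
segments-to-F90 ≥ 2 (inclusive) is PD_Seg.

## Cohort statistics

The nonparametric path is fixed by design for force measures; no normality
gating is performed, and routine parametric demographic checks are out of
scope. Conventions:

- **Prevalence**: exact binomial test against p₀ = 0.5; the two-sided p
  doubles the smaller tail (capped at 1), the convention of the major
  statistics packages; a minimum-likelihood-sum alternative is available
  via `method="minlike"`. The 95% CI uses the Clopper-Pearson inverse
  incomplete-beta bounds, closed at 0 and 1 for k = 0 and k = n.
- **Omnibus**: Kruskal-Wallis with midrank tie correction (scipy); a pooled
  sample with all values identical is reported as H = 0, p = 1.
- **Pairwise**: Dunn's z on pooled midranks with tie correction — the
  standard follow-up to Kruskal-Wallis — Bonferroni-adjusted with
  m = g(g−1)/2 contrasts per measure family; each contrast carries
  r = |z|/√(nᵢ + nⱼ). The n entering r is exposed explicitly.
- **Two-group contrasts**: Mann-Whitney U with tie-corrected normal z;
  for combined n ≤ 12 an exact enumeration p over all labelings is
  reported alongside.
- **Repeated ordinals**: Friedman's test with within-row midranks and tie
  correction (valid for k = 2, where it reduces to the sign-test
  statistic), complete-case over rows with the dropped count recorded.
  Homogeneous subsets: conditions are ordered by mean rank and every
  maximal contiguous run whose restricted Friedman test has p > α is
  reported; runs contained in larger runs are dropped, so subsets can
  overlap. The rule is deterministic; the step-down procedure of commercial
  packages is unpublished, so this documented rule stands in its place.
- **Descriptives**: median; IQR = Q3 − Q1 with linear-interpolation
  quantiles; CV = 100·SD/mean with the n−1 SD across subject medians,
  undefined for zero mean.

## Synthetic cohort

The simulator exists to make every stage testable with known ground truth.
Neuromuscular drive is a train of rectangular bursts; force is the drive
convolved with a critically damped second-order twitch kernel
h(t) = (t/τ²)e^(−t/τ) with unit steady-state gain, scaled so the noiseless
peak equals a drawn target, then forward-backward low-pass filtered (4th
order Butterworth, 50 Hz) and sampled at 200 Hz with additive white
Gaussian noise after filtering — the order in which a recording chain
introduces broadband noise.

Default study conditions: 45 pulses per session, onsets uniformly 3–5 s
apart; target peaks normal (40, 3.5²) %MVC; per-subject MVC normal
(45, 8²) N, emitted in raw newtons so the normalization path is exercised.
Multi-burst pulses use mean burst durations 86/65/52.5/53.7/52.5 ms and
gap means 80/59.7/50.5/49/50.1 ms with CVs of 16–26%, all drawn truncated
at ±3 SD to stay positive. Archetype multi-burst probabilities are
OA 4.2%, PD_NoSeg 27.4% (counts 2–3), PD_Seg 82% (counts 2–5, weighted
toward 2–3); these are the per-group percent-multisegment levels the
pipeline is designed to discriminate. Single-burst drive durations are
152–165 ms, the uninterrupted rise of a non-segmented pulse.

Two calibration choices matter. τ = 25 ms places the noiseless smooth-pulse
peak RFD at the scale of healthy rapid contractions (~400–550 %MVC/s for a
40 %MVC pulse). During gaps the drive drops to 60% of the level holding
the force already reached (`gap_drive_frac`) rather than to zero: a
transient *reduction* of drive produces the plateau-like slowing periods
seen in segmented recordings, keeps the force maximum in the final burst,
and keeps segmented pulses slower in peak RFD than smooth ones, as they
are in patients. Burst amplitudes follow an escalating profile
(1.0/1.35/1.55/1.75/1.95), each divided by the kernel's finite-burst
response 1 − (1 + d/τ)e^(−d/τ) so a burst's standalone force contribution
tracks the profile regardless of its sampled duration; the largest step is
first-to-second, so the peak RFD of a typical 2–3-burst pulse falls in the
second segment. All randomness flows from one master seed via per-subject
hashes; identical seeds give bit-identical cohorts.

What the simulator does *not* emulate: motor-unit pool physiology, EMG,
tremor oscillations, fatigue or drift, amplitude-range sub-protocols, or
the between-subject covariance structure of clinical covariates. Passing
recovery tests therefore demonstrates that the analysis correctly inverts
this generative family — bursts at the documented duration/gap scales under
broadband noise — not that it reproduces any clinical cohort's statistics.

## Problem sizes and measured behavior

The test suite and the acceptance script use sessions of 40–45 pulses,
1,000-pulse oracle comparisons and one full 79-subject cohort (39 PD_Seg /
18 PD_NoSeg / 22 OA at default noise), sizes at which the relevant rates
are stable across seeds; the whole suite runs in well under a minute.
Measured at these sizes: segment counts agree with an independent
sign-scan recount on 100% of pulses; noiseless three-burst pulses recover
their burst count exactly with slowing-period errors ≤ 5 ms; at default
noise (SD 0.3 %MVC, and unchanged up to 0.5) ≥ 97% of pulses with
generative gaps ≥ 40 ms recover their burst count; and subject
classification agrees with generative archetypes for all 79 subjects.
Gaps much below 40 ms are not resolvable in principle: two slope passes
with 50 ms windows give the F″ estimate an ~100 ms support, which is the
method's resolution floor, inherited from the analysis it implements.

## Known limitations

- The first segment's measured duration is biased long by ~10–15 ms: it
  starts at the threshold-based force initiation rather than at an F″
  maximum, and its end (an F″ minimum) lags the true drive offset by the
  smoothing delay. The same asymmetry exists in the laboratory measure.
- The exact-enumeration Mann-Whitney p is limited to combined n ≤ 12
  (C(12,6) = 924 labelings); above that only the tie-corrected normal
  approximation is reported.
- The homogeneous-subset rule is one deterministic choice among several
  plausible step-down procedures; subset membership near α can differ from
  other software.
- `detect_pulses` assumes pulses return near baseline between cues; sessions
  with sustained background force need the QC override path.
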