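# motorseg

Motor-segmentation analysis of rapid isometric force pulses.

Some people with Parkinson's disease cannot sustain the single burst of
neuromuscular excitation that normally drives a rapid contraction. Their
force rises in several short **segments** separated by **slowing periods** —
transient reductions in drive — which lowers the rate of force development
(RFD) and prolongs the contraction. This package implements the
force-recording analysis that quantifies that impairment, classifies
subjects by it, and runs the accompanying nonparametric cohort statistics,
together with a synthetic burst-drive simulator so the whole pipeline is
testable end to end without clinical data.

## The measurement

Given a single-channel force recording F(t) (200 Hz, normalized to percent
of maximal voluntary contraction, %MVC):

- **Derivatives.** RFD = F′(t) and F″(t) are estimated by a moving
  least-squares slope with a 50 ms centered window (11 samples at 200 Hz);
  F″ is the moving slope of the RFD series.
- **Pulses.** Candidate peaks are local force maxima ≥ 10 %MVC at least 1 s
  apart. A 20 %MVC/s RFD threshold fixes each pulse's onset and offset.
- **Segments.** On the interval from onset to the force peak (and to F90,
  the first sample ≥ 90% of peak force), the number of segments is
  `⌈(Z + 1)/2⌉` where Z is the number of zero crossings of F″. Segment
  boundaries are the F″ minima (segment ends) and maxima (segment starts)
  between successive crossings; the plateaus between consecutive segments
  are the slowing periods.
- **Per subject.** 41 pulses peaking in 20–60 %MVC are drawn at random
  (seeded); medians of every pulse metric are taken. A Parkinson's subject
  with median segments-to-F90 ≥ 2 is classified PD_Seg, otherwise PD_NoSeg.
- **Cohort.** Segmentation prevalence uses an exact binomial test against
  50% with a Clopper-Pearson 95% CI. Group comparisons use Kruskal-Wallis
  with Dunn pairwise follow-ups (Bonferroni-adjusted, effect size
  r = |z|/√n), Mann-Whitney U for two-group contrasts, and Friedman's test
  with step-down homogeneous subsets for ordinal segment/slowing durations.

## Worked example

`examples/01_segment_a_pulse.py` builds a noiseless three-burst pulse
(86/65/52 ms bursts, 80/60 ms drive gaps) and segments it:

```
peak force        : 39.8 %MVC
time to peak      : 360 ms   time to F90: 350 ms
segments to peak  : 3   (F'' zero crossings: 5)
segment durations : [95, 65, 50] ms
slowing periods   : [85, 65] ms (generative gaps: 80/60)
```

The pipeline recovers the generative burst count exactly and the slowing
periods to within 5 ms. `examples/02_classify_subjects.py` classifies a
nine-subject synthetic cohort (all nine match their generative archetype),
and `examples/03_cohort_statistics.py` prints the full inferential report
for a 39/18/22 cohort, e.g.

```
prevalence: 39/57 = 68% segmented, p = 0.008, 95% CI [0.55, 0.80]

n_segments_to_f90: Kruskal-Wallis H(2) = 73.4
  PD_Seg    vs PD_NoSeg : z =  6.77, p_adj = 3.97e-11, r = 0.90
  PD_Seg    vs OA       : z =  7.23, p_adj = 1.44e-12, r = 0.93
  PD_NoSeg  vs OA       : z =  0.00, p_adj = 1, r = 0.00
```

meaning roughly: two-thirds of the simulated Parkinson's subjects are
segmented (the interval excludes 50%), and the segmented group differs
from both other groups in median segment count with very large effect
sizes, while the non-segmented group is indistinguishable from the healthy
older adults.

## Command line

A thin CLI wraps the same functions:

```
motorseg simulate --out data/ --seed 1            # synthetic cohort as CSVs
motorseg analyze  --data data/ --out results/ --seed 1
motorseg stats    --summaries results/subjects_summary.csv --out stats/
```

`analyze` writes a per-pulse table, a subject-summary table, the stats
report (JSON) and the resolved run configuration; reruns with the same
inputs and seed are byte-identical.

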