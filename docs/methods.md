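# Methods

`pct` implements a single-unit and population analysis chain for
trial-structured spike data from tactile tasks — touch mapping, response
latency, receptive-field gradients and cued tactile imagery — together with
a ground-truth spike-train simulator of those four paradigms. This note
documents the models, the parameter choices, and the reasoning behind the
design decisions that were genuinely open.

## The generative model

Every simulated unit is an inhomogeneous Poisson process

    lambda_i(t) = b_i + G_{i,c,epoch} * r((t - t_on - L_i) / rise)

with baseline `b_i` (Hz), a condition- and epoch-specific gain `G` (Hz), an
onset latency `L_i` (s) and a linear 0→1 ramp `r` of duration `rise`.
During the stimulus epoch the gain is the actual-touch gain `g[c]` on actual
trials and the imagery gain `m[c]` on imagery trials; on imagery trials the
cue–delay epoch additionally carries cue gains `u[c]`. The null condition
and actual touch to the insensate hands carry zero gain by construction —
they are the negative controls every analysis must leave empty.

Structure among the gains is what the analyses are later asked to recover:

- **Mirror symmetry.** Right-side gains are drawn first; left-side gains are
  the right gains plus `N(0, mirror_sigma)` asymmetry. `mirror_sigma = 0`
  yields exactly bilateral fields; `independent_sides=True` draws the two
  sides independently (the maximally asymmetric control).
- **Shared actual/imagery substrate.** `m[c] = kappa * g[c] + (1 - kappa) *
  unique`, so `kappa` (`imagery_share`) is the known fraction of imagery
  coding inherited from actual touch. The insensate hand's imagery gain is
  drawn independently of this mixture (`hand_imagery_scale`), reflecting the
  dissociation in which the hand responds to imagined but not actual touch;
  set it to zero to make the mixture exact everywhere.
- **Cue-delay coding.** `u[c] = alpha * m[c] + (1 - alpha) * unique`
  (`cue_share`), applied only during the cue–delay of imagery trials — the
  only epoch in which the cue is informative to the subject.
- **Gradient-task fields.** Gains over the nine collinear sites follow a
  Gaussian spatial profile with random centre, width 1.5–4 cm and
  Gamma-distributed amplitude, so field-size estimation has a ground truth.

Spikes are generated by thinning a homogeneous process at the per-trial rate
ceiling; the draw is exact for the piecewise-linear rate and byte-identical
for a fixed seed.

### Default parameters and why

| parameter | default | rationale |
| --- | --- | --- |
| `n_units` | 100 | one microelectrode-array session's yield |
| `tuned_fraction` | 0.7 | produces a ~0.70 responsive fraction under the default selection thresholds, matching the regime where roughly two-thirds of recorded units respond to touch |
| `baseline_mean` | 5 Hz | Gamma(2)-distributed baselines typical of parietal units |
| `gain_mean` | 35 Hz | Gamma(2)-distributed per-field gains; see below |
| `part_prob` | 0.55 | per-body-part field participation, giving the diverse 0–4 field counts per side the field-count analysis tallies |
| `mirror_sigma` | 0.5 Hz | small residual left/right asymmetry |
| `imagery_share`, `cue_share` | 0.6, 0.5 | partially shared coding between formats and epochs |
| `latency_mean`, `latency_jitter` | 50 ms, 5 ms | short-latency tactile onset with a tight within-area spread |
| `ramp_rise` | 15 ms | fast onset transient |
| trials/condition | 10 (mapping, gradient), 8 (latency, imagery) | the emulated session designs |
| epoch durations | 1.5 s cue, 1 s delay, 3 s stimulus (touch tasks); 0.5 s cue, 2 s delay (imagery task) | the emulated trial timelines; one timing is used for both formats within the imagery task so that cue-aligned windows are comparable across formats |
| contact jitter | uniform [0, 0.3] s | experimenter delay between go cue and probe contact; harmless because latency analyses align to the contact event |

The gain scale deserves a note. The population-latency method summarises
2 ms-binned, unsmoothed spike counts by the first principal component of the
units × (time · condition · repetition) matrix. At that bin width the
per-bin Poisson noise eigenvalues compete directly with the rank-one signal
eigenvalue, and PC1 only locks onto the touch response when the summed
squared gains clear the largest per-unit noise variance. A mean per-field
gain of 35 Hz on a 5 Hz baseline — strong but within the range of driven
somatosensory responses — puts the simulated population in the regime the
method was designed for: a clean population onset visible in PC1. The same
setting leaves the responsive fraction, decoding and similarity analyses in
realistic (non-saturated-at-floor, non-degenerate) regimes.

### What the generator does not emulate

No refractoriness or spike-history dependence, no correlated noise across
units, no slow drifts or adaptation across trials, no waveform-level detail
(unit SNR and isolation class are carried as metadata only). Passing tests
therefore certify the analysis chain against Poisson trial-exchangeable
data with known structure — not against every pathology of chronic array
recordings, where correlated noise in particular can widen all the null
distributions used here.

## Analysis models

**Unit selection.** Units with session-wide mean rate > 0.5 Hz and SNR > 0.5
are retained; both are strict inequalities, and the mean rate is computed
over all trial time, treating it as a unit-quality statistic rather than a
task quantity.

**Tuning.** Stimulus-window mean rates (0.5–2.5 s after go; half-open
windows throughout) are regressed per unit on condition indicators, pooling
the 1.5 s pre-cue baseline samples as the zero-indicator reference.
Per-condition t-tests and the overall F-test are computed vectorised across
units; all unit × condition t-tests in one analysis form a single
Benjamini–Hochberg family (the most conservative reading of "FDR
corrected"), and the F-tests form a second family across units. With the
baseline omitted the model's F-test is algebraically the one-way ANOVA
across conditions, which is exposed directly for the discrimination counts.
The population chi-square compares the responsive-unit count against the
`alpha * N` expected by chance in a 2-cell goodness-of-fit with df = 1;
this construction is an interpretation — the source analyses do not spell
out the cells — and is flagged as such.

**Decoding.** Gaussian classes with equal diagonal covariance: per-unit
variances pooled across conditions, floored at 1e-6 Hz² to avoid degenerate
discriminants; uniform priors; argmax ties break to the earlier condition.
Leave-one-out folds iterate trials in stored order, so confusion matrices
are bit-reproducible. Note that leave-one-out decoders are pessimistically
biased at the null (the held-out trial's class mean moves away from it), so
chance-level data decode slightly *below* 1/k; calibration checks use exact
binomial bands that account for the direction of this bias.

**Population similarity.** Condition-mean population vectors are computed on
independent random halves of each condition's trials (odd trial counts put
the extra trial in the A half), compared across all condition pairs
including the diagonal — the within-condition noise ceiling — and averaged
over 250 splits, after which the matrix is symmetrised. No centering is
applied in this static analysis. Contrasts between two independent
correlation distributions use a pooled label-shuffle permutation test with
2000 shuffles and the add-one p-value.

**Mirror symmetry at the population level.** Whether a left–right
correlation is "at the ceiling" is tested by relabeling which side each
trial belongs to and recomputing the split-half ceiling-minus-cross deficit
under each relabeling. Under mirror-symmetric coding the two sides' trials
are exchangeable, making this test exactly calibrated. The alternative —
feeding the 250 correlated split resamples into the pooled-shuffle contrast
— is not used for this purpose: its null width shrinks as the split count
grows while the trial-sampling noise in the statistic does not, so it
rejects even exactly symmetric populations at a rate that grows with
`n_splits`. The pooled-shuffle contrast remains the right tool when the two
distributions come from genuinely different measurements.

**Latency.** Trials align to probe contact; counts in 201 two-millisecond
bins spanning −150 ms to +252 ms (the span is stated inclusively as
−150–250 ms in the emulated design; the half-open grid needs the extra
2 ms to hold 201 bins). PC1 loadings come from the row-centred SVD; the
sign is oriented so the post-contact mean exceeds the pre-contact mean;
single-trial traces are projections onto the fixed loadings. The
three-segment continuous piecewise-linear fit is found by exhaustive search
over breakpoint pairs on the bin grid — made cheap by precomputing the
Gram matrices of the four-column basis for every candidate pair — followed
by Nelder–Mead refinement of the breakpoints. Latency is the earliest
crossing of the fitted function above the 95th percentile of the raw
baseline values in [−150, 0) ms; a never-crossing fit returns a flagged
undefined estimate. The bootstrap resamples single-trial traces with
replacement, re-averages, re-fits (at grid resolution) and re-thresholds;
1000 resamples give the interquartile range. A caveat recorded here because
the benchmark reports it: a correctly calibrated bootstrap quartile
interval is a central 50% interval, so its coverage of the true latency
across replicate sessions concentrates near 50%; the IQR describes
resampling spread, not a high-coverage confidence interval.

**Receptive fields.** Field counts tally FDR-significant lateralised sites
per side into a 5 × 5 matrix. Peak-structure classification restricts to
units with an FDR-significant ANOVA over the four collinear sites, takes the
argmax site (ties toward the list start), walks outward, and tests each
adjacent pair beyond the peak one-tailed. A unit is multi-peak when a
farther site *significantly* exceeds its nearer neighbour (BH over the
unit's pair tests); the alternative reading — any non-significant decay
step implies a second peak — is available behind
`criterion="nonsignificant_decay"` but would label most units multi-peak at
small trial counts, which is why significant reversal is the default.
Gaussian field sizing fixes the centre at the preferred site, fits
amplitude, width and offset by bounded nonlinear least squares from three
starts, and reports the full width at half maximum, `2 sqrt(2 ln 2) sigma`.
The single-unit mirror R² predicts left-side trials either from the
remaining left trials (leave-one-out) or from the right-side condition
means with one random right trial dropped per fold so both predictors see
the same amount of training data.

**Temporal dynamics.** Sliding 500 ms windows stepped at 100 ms (50 ms base
bins so window edges, steps and the 0.25–0.75 s crossnobis reference all
fall on bin edges). One leave-one-trial-out partition is reused at every
train × test window pair so every matrix entry reflects the same amount of
training and test data; per-fold class statistics are maintained by
rank-one downdates and all window pairs are scored in one vectorised pass.
The crossnobis estimate whitens fold-wise mean differences from the
reference window by the diagonal covariance pooled from reference-window
residuals (same variance floor as the decoder) and multiplies independent
folds, making it unbiased at the null and equal in expectation to the
squared whitened separation otherwise; fold assignments are random, seeded,
and averaged. The single-unit variant of the generalization matrix feeds
each unit's matrix into a units-as-observations PCA. The cross-format
correlation builds, per window and trial split-half, a (2N × 2) matrix of
trial-averaged rates (rows: units × the two right-side sites, columns:
actual and imagined), subtracts each matrix's global mean, and correlates
train and test columns across all window pairs as cosines of the centred
columns — the global centering is what makes the cosine meaningful, and a
per-column Pearson would silently undo it. Fifty random splits are
averaged, with 4/4 train/test halves at the emulated 8 trials per
condition.

## Benchmarks and their problem sizes

`pct.benchmarks` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) re-derives the chain's headline properties from
scratch: latency recovery at 30/50/80 ms (100 units, 8 trials/condition, 20
replicate sessions per latency sharing one population, 1000 bootstrap
resamples), decoder chance calibration on untuned sessions and separable
decoding with independently drawn sides, realised false-discovery
proportion on 20 fully null 1000-unit populations, mirror-symmetry recovery
on 20 replicates each of mirrored and independent-sides generators,
crossnobis calibration against its analytic expectation, cross-epoch
generalization across shared-coding fractions 0/0.5/1 (60 units, 10
replicates each), cross-format recovery for fully shared vs orthogonal
imagery coding (fully tuned populations, so the tuned/untuned indicator
cannot masquerade as shared coding), and exact small-instance agreement
with brute-force oracles. Replicate counts are the package's chosen
trade-off between statistical resolution and a suite that runs in a few
minutes on one CPU.

## Known limitations

- All calibration claims inherit the generator's assumptions; correlated
  noise or non-Poisson dispersion in real recordings would widen the null
  distributions of every permutation and bootstrap procedure used here.
- The latency bootstrap IQR is a spread statistic, not a coverage interval
  (see above).
- The chi-square population test and the peak-structure criterion encode
  documented interpretations of under-specified procedures.
- The permutation test comparing the two sides' latency distributions
  operates on bootstrap draws; with many draws it resolves sub-millisecond
  differences, so its p-value should be read together with the effect size.
- Epoch timing within the imagery task is shared between formats; analyses
  that depend on format-specific delay lengths are out of scope.
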