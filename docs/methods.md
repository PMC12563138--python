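# Methods

## The estimator

Histomorphometric studies of grafted sites report, per healing time, the
percentage of evaluated tissue area occupied by newly formed bone (B) and by
residual graft (G). The break-even point is the time t* at which B = G and
the shared level y* at that time. The estimator assumes linear progression
between observation times: two-point lines are drawn through the bone and
graft observations over one segment (t₁, t₂) and intersected in closed form,

    t* = (c_g − c_b) / (m_b − m_g),   y* = m_b t* + c_b.

The two-point fit is exact by construction (the lines pass through the
anchoring observations), so the estimate is fully determined by the four
observed percentages and two times — there is no residual error to
propagate, which is also why the source studies report point estimates only.

**Segment selection.** With more than two time points, the segment whose
endpoints bracket the sign change of B − G is chosen — the two observations
closest to the anticipated crossing, where the secant approximation is most
accurate. Ties resolve to the earliest such segment; an exact equality
B = G at an observed time counts as a crossing there. Without any sign
change the last segment is used and the crossing projected forward.

**Validity classification.** Every geometry maps to a status rather than an
exception:

| status | condition |
|---|---|
| `within_interval` | t₁ ≤ t* ≤ t₂ (interpolation) |
| `extrapolated` | t₂ < t* ≤ f·t₂ (accepted forward projection) |
| `not_reached` | t* > f·t₂ (projection too far; reported NA) |
| `already_crossed` | t* < t₁ (bone already above graft at entry) |
| `divergent` | m_b ≤ m_g (parallel or separating lines; reported NA) |

The bound f is `max_extrapolation_factor`, default **1.5** (dimensionless
multiple of the last observation time). The default separates the accepted
projections in the bundled dataset (ratios up to ≈1.37) from the rejected
one (≈1.77, a ≈318-day projection from a 180-day last observation, where
bone formation and graft resorption had visibly plateaued). There is no
biological law behind any particular value, so it is configurable; analyses
should state the bound used.

For `not_reached`, `already_crossed` and non-parallel `divergent` geometry
the intersection coordinates are retained on the result object for
diagnostics and for re-classification under a different bound, but report
renderers print NA for `not_reached` and `divergent`. This keeps the
estimator exactly symmetric under exchanging the two lines (the coordinates
are invariant; only the status, which encodes the biological orientation,
changes).

**Numerical notes.** When the computed t* lands within 1e-12 (relative) of a
segment endpoint it is snapped to that endpoint, so an observed equality
B = G is reported at exactly that time. Internal values are never rounded;
report renderers round to `report_decimals` (default 1) and mark
extrapolated rows with a footnote `a`.

**Units.** Times are normalized to days on input: weeks × 7, months × 30.
The bundled dataset's only month-denominated series is the non-convergent
one, where no plausible month length changes the classification.

**Replicates.** When per-animal rows are present they are aggregated to
arithmetic group means per time point before fitting (published inputs are
group means); raw replicates are kept for the bootstrap.

**Dimension loss.** Shrinkage of the whole augmented region between two
periods, (A₁ − A₂)/A₁ × 100, is a separate quantity from the graft's share
of the evaluated area; it is computed when total areas are supplied and may
be negative (gain).

## The simulator

`sim.KineticModel` provides a nonlinear ground truth to measure what the
linearity assumption costs:

    B(t) = b_max (1 − e^{−k_b t})                (monomolecular, default)
    G(t) = g_res + (g0 − g_res) e^{−k_g t}

with b_max + g0 ≤ 100 and rates per day. These are the simplest forms with
the qualitative phases seen in multi-interval healing data — rapid early
change, later stabilization. A normalized shifted logistic bone curve
(B(0) = 0, inflection at `t_mid`) is available for sigmoidal early healing.
B − G is strictly increasing, so the true crossing is the unique root of
B = G, found by bracketing root search to 1e-6-day tolerance.

**Sampling model.** Each simulated animal observes the curve values plus
independent additive Gaussian noise (sd in percent), truncated to [0, 100];
when a noisy bone/graft pair sums above 100, both are scaled proportionally,
preserving the compositional constraint with minimal distortion. The
published studies report no inter-animal variance, so default noise levels
in examples (1–3%) are illustrative, not calibrated. One integer seed
drives a single generator; the stream order within a dataset is time point →
animal → bone draw, graft draw. Monte-Carlo replicate datasets use
independent child streams spawned from the seed.

**Bias study.** `bias_study` simulates many datasets, runs the full linear
pipeline on each, and reports mean estimate, bias and RMSE against the exact
crossing, plus the fraction of datasets yielding a reportable crossing. Two
robust findings: the linear estimate converges to the truth as the sampling
times bracket the crossing more tightly (error roughly quarters when the
bracket halves, for these smooth kinetics — noiseless error 0.08 d at a
±2-day bracket vs 4.9 d at ±16 days for the reference model b_max = 40%,
k_b = 0.05/d, g0 = 50%, k_g = 0.03/d), and one-sided sampling far from the
crossing produces a systematic, curvature-determined bias. This supports
the design guidance that follow-up times should straddle the anticipated
crossing.

**Bootstrap.** With ≥2 labelled animals per time point,
`bootstrap_break_even` resamples animals with replacement within each time
point (the studies' randomization unit), re-runs the pipeline per resample,
and returns a percentile interval (95% default) for the break-even time,
recording the fraction of non-convergent resamples. Zero-variance
replicates collapse the interval to the point estimate; a fixed seed makes
the interval bit-reproducible.

## What the synthetic data does and does not show

The simulator emulates smooth monotone kinetics with independent Gaussian
measurement noise on group-level compositions. Real histomorphometry adds
features it does not model: correlated bone/graft errors within a section,
between-animal heterogeneity in kinetic parameters, section-orientation
effects (sagittal vs coronal sampling of the augmented region), and
non-monotone early phases. Passing tests therefore establish the
estimator's geometric correctness and its behavior under the stated kinetic
family, not accuracy guarantees for any particular animal model.

## Design choices and limitations

- The estimator is deliberately the two-point linear method; fitting the
  nonlinear kinetic model to real two-point data is not offered because two
  observations cannot identify five parameters.
- Percentages from different studies are treated as independent series;
  whether evaluated-area definitions make them commensurable across studies
  is a biological question the package does not resolve.
- Problem sizes in tests and examples (≤1000 random trend pairs for the
  grid-scan cross-check, ≤2000 bootstrap resamples, ≤200 bias-study
  replicates) were chosen as comfortably sufficient for the statistical
  statements being checked, and all run in seconds.
- The comparison table sorts by estimated crossing time with non-reportable
  rows last; byte-stable output across runs is a tested property.
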