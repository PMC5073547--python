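# Methods

## The screening tool and its score

`mskscreen` analyses a modified 8-item musculoskeletal prognostic
screening tool. The items are five psychosocial indicators (fear of
activity, catastrophising, anxiety, low mood, bothersomeness), two EQ-5D
function items ("some problems walking about", "some problems washing or
dressing", both yes/no), and the SF-12 bodily-pain item (positive for
the two most severe of its six response levels). Each item is
dichotomised to 0/1 and the tool score is the count of positive items,
range 0–8. Scores 0–3 classify a patient as at low risk of a poor
outcome, 4 or more as at medium/high risk. The tool deliberately has no
high-risk-only subscale here: there is no psychological-distress
reference standard in the data the tool is aimed at, so only the
low vs medium/high distinction is analysed.

Item dichotomisation accepts either pre-coded 0/1 indicators (the
canonical CSV input) or raw questionnaire text with a configurable
positive-response set per item (`MappingProfile`). The shipped default
follows the original tool's convention — agree/disagree statements
positive on "agree", bothersomeness positive for the top two categories,
EQ-5D items on "yes", SF-12 pain on "very severe"/"extremely". Any
unrecognised non-empty response is treated as negative so that profiles
only enumerate positive categories; a missing or non-binary value marks
the record incomplete and the error names the item.

## Outcome definition

The 6-month outcome is the SF-36 Physical Component Score (PCS),
population-normalised to 0 (worst) – 100 (best), consumed as a given
number. It is banded by fixed tertiles of the scale: poor ≤ 33,
middle (33, 66], good > 66. "Poor outcome" — the event all ROC and
cut-point analyses predict — is the most severe band. The boundary is
implemented so that a fractional value such as 33.5 falls in the middle
band, preserving the ≤ 33 poor rule exactly.

Missing data are handled by complete-case analysis: a record missing any
of the eight items or the 6-month PCS is excluded, with counts per
reason kept in an exclusion log. Exclusions plus analysed records always
equal the input rows.

## Discrimination: ROC, AUC, DeLong variance

Cases are poor-outcome patients; a patient is test-positive at threshold
c iff score ≥ c. The AUC is the Mann–Whitney functional — the
probability that a random case outscores a random control, with ties
credited 0.5 — computed in O((m+n) log(m+n)) via placement values and
identical (to 1e-12, verified by tests) to the trapezoidal area of the
empirical ROC curve and to brute-force pair enumeration.

The AUC variance uses DeLong's structural components:
`var = S10/m + S01/n`, the sample variances (n−1 denominator) of the
case and control placement values scaled by the group sizes. The
implementation reproduces R `pROC`'s `var()` to all printed digits on a
frozen instance. Confidence intervals are Wald, AUC ± 1.96·√var,
truncated to [0, 1].

Equality of AUCs across the five pain regions (disjoint patient groups,
hence independent AUCs with no covariance terms) is tested with the
inverse-variance-weighted chi-square

    Q = Σ wᵢ (AUCᵢ − Ā)²,  wᵢ = 1/varᵢ,  Ā = Σ wᵢ AUCᵢ / Σ wᵢ,

referred to χ²(k−1). A group with zero estimated variance (perfect
separation) has infinite weight; it is handled in the limit — it pins
the weighted mean at its own AUC and contributes no finite term — with a
warning, rather than by division by zero. Two zero-variance groups with
different AUCs yield Q = ∞, p = 0.

**Known limitation.** The Q statistic uses estimated weights, and with
few cases per group it is mildly anti-conservative: in our Monte-Carlo
studies with 5 groups of 200 patients (~37 cases each, discrete 0–8
scores, AUC ≈ 0.77) the true type-I error at α = 0.05 is around
0.06–0.07, falling back to ~0.05 by ~800 patients per group. The
inflation is a property of the statistic (Jensen-type bias of 1/v̂ plus
skewness of the AUC distribution), not of the variance estimator, which
is unbiased in the same experiments. Region-level comparisons on small
groups should be read with this in mind.

## Cut-point selection

For candidate cut-points c ∈ {1..8} (c = 0 and c = 9 are degenerate —
everyone or no one positive — and excluded by default, configurably):
sensitivity = P(score ≥ c | poor), specificity = P(score < c | not
poor), Youden's J = sensitivity + specificity − 1. Two selectors:

* **Youden**: the cut-point maximising J.
* **Specificity floor**: among cut-points with specificity ≥ 0.7 (i.e.
  false-positive rate < 30%, the a-priori clinical limit on
  overtreatment), the one maximising J; `objective="sensitivity"`
  switches to maximising sensitivity under the floor; `None` if no
  cut-point satisfies the floor.

Ties on the objective (within 1e-12, to absorb float summation noise)
break toward the lower cut-point — the higher-sensitivity choice, since
a screening tool prefers missing fewer poor-outcome patients. Both
selectors are held equal to exhaustive 2×2-table scans in tests.

## Descriptives

Cohort summaries report n, score mean and sample SD (n−1), the
percentage at the minimum (0) and maximum (8) score, region mix, poor-
outcome prevalence, and PCS mean/SD. Floor and ceiling effects are
flagged when strictly more than 10% of patients sit at the respective
extreme; exactly 10.0% is not flagged.

## Synthetic cohort generator

No patient-level data ship with the package, so the generator emulates
the statistical structure the analysis assumes, with one latent severity
per patient:

    θ ~ N(0,1)
    item_i | θ ~ Bernoulli(logistic(αᵢ + βᵢ θ)),  βᵢ ≥ 0
    region ~ Categorical(region mix)
    pcs_6m = μ − γ_region·θ + ε,  ε ~ N(0, σ²),  clipped to [0, 100]

A single latent factor is the simplest structure under which a summed
item score can discriminate the outcome: the item–item and item–outcome
correlations all flow through θ, and γ_region (PCS points lost per unit
severity) tunes each region's prognostic strength; γ = 0 gives a null
region with AUC 0.5. Randomness uses one root seed with named
`SeedSequence` sub-streams per variable block (latent, items, region,
outcome noise, missingness), so changing e.g. the region mix leaves the
item draws of each patient index untouched. Missingness is
missing-completely-at-random, default 0 — it exists to exercise the
complete-case logic, not to model informative dropout.

Two presets emulate the published summaries of the cohorts the tool was
evaluated in: `cohort1`, a community-physiotherapy cohort (target score
mean 3.35, SD 2.09, floor 8.4%, ceiling 2.2%, poor outcome 18.5%, PCS
43.7 (10.9), region mix lower limb 31.1 / back 28.7 / upper limb 23.5 /
neck 11.8 / multisite 4.8%), and `cohort2`, an interface-service cohort
(mean 3.95, SD 2.65, floor 12.6%, ceiling 10.9%, poor 28.2%, PCS
38.41 (12.76), mix 30.8 / 26.7 / 23.8 / 5.4 / 13.4%). Calibration was
done once, semi-analytically, and the constants committed:

1. Item intercepts αᵢ = a + s·δᵢ (δ a fixed difficulty-offset shape) and
   a common loading b were fitted by least squares to the score mean,
   SD, floor and ceiling, computed exactly by Gauss–Hermite quadrature
   over θ with a Poisson-binomial recursion for the score pmf
   (`calibration.py`).
2. The residual outcome SD was fixed at σ = 8 PCS points for both
   presets, chosen so the total PCS SD lands near the published values
   given the fitted γ's.
3. Per-region γ was solved so the model's exact population AUC (also by
   quadrature) equals each region's published AUC; μ was solved last so
   the mixture poor-outcome prevalence is exact. Because the tertile
   threshold (33) then pins μ, the PCS means come out ≈ 42.6/39.9 rather
   than the printed 43.7/38.41 — prevalence and discrimination were
   prioritised over the PCS mean, which feeds no downstream analysis
   beyond descriptives.

Clipping PCS to [0, 100] cannot move a value across the poor threshold,
so prevalence and AUC from the quadrature oracle are exact for the
clipped model; at these parameter values clipping is also numerically
negligible for the moments. Documented calibration tolerance at
n = 5000: ±0.15 on the score mean, ±3 percentage points on prevalence,
±2 points on each region share.

What the generator does **not** emulate: item-level content (the eight
items are exchangeable up to their intercepts — no "walking item is less
relevant for upper-limb pain" structure), region-specific item profiles,
informative follow-up attrition, demographics, and within-patient
longitudinal dynamics. Passing tests therefore show that the pipeline's
statistics behave correctly on data with the assumed latent-severity
structure and the published summary statistics — not that the tool is
valid in any real population.

## Problem sizes and seeds used by the test suite

Monte-Carlo checks use fixed seeds and these sizes, chosen to give
stable verdicts at interactive runtimes: AUC/selector oracle equivalence
on 500 random instances of n ≤ 200; bootstrap comparison at 500
cases / 500 controls with 2000 resamples; equality-test type-I error
from 2000 replicates of 5 × 200 patients; preset calibration at
n = 5000; CI coverage from 200 replicates of n = 5000 against a
10⁶-draw Monte-Carlo oracle. `scripts/acceptance.py` simulates the two
cohorts at their published sizes (1887 and 1082) and reports every
quantity from a fresh run of the full pipeline.
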