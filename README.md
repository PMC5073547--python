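# mskscreen

Risk-stratification analysis for musculoskeletal cohorts: scoring of a
modified 8-item prognostic screening tool, 6-month physical-health
outcome classification, per-pain-region discrimination (ROC/AUC), and
optimal risk cut-point selection — with a calibrated synthetic cohort
generator so the whole pipeline runs without access to patient data.

## The problem

Prognostic screening tools stratify primary-care patients by their risk
of a poor outcome so treatment can be matched to risk. A well-validated
9-item tool exists for low back pain; a modified 8-item version replaces
its back-specific items with generic ones (EQ-5D walking and
washing/dressing, SF-12 bodily pain) so it can be used across
musculoskeletal presentations. The analysis questions this package
implements, for epidemiologists and methods researchers:

1. Does the baseline tool score discriminate patients who will have a
   poor 6-month outcome, within each pain region (neck, back, upper
   limb, lower limb, multisite)?
2. Are the regional discriminative abilities equal?
3. Is there one score cut-point that works across regions and services?

## Model and statistics

* **Score**: count of 8 positive binary items, range 0–8; low risk if
  score ≤ 3, medium/high risk if ≥ 4.
* **Outcome**: SF-36 Physical Component Score (0–100) at 6 months,
  banded by tertiles ≤33 / (33, 66] / >66; *poor* = ≤ 33.
* **AUC**: Mann–Whitney, `A = P(S_case > S_ctrl) + ½P(tie)`, equal to
  the trapezoidal area under the empirical ROC curve; variance by
  DeLong's structural components `var = S10/m + S01/n` (matches R
  pROC); 95% CI `A ± 1.96·√var`.
* **Equality across k regions** (disjoint groups):
  `Q = Σ wᵢ(Aᵢ − Ā)²` with `wᵢ = 1/varᵢ`, `Q ~ χ²(k−1)` under H₀.
* **Cut-points**: per cut c ∈ {1..8} (positive iff score ≥ c),
  sensitivity, specificity and Youden's `J = se + sp − 1`; optimal cut
  by (1) max J and (2) max J subject to specificity ≥ 0.7
  (false-positive rate < 30%).
* **Synthetic cohorts**: latent severity θ ~ N(0,1); item i positive
  with probability logistic(αᵢ + βᵢθ); `pcs = μ − γ_region·θ + ε`,
  ε ~ N(0, σ²). Two presets reproduce the published summary statistics
  of a community-physiotherapy cohort (n=1887) and an interface-service
  cohort (n=1082). See `docs/methods.md`.

## Worked example

```sh
mskscreen simulate --preset cohort2 --n 1082 --seed 2 --out cohort2.csv
mskscreen analyze --in cohort2.csv --out report.json
mskscreen report --in report.json --format md
```

or, through the numbered analysis scripts:

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_descriptives.py
python analysis/03_regional_discrimination.py
python analysis/04_cutpoint_selection.py
```

which prints, for the interface-service preset (seed 1):

```
cohort2: n=1082 (excluded 0), score 3.89 (SD 2.65), floor 12.7% / ceiling 11.6%
[floor effect, ceiling effect], poor outcome 27.4%

cohort2: per-region discrimination
  neck        n=59   poor=23  AUC 0.93 (95% CI 0.86-0.99)
  back        n=318  poor=81  AUC 0.74 (95% CI 0.68-0.80)
  upper_limb  n=229  poor=62  AUC 0.87 (95% CI 0.81-0.92)
  lower_limb  n=327  poor=87  AUC 0.84 (95% CI 0.80-0.89)
  multisite   n=149  poor=43  AUC 0.79 (95% CI 0.71-0.87)
  equality test: chi2=19.70, df=4, p=0.001 -> regional AUCs differ at the 5% level

cohort2: selected cut-points (positive iff score >= cut)
  neck        Youden's J -> 6   specificity>=0.7 -> 6
  back        Youden's J -> 5   specificity>=0.7 -> 6
  ...
A single cut-point would NOT serve all pain regions within each service.
```

Reading the output: the score discriminates poor 6-month outcome in
every region (AUCs 0.74–0.93); the score distribution in this service
shows both floor and ceiling effects (>10% at 0 and at 8); and the
optimal cut-point shifts between 5 and 6 depending on region and
selection rule, so a single shared cut-point would misclassify some
regions. (The equality test rejects here because the synthetic model
bakes the published between-region AUC differences in as true effects.)

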