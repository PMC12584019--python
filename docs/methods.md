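# Methods

## The staging problem

ClinFIT (Clinical Functioning Information Tool) summarises an inpatient's
functioning as a total raw score of 0–300 (30 ICF-derived categories, each
0–10; higher = greater functional limitation). On its own the total does not
stage a patient. `clinstage` derives integer cutoffs on that scale which
stratify patients by *rehabilitation intensity*, using the Therapy
Disciplines (TD) domain of the Rehabilitation Complexity Scale v2 as the
ordinal reference: TD0 no therapist involvement, TD1 one discipline, TD2
two–three, TD3 four or more. TD counts **delivered** services, so the staging
reflects provision, not directly assessed need.

## The stepwise ROC procedure

For the highest TD level `L` present down to 1:

1. On the current sample, form the cumulative dichotomy
   positives = `td >= L`, negatives = `td < L`. The dichotomy is cumulative
   rather than level-vs-adjacent-level-only: it is the only reading under
   which each step's confusion-matrix total equals the previous total minus
   the previous predicted positives, which is the bookkeeping the derivation
   tables follow.
2. Evaluate every integer cutoff 0–300 (ClinFIT totals are integer sums; no
   observed-score midpoints) and keep the one maximising the Youden index
   `J = Se + Sp − 1`. Ties are broken toward the smallest cutoff; the
   comparison inside the search uses the exact integer numerator
   `tp·n_neg − fp·n_pos` so that mathematically tied cutoffs are true ties.
3. A score is predicted positive when `score >= cutoff`. Exclude the
   predicted positives and continue with the remainder. Exclusion removes
   *predicted* positives, not true-label positives — this is what makes the
   remaining-sample recursion `n_{k+1} = n_k − (tp_k + fp_k)` hold.
4. A comparison whose positive or negative class is smaller than
   `min_class_size` (default 2 — derivations have legitimately run with as
   few as 2 positives) is skipped with an audited warning.

After the loop, retention rules run: a candidate is dropped if its AUC is
below `min_auc` (default 0.6) or its Youden index below `min_youden`
(default 0.3); then, while any adjacent pair of survivors is separated by
fewer than `min_separation` points (default 15 = 5% of the scale), the
member with the lower Youden index is dropped and separation re-checked.
The paper trail does not say which member of a too-close pair to discard;
dropping the weaker discriminator is this package's choice. The merge loop
terminates because each iteration removes one cutoff.

A provisionally retained cutoff still causes exclusion for subsequent steps
even if it is later dropped — the derivation is strictly sequential and the
audit records the order effect. `refit_after_drop=True` instead re-runs the
sequential pass with dropped comparisons disabled until stable; it is off by
default because the sequential narrative is the reference behaviour.

Retained cutoffs `c1 < … < cK` give `K+1` stages with bands
`[0, c1), …, [cK, 300]`; with two cutoffs the stages are named
light / moderate / high. Note the boundary convention: with cutoffs
(135, 192), a score of 135 is already *moderate* (`>=` at the boundary).
The convention is fixed by the derivation tables — predicted positives are
`score >= cutoff` and the resulting stage counts match the published
83/82/105 split — even though band prose elsewhere sometimes writes the
light band as "≤ 135", which differs by exactly the boundary point.

### Undefined metrics

Sensitivity/specificity with an empty class, AUC with one class present, or
a paired t with zero-variance differences raise errors rather than return
sentinels. Subgroup steps can genuinely run out of positives; that must
surface, not be averaged over.

### Manual overrides

`forced_cutoffs={level: cutoff}` replaces the Youden search at a step, and
`excluded_candidates={level: [values]}` removes specific values from the
search. Both are flagged in the audit and logged; they exist because
published subgroup tables occasionally reflect hand-substituted thresholds
(one diagnosis subgroup swapped a statistically admissible but insensitive
threshold for a more balanced pair), and such judgment calls must be
reproducible *as overrides*, never silently automated.

## Subgroup analyses

Strata are marginal, one factor at a time — sex, age band (boundary 65,
`>=` inclusive on the older side), diagnosis group (stroke / MSK / cancer /
other) — each running the identical procedure with identical criteria.
Crossed strata are not supported: crossing explodes sparsity and has no
reference output to compare with. Steps whose positive class has fewer than
10 members are flagged "exploratory" in reports. Strata where no comparison
can run yield 1-stage models with warnings, not failures.

## Paired pre/post statistics

Admission vs discharge totals are compared with a classical paired t-test
(patients missing discharge are excluded and counted). The effect size is
the paired-design Cohen's `d_z` = mean(differences) / SD(differences);
differences are oriented admission − discharge so positive = improvement.
The algebraic identity `t = d_z · sqrt(n)` is used as an internal check.
The default 95% CI is the normal approximation
`d ± 1.96 · sqrt(1/n + d²/(2n))`; a noncentral-t inversion is available via
`ci_method="nct"`. The `d_z` variant and the normal CI are assumptions — the
variant used upstream of the reference values is not stated — and are
therefore reported explicitly. Bands follow Cohen: 0.2 / 0.5 / 0.8 =
small / medium / large (below 0.2 reported as negligible).

## The synthetic-data generator

Patient-level data for the derivation cohort are not deposited, so the
generator emulates its published structure:

| parameter | default | source/rationale |
|---|---|---|
| `n` | 270 | cohort size |
| `admission_mean`, `admission_sd` | 165.3, 59.4 | printed admission moments; scores are a rounded normal clipped to [0, 300] |
| `discharge_mean_improvement` | 67.8 | 165.3 − 97.5 |
| `improvement_sd` | 57.5 | back-derived from the printed paired d = 1.18 (67.8 / 1.18) |
| `td_thresholds` | (141, 198, 260) | quantiles of N(165.3, 59.4²) at the cumulative TD proportions 34.4 / 70.7 / 94.4%, so the TD marginals land on 34.4/36.3/23.7/5.6% |
| `td_noise` | 0.1 | no error model is published for referral counts; 0.1 yields step AUCs in the 0.7–0.9 range typical of the reference tables |
| `sex_male_prop`, `age_mean`, `age_sd` | 0.541, 62.9, 14.3 | printed demographics |
| `diagnosis_props` | 0.330/0.211/0.233/0.226 | printed diagnosis mix |

The latent TD level is the number of planted thresholds at or below the
admission score; the observed level is perturbed by ±1 (direction
equiprobable) with probability `td_noise`, clipped to 0–3. Everything is
reproducible from `seed`.

What the generator does **not** emulate, and hence what passing tests do not
show about real data: the real score distribution is bounded and skewed, not
a clipped normal; the real age distribution puts 49.6% at ≥ 65 whereas
N(62.9, 14.3²) implies ≈ 44%; demographics are drawn independently of scores
(no published joint structure); discharge clipping at the scale floor means
the generator's discharge mean is ≈ 102 rather than the printed 97.5
(≈ 12% of raw discharge draws fall below 0) while the implied effect size
stays ≈ 1.18 because the clipping shrinks the mean and SD of the differences
nearly proportionally; and real within-TD-level score distributions are
unknown — the latent-band + symmetric-noise link is one admissible model,
not an estimate.

### Exact confusion fixtures

`cohort_from_confusion_fixture` turns a published cutoff-performance table
(ordered `(cutoff, tp, fp, tn, fn)` rows, highest comparison first) into a
cohort that replays the table cell-for-cell when the stepwise procedure is
run with those cutoffs forced. Scores are placed mid-band (robust to
off-by-one convention changes); TD labels are minimal (positives at the
dichotomy's upper level, negatives one below), except carried false
negatives, which keep their higher level so later steps' cells come out
exactly. The builder validates the remaining-sample identity and the
carried-positive feasibility and rejects inconsistent tables — including one
published diagnosis-subgroup table whose rows, reflecting a manual threshold
substitution, do not satisfy the sequential identity.

## Problem sizes and numerical choices

Recovery experiments use n = 5000 per cohort with planted thresholds
(135, 160, 192): large enough that every integer score near a threshold is
observed, which is what makes noise-free recovery exact (the smallest
Youden-maximising cutoff is then the planted threshold itself). The noisy
experiment uses 100 seeds at `td_noise = 0.1` and asks for recovery within
±5 points in ≥ 95 of them. Presentation rounding is half-up — 3 decimals for
proportions, 1 decimal for means/SDs/percentages — applied only at the
reporting boundary; internal arithmetic is unrounded. Percentage blocks in
summaries may sum to 100 ± 0.2 (up to four categories × 0.05 rounding
drift); values are plain roundings, never largest-remainder adjusted.

## Known limitations

Cutoff uncertainty (bootstrap CIs), cross-validated or externally validated
cutoffs, ordinal-regression or tree-based alternatives, and item-level
ClinFIT simulation are out of scope. The reference cutoffs themselves were
derived on a single-centre cohort and are exploratory; this package
reproduces and generalises the *procedure*, it does not validate the
thresholds clinically.
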