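# Methods

## Scope and model

`credmeta` synthesizes case-control genetic association evidence for a
variant-disease pair from study-level genotype counts. Each study
contributes six counts (hom-major / het / hom-minor for cases and
controls). The association model is the additive (allele) model on the
labelled minor allele: each subject contributes two alleles, the study
effect is the log odds ratio of the minor-vs-major allele 2×2 table,

    log OR = ln[(a·d)/(b·c)],   SE = sqrt(1/a + 1/b + 1/c + 1/d),

with a Haldane–Anscombe continuity correction (+0.5 to all four cells)
when any cell is zero (on by default; the correction flag travels with
the estimate). Genotype-level models (dominant/recessive/codominant) are
out of scope. The minor allele is the dataset's declared label and is not
re-derived per study, so a pooled control "MAF" above 0.5 is reported
as-is rather than flipped; this keeps summaries comparable across studies
whose sample frequencies straddle 0.5.

## Pooling and heterogeneity

Pooling is inverse-variance on the log OR (not Mantel–Haenszel): it is the
estimator consistent with the per-study OR/CI arithmetic used everywhere
else in the pipeline. Cochran's Q, I² = max(0, (Q−df)/Q)·100, and the
DerSimonian–Laird moment estimator τ² = max(0, (Q−df)/C) with
C = Σw − Σw²/Σw are computed from the fixed-effect weights. The model per
association is chosen by the heterogeneity rule — random effects when
P_Q < 0.1, fixed otherwise — with `fixed`/`random` available as forced
settings in `AnalysisConfig.model_selection`. I² bins: mild ≤ 25,
moderate 25–50, large ≥ 50 (boundaries assigned to the outer bins). An
association needs at least three independent datasets; smaller groups are
flagged ineligible and skipped with a note rather than an error.

One test cross-checks the DL machinery (pooled estimate, SE, Q, τ²)
against `metafor::rma(method="DL")` via Rscript; the R package is an
oracle only, never the implementation.

## Bias battery

* **Egger regression**: OLS of θ/SE on 1/SE; the intercept's two-sided t
  test (df = k−2) at level 0.1.
* **Begg rank correlation**: Kendall's τ between
  (θ_i − θ̂_fixed)/sqrt(v_i − v̂) and v_i, tie-corrected asymptotic p.
* **Excess significance**: observed count of studies with p < 0.05 versus
  the sum of per-study powers to detect the pooled (chosen-model) estimate
  as plug-in true effect; 1-df chi-square form
  (O−E)²·[1/E + 1/(k−E)], flagged when p < 0.1 *and* O > E. When E
  reaches 0 or k the statistic degenerates and the test abstains (p = 1).
* **Sensitivity**: leave-one-out, drop-the-earliest-study (all studies
  tied at the minimum year drop together), and drop-HWE-violators
  (control-genotype chi-square p < 0.05). Scenarios that would leave
  fewer than three studies are recorded as not evaluable. A
  non-significant base association returns an all-false, non-applicable
  report.

## Credibility grading

Venice letters:

* **Amount of evidence** — combined minor-allele count in cases +
  controls: A > 1000, B 100–1000, C < 100 (standard published rubric; in
  summary mode the count is approximated by MAF · 2 · (cases+controls)).
* **Replication** — A/B/C from the mild/moderate/large I² bins. Published
  letters occasionally reflect subgroup-consistency judgments a pure I²
  rubric cannot reproduce; `venice_grade` accepts a
  `replication_override` for curated letters but never guesses one.
* **Protection from bias** — C on any hard indicator (Egger or Begg
  p < 0.1, excess significance, any sensitivity loss, or a pooled effect
  with max(OR, 1/OR) < 1.15); B only via configured soft indicators
  (default none); A otherwise.

FPRP follows FPRP = p(1−π) / [p(1−π) + π·power] with prior π = 0.05 and
power computed against a detectable OR of 1.5 at α **equal to the
observed p** — the convention that reproduces published FPRP columns when
the SE is reconstructed from a printed CI as ln(CI_hi/CI_lo)/3.92.
Protective effects are assessed against 1/OR0, making FPRP symmetric
under OR → 1/OR. Noteworthiness is FPRP < 0.20.

The combined call starts from the letters (strong = AAA, weak = any C,
else moderate) and moves one level up when FPRP < 0.05, one level down
when FPRP ≥ 0.20, bounded at strong/weak. Applied to the 29 packaged
published rows this rule reproduces every printed strong/moderate/weak
label and the 18/5/6 → 22-strong tallies, which is what the acceptance
tests assert.

### Numerical notes

* Critical values use `norm.isf(α/2)`, which survives observed p-values
  small enough that 1−α/2 rounds to 1 in double precision.
* `fprp_from_summary` flags a CI whose log midpoint deviates from ln(OR)
  by more than 10% of the log half-width (`ci_consistent=False`): such
  rows carry printing/typo noise that reconstruction cannot survive, and
  reproduction checks exclude them. Two packaged rows trip the flag.
* A null summary OR gives p = 1, power = 1 and FPRP ≈ 1−π; the result is
  well-defined but scientifically vacuous.

Prospective power (`prospective_power`) is the classical two-proportion
normal-approximation test on allele counts (2n alleles per arm, null SE
pooled across arms), with the case allele frequency obtained by the odds
transform of the control MAF.

## Synthetic data

`simulate_association` draws, per study: arm sizes uniform on the
configured ranges; control genotypes multinomial from Hardy–Weinberg
proportions at the control MAF, optionally distorted by an inbreeding
coefficient f (heterozygosity shrinks by 1−f — controls only, since the
HWE filter inspects controls); a study-specific log OR ~
Normal(ln OR_true, τ²); case genotypes multinomial under HWE at the
odds-transformed case allele frequency (the allele-level odds model,
matching the analysis model — genotype-level ORs are not simulated).
Optional publication censoring drops each study whose own two-sided
allele-test p is ≥ 0.05 with probability `pub_bias_drop`, the simplest
mechanism that induces funnel asymmetry. Everything is reproducible from
`seed` via one `numpy` Generator.

Defaults (5 studies, 500–2500 subjects/arm, MAF 0.30, years 2007–2020,
Asian/Caucasian mix) mirror the scale of a typical candidate-gene
literature on which this kind of synthesis operates. The generator does
**not** emulate linkage disequilibrium between variants, covariate
confounding, population stratification, genotyping error, or overlapping
subject pools between publications — calibration results on simulated
data therefore speak to the statistical machinery, not to those
real-data pathologies.

## Calibration suite sizes

The test suite verifies, under the null simulator: pooled type-I error
≤ 7% and CI coverage 95% ± 2% (2,000 replicates each), Egger rejection
0.10 ± 0.04 (2,000 replicates), HWE p-value uniformity (5,000
replicates), and recovery of a true OR 1.5 within (1.3, 1.7) in ≥ 90% of
1,000 replicates. These sizes keep Monte-Carlo standard errors well
below the asserted bands while the whole suite runs in well under a
minute.

## Known limitations

* Summary-mode grading inherits the rounding of printed ORs/CIs; ±0.015
  absolute is the realistic FPRP reproduction tolerance.
* The amount-of-evidence letter in summary mode uses the control-MAF
  approximation to the combined minor-allele count.
* τ² estimation is DL only; REML/Paule–Mandel are deliberately out of
  scope.
* The excess-significance test uses the pooled estimate as plug-in truth;
  with few studies this is noisy and the test is conservative by design.
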