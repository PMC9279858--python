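"""Small-study/publication-bias tests, excess significance, sensitivity runs.

Three complementary batteries guard a pooled association:

* Egger regression (standardized effect on precision; non-zero intercept
  signals funnel asymmetry) and the Begg rank-correlation test.
* The excess-significance test: the observed number of nominally significant
  studies against the number expected from each study's power to detect the
  pooled effect.
* Sensitivity re-analyses: leave-one-out, dropping the earliest-published
  study (all studies tied at the minimum year are dropped together), and
  dropping studies whose controls violate Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .config import AnalysisConfig
from .effects import EffectEstimate, hwe_test
from .errors import InsufficientStudiesError
from .meta import MetaResult, pool_fixed, run_association
from .records import AssociationKey, StudyRecord


@dataclass
class ExcessSignificance:
    observed: int
    expected: float
    chi2: float
    p: float
    excess: bool


@dataclass
class SensitivityReport:
    leave_one_out_loss: bool = False
    first_study_loss: bool = False
    hwe_loss: bool = False
    robust: bool = True
    applicable: bool = True
    not_evaluable: tuple[str, ...] = ()


@dataclass
class BiasAssessment:
    egger_intercept: float
    egger_p: float
    begg_tau: float
    begg_p: float
    excess: ExcessSignificance
    sensitivity: SensitivityReport
    any_bias_signal: bool


def egger_test(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Egger regression: OLS of theta/se on 1/se.

    Returns the intercept and its two-sided t-test p-value (df = k - 2).
    """
    if len(effects) < 3:
        raise InsufficientStudiesError("Egger test needs at least 3 studies")
    x = np.array([1.0 / e.se for e in effects])
    y = np.array([e.log_or / e.se for e in effects])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[0]), float(fit.pvalues[0])


def begg_test(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation between standardized deviations and variances.

    Deviations from the fixed-effect pooled estimate are standardized by
    ``sqrt(v_i - v_pooled)``; the Kendall tau p-value uses the tie-corrected
    normal approximation.
    """
    if len(effects) < 3:
        raise InsufficientStudiesError("Begg test needs at least 3 studies")
    pooled, pooled_se = pool_fixed(effects)
    v_pooled = pooled_se**2
    v = np.array([e.se**2 for e in effects])
    u = np.array(
        [(e.log_or - pooled) / np.sqrt(e.se**2 - v_pooled) for e in effects]
    )
    res = stats.kendalltau(u, v, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def excess_significance(
    effects: Sequence[EffectEstimate],
    pooled_log_or: float,
    alpha: float = 0.05,
    threshold: float = 0.1,
) -> ExcessSignificance:
    """Observed vs expected number of significant studies (chi-square form).

    Per-study power is the two-sided normal power to detect the pooled log
    OR at level ``alpha`` given that study's standard error; at a null
    pooled effect each study's power equals ``alpha`` exactly.
    """
    if len(effects) < 3:
        raise InsufficientStudiesError("excess-significance needs at least 3 studies")
    k = len(effects)
    z_crit = stats.norm.isf(alpha / 2.0)
    mu = abs(pooled_log_or)
    powers = [
        float(
            stats.norm.cdf(mu / e.se - z_crit) + stats.norm.cdf(-mu / e.se - z_crit)
        )
        for e in effects
    ]
    expected = float(np.sum(powers))
    observed = sum(1 for e in effects if e.p < alpha)
    if 0.0 < expected < k:
        chi2 = (observed - expected) ** 2 * (1.0 / expected + 1.0 / (k - expected))
        p = float(stats.chi2.sf(chi2, df=1))
    else:  # all (or none) of the studies expected significant: nothing to test
        chi2, p = 0.0, 1.0
    return ExcessSignificance(
        observed=observed,
        expected=expected,
        chi2=chi2,
        p=p,
        excess=(p < threshold and observed > expected),
    )


def sensitivity_suite(
    records: Sequence[StudyRecord],
    key: AssociationKey | None = None,
    config: AnalysisConfig | None = None,
) -> SensitivityReport:
    """Re-run the association under each removal scenario.

    A "loss" is a base-significant association turning non-significant in a
    scenario.  Scenarios that would leave fewer than the minimum number of
    studies are recorded as not evaluable, never as failures.  A
    non-significant base association yields an all-false, non-applicable
    report.
    """
    config = config or AnalysisConfig()
    records = list(records)
    base = run_association(records, key, config)
    if not base.significant:
        return SensitivityReport(applicable=False)

    not_evaluable: list[str] = []

    def lost(subset: list[StudyRecord]) -> bool | None:
        if len(subset) < config.min_studies:
            return None
        return not run_association(subset, key, config).significant

    loo = False
    loo_any_evaluable = False
    for i in range(len(records)):
        outcome = lost(records[:i] + records[i + 1 :])
        if outcome is None:
            continue
        loo_any_evaluable = True
        loo = loo or outcome
    if not loo_any_evaluable:
        not_evaluable.append("leave_one_out")

    min_year = min(r.year for r in records)
    remaining = [r for r in records if r.year != min_year]
    first = lost(remaining)
    if first is None:
        not_evaluable.append("first_study")
        first = False

    keep = [r for r in records if not hwe_test(r, config.hwe_threshold).violates]
    if len(keep) == len(records):
        hwe = False  # nothing to drop: scenario coincides with the base analysis
    else:
        outcome = lost(keep)
        if outcome is None:
            not_evaluable.append("hwe")
            hwe = False
        else:
            hwe = outcome

    return SensitivityReport(
        leave_one_out_loss=loo,
        first_study_loss=first,
        hwe_loss=hwe,
        robust=not (loo or first or hwe),
        applicable=True,
        not_evaluable=tuple(not_evaluable),
    )


def assess_bias(
    records: Sequence[StudyRecord],
    meta: MetaResult,
    config: AnalysisConfig | None = None,
) -> BiasAssessment:
    """Run the full bias battery against an already-pooled association."""
    config = config or AnalysisConfig()
    effects = list(meta.effects)
    intercept, egger_p = egger_test(effects)
    tau, begg_p = begg_test(effects)
    excess = excess_significance(
        effects,
        meta.log_or,
        alpha=config.significance,
        threshold=config.bias_p_threshold,
    )
    sens = sensitivity_suite(records, meta.key, config)
    signal = (
        egger_p < config.bias_p_threshold
        or begg_p < config.bias_p_threshold
        or excess.excess
        or (
            sens.applicable
            and (sens.leave_one_out_loss or sens.first_study_loss or sens.hwe_loss)
        )
    )
    return BiasAssessment(
        egger_intercept=intercept,
        egger_p=egger_p,
        begg_tau=tau,
        begg_p=begg_p,
        excess=excess,
        sensitivity=sens,
        any_bias_signal=signal,
    )
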