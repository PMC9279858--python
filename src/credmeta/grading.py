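"""Venice-criteria grading, FPRP, power, and the combined credibility call.

The false-positive report probability (FPRP) of a nominally significant
association is

    FPRP = p(1 - pi) / [p(1 - pi) + pi * power]

where ``pi`` is the prior probability of a true association, ``p`` the
observed two-sided p-value, and ``power`` the probability of detecting a
specified odds ratio (OR0) at significance level alpha = p.  Evaluating
power at the observed p rather than a fixed 0.05 is the convention used
throughout; protective effects are assessed against 1/OR0 so the measure is
symmetric under OR -> 1/OR.

Venice criteria grade three axes A/B/C: amount of evidence (combined
minor-allele count), replication (between-study heterogeneity), and
protection from bias.  The combined credibility call starts from the Venice
letters (strong = AAA, weak = any C, else moderate) and moves one level up
when FPRP < 0.05 or one level down when FPRP >= 0.20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .bias import BiasAssessment
from .errors import NotGradeableError
from .meta import LARGE, MetaResult, MILD, MODERATE, classify_heterogeneity

STRONG = "strong"
WEAK = "weak"
_LEVELS = (WEAK, "moderate", STRONG)  # index = rank

#: 2 * 1.96, the printed-CI log-width divisor for SE reconstruction
_CI_WIDTH_Z = 2 * 1.96


@dataclass
class FPRPResult:
    prior: float
    or0: float
    p_used: float
    power: float
    fprp: float
    noteworthy: bool
    ci_consistent: bool = True


@dataclass
class VeniceGrade:
    amount: str
    replication: str
    bias: str

    def __post_init__(self) -> None:
        for letter in (self.amount, self.replication, self.bias):
            if letter not in ("A", "B", "C"):
                raise ValueError(f"Venice letters must be A/B/C, got {letter!r}")

    @property
    def as_string(self) -> str:
        return self.amount + self.replication + self.bias

    @classmethod
    def from_string(cls, text: str) -> "VeniceGrade":
        if len(text) != 3:
            raise ValueError(f"Venice grade must be 3 letters, got {text!r}")
        return cls(*text)


@dataclass
class CredibilityRating:
    venice: VeniceGrade
    fprp_value: float
    base_level: str
    final_level: str


@dataclass
class PowerSpec:
    """Inputs for a prospective allele-count power calculation."""

    n_cases: int
    n_controls: int
    maf: float
    detectable_or: float
    alpha: float = 0.05


def power_detect_or(se: float, or0: float, alpha: float) -> float:
    """Two-sided normal power to detect log(or0) given a standard error.

    ``power = Phi(ln(or0)/se - z) + Phi(-ln(or0)/se - z)`` with
    ``z = z_{1-alpha/2}``.  At or0 = 1 this equals alpha for any se.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0 < alpha <= 1:  # alpha = 1 arises from a null observed effect
        raise ValueError("alpha must be in (0, 1]")
    # isf survives alpha small enough that 1 - alpha/2 rounds to 1.0
    z_crit = stats.norm.isf(alpha / 2.0)
    mu = abs(math.log(or0)) / se
    return float(stats.norm.cdf(mu - z_crit) + stats.norm.cdf(-mu - z_crit))


def fprp(
    p_used: float,
    power: float,
    prior: float,
    or0: float = 1.5,
    noteworthy_level: float = 0.20,
) -> FPRPResult:
    """FPRP from an observed p, power against OR0, and a prior."""
    if not 0 < p_used <= 1 or not 0 < power <= 1 or not 0 < prior <= 1:
        raise ValueError("p_used, power and prior must be in (0, 1]")
    value = (p_used * (1 - prior)) / (p_used * (1 - prior) + prior * power)
    return FPRPResult(
        prior=prior,
        or0=or0,
        p_used=p_used,
        power=power,
        fprp=value,
        noteworthy=value < noteworthy_level,
    )


def fprp_from_summary(
    or_value: float,
    ci_low: float,
    ci_high: float,
    prior: float = 0.05,
    or0: float = 1.5,
    noteworthy_level: float = 0.20,
) -> FPRPResult:
    """FPRP from a published summary OR and its 95% CI.

    The standard error is reconstructed from the log-CI width,
    ``se = ln(ci_high/ci_low) / 3.92``; the observed p is the two-sided
    normal p of ``ln(OR)/se``; power is evaluated at alpha = p against OR0
    (reciprocal OR0 for protective effects, equivalent by symmetry).  A CI
    whose log midpoint deviates from ln(OR) by more than 10% of the log
    half-width (a printed-rounding / typo signature) is flagged
    ``ci_consistent=False``.
    """
    if not 0 < ci_low < or_value < ci_high:
        raise ValueError("require 0 < ci_low < OR < ci_high")
    half_width = math.log(ci_high / ci_low) / 2.0
    midpoint = (math.log(ci_high) + math.log(ci_low)) / 2.0
    consistent = abs(midpoint - math.log(or_value)) <= 0.10 * half_width

    se = math.log(ci_high / ci_low) / _CI_WIDTH_Z
    z = math.log(or_value) / se
    p_used = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    power = power_detect_or(se, or0 if or_value >= 1 else 1.0 / or0, alpha=p_used)
    result = fprp(p_used, power, prior, or0=or0, noteworthy_level=noteworthy_level)
    result.ci_consistent = consistent
    return result


def venice_grade(
    meta: MetaResult,
    bias: BiasAssessment,
    minor_allele_count: int | None = None,
    small_effect_or: float = 1.15,
    amount_a: int = 1000,
    amount_b: int = 100,
    bias_p_threshold: float = 0.1,
    replication_override: str | None = None,
    soft_indicator: bool = False,
) -> VeniceGrade:
    """Grade a significant pooled association on the three Venice axes.

    * amount: A when the combined (cases + controls) minor-allele count
      exceeds ``amount_a``, B when between ``amount_b`` and ``amount_a``,
      C below ``amount_b``;
    * replication: A/B/C from the mild/moderate/large I² bins, unless a
      subgroup-consistency judgment overrides the letter;
    * protection from bias: C on any hard indicator (Egger or Begg p below
      the bias threshold, excess significance, any sensitivity loss, or a
      pooled effect smaller than ``small_effect_or`` on the max(OR, 1/OR)
      scale); B via configured soft indicators; A otherwise.
    """
    if not meta.significant:
        raise NotGradeableError(f"association {meta.key} is not significant")
    count = meta.minor_allele_count if minor_allele_count is None else minor_allele_count
    if count > amount_a:
        amount = "A"
    elif count >= amount_b:
        amount = "B"
    else:
        amount = "C"

    if replication_override is not None:
        replication = replication_override
    else:
        replication = {MILD: "A", MODERATE: "B", LARGE: "C"}[
            classify_heterogeneity(meta.het.i2)
        ]

    sens = bias.sensitivity
    hard = (
        bias.egger_p < bias_p_threshold
        or bias.begg_p < bias_p_threshold
        or bias.excess.excess
        or (
            sens.applicable
            and (sens.leave_one_out_loss or sens.first_study_loss or sens.hwe_loss)
        )
        or max(meta.or_value, 1.0 / meta.or_value) < small_effect_or
    )
    bias_letter = "C" if hard else ("B" if soft_indicator else "A")
    return VeniceGrade(amount=amount, replication=replication, bias=bias_letter)


def combine_credibility(
    venice: VeniceGrade,
    fprp_value: "FPRPResult | float",
    upgrade_below: float = 0.05,
    downgrade_at: float = 0.20,
) -> CredibilityRating:
    """Combine Venice letters with FPRP into the final credibility level.

    Base level: strong when all three letters are A, weak when any letter
    is C, moderate otherwise.  The FPRP shifts the level one step up when
    below ``upgrade_below`` and one step down when at or above
    ``downgrade_at``, bounded at strong/weak.
    """
    value = fprp_value.fprp if isinstance(fprp_value, FPRPResult) else float(fprp_value)
    letters = venice.as_string
    if letters == "AAA":
        base = STRONG
    elif "C" in letters:
        base = WEAK
    else:
        base = "moderate"

    rank = _LEVELS.index(base)
    if value < upgrade_below:
        rank = min(rank + 1, len(_LEVELS) - 1)
    elif value >= downgrade_at:
        rank = max(rank - 1, 0)
    return CredibilityRating(
        venice=venice, fprp_value=value, base_level=base, final_level=_LEVELS[rank]
    )


def prospective_power(spec: PowerSpec) -> float:
    """Power of a two-proportion allele-count test at the given design.

    Each subject contributes two alleles: the control minor-allele
    proportion is the MAF over ``2 * n_controls`` alleles, the case
    proportion is the odds transform of the MAF by the detectable OR, and
    power uses the two-sided normal approximation with the null SE pooled
    across arms.
    """
    if spec.maf <= 0 or spec.maf > 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if spec.detectable_or <= 0:
        raise ValueError("detectable_or must be positive")
    n0 = 2.0 * spec.n_controls
    n1 = 2.0 * spec.n_cases
    p0 = spec.maf
    odds1 = spec.detectable_or * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    delta = p1 - p0
    p_bar = (n1 * p1 + n0 * p0) / (n1 + n0)
    se_null = math.sqrt(p_bar * (1 - p_bar) * (1.0 / n1 + 1.0 / n0))
    se_alt = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    upper = (delta - z_crit * se_null) / se_alt
    lower = (-delta - z_crit * se_null) / se_alt
    return float(stats.norm.cdf(upper) + stats.norm.cdf(lower))
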