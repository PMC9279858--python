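"""Fixed- and random-effects pooling, heterogeneity statistics, subgroup runs.

Pooling is inverse-variance on the log odds ratio.  Between-study variance
uses the DerSimonian-Laird moment estimator; the model is chosen per
association by the heterogeneity rule (random effects when P_Q < 0.1 by
default, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .effects import Z95, EffectEstimate, control_maf, study_effect
from .errors import IneligibleAssociationError, InsufficientStudiesError
from .records import AssociationKey, StudyRecord

MILD = "mild"
MODERATE = "moderate"
LARGE = "large"


@dataclass
class HeterogeneityStats:
    q: float
    df: int
    p_q: float
    i2: float  # percent, in [0, 100]
    tau2: float


@dataclass
class MetaResult:
    key: AssociationKey
    k: int
    n_cases: int
    n_controls: int
    model: str  # "fixed" | "random"
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    het: HeterogeneityStats
    weights: tuple[float, ...]  # normalized, sum to 1
    maf: float
    significant: bool
    effects: tuple[EffectEstimate, ...] = ()
    minor_allele_count: int = 0


def _check_k(effects: Sequence[EffectEstimate], minimum: int) -> None:
    if len(effects) < minimum:
        raise InsufficientStudiesError(
            f"need at least {minimum} studies, got {len(effects)}"
        )


def pool_fixed(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance fixed-effect pooled (log OR, se)."""
    _check_k(effects, 2)
    w = np.array([1.0 / e.se**2 for e in effects])
    theta = np.array([e.log_or for e in effects])
    return float(np.sum(w * theta) / np.sum(w)), float(1.0 / math.sqrt(np.sum(w)))


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q, I² and the DerSimonian-Laird tau²."""
    _check_k(effects, 2)
    w = np.array([1.0 / e.se**2 for e in effects])
    theta = np.array([e.log_or for e in effects])
    pooled, _ = pool_fixed(effects)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df=df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def pool_random(
    effects: Sequence[EffectEstimate], tau2: float
) -> tuple[float, float]:
    """DerSimonian-Laird random-effects pooled (log OR, se)."""
    _check_k(effects, 2)
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    theta = np.array([e.log_or for e in effects])
    return float(np.sum(w * theta) / np.sum(w)), float(1.0 / math.sqrt(np.sum(w)))


def classify_heterogeneity(i2: float) -> str:
    """Bin I² (percent): mild (<= 25), moderate (25-50), large (>= 50)."""
    if not 0.0 <= i2 <= 100.0:
        raise ValueError(f"i2 must be in [0, 100], got {i2}")
    if i2 <= 25.0:
        return MILD
    if i2 >= 50.0:
        return LARGE
    return MODERATE


def run_association(
    records: Sequence[StudyRecord],
    key: AssociationKey | None = None,
    config: AnalysisConfig | None = None,
) -> MetaResult:
    """Meta-analyze one association from raw genotype counts.

    Builds per-study allele-model effects, selects fixed vs random effects
    per the configured rule, and returns the pooled estimate with
    heterogeneity statistics, normalized weights, pooled control MAF and a
    significance flag.  Raises :class:`IneligibleAssociationError` when
    fewer than ``config.min_studies`` analyzable records are supplied.
    """
    config = config or AnalysisConfig()
    records = list(records)
    if key is None:
        key = AssociationKey(
            records[0].variant_id if records else "?",
            records[0].disease if records else "?",
            "Overall",
        )
    if len(records) < config.min_studies:
        raise IneligibleAssociationError(key, len(records), config.min_studies)

    effects = tuple(
        study_effect(r, correction=config.continuity_correction) for r in records
    )
    het = heterogeneity(effects)

    if config.model_selection == "fixed":
        model = "fixed"
    elif config.model_selection == "random":
        model = "random"
    else:
        model = "random" if het.p_q < config.het_p_threshold else "fixed"

    if model == "fixed":
        log_or, se = pool_fixed(effects)
        raw_w = np.array([1.0 / e.se**2 for e in effects])
    else:
        log_or, se = pool_random(effects, het.tau2)
        raw_w = np.array([1.0 / (e.se**2 + het.tau2) for e in effects])

    z = log_or / se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    weights = tuple(float(x) for x in raw_w / raw_w.sum())

    return MetaResult(
        key=key,
        k=len(records),
        n_cases=sum(r.n_cases for r in records),
        n_controls=sum(r.n_controls for r in records),
        model=model,
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p=p,
        het=het,
        weights=weights,
        maf=control_maf(records),
        significant=p < config.significance,
        effects=effects,
        minor_allele_count=sum(r.minor_allele_count for r in records),
    )
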