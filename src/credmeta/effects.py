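"""Per-study allele-model effect estimates, control MAF, and HWE testing.

The additive genetic model is operationalised as the allele-count 2x2
comparison: each subject contributes two alleles, and the study odds ratio
contrasts minor- versus major-allele counts between cases and controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

from scipy import stats

from .errors import DegenerateInputError
from .records import StudyRecord

#: two-sided 95% normal quantile as conventionally printed
Z95 = 1.96
HWE_THRESHOLD = 0.05


@dataclass
class AlleleTable:
    """2x2 allele-count table (real-valued to allow continuity correction)."""

    case_minor: float
    case_major: float
    ctrl_minor: float
    ctrl_major: float
    corrected: bool = False


@dataclass
class EffectEstimate:
    """One study's log odds ratio under the allele model."""

    study_id: str
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    corrected: bool = False


@dataclass
class HWEResult:
    """Chi-square goodness-of-fit of control genotypes to Hardy-Weinberg."""

    chi2: float
    df: int
    p: float
    violates: bool
    testable: bool = True


def allele_table(record: StudyRecord, correction: bool = True) -> AlleleTable:
    """Collapse genotype counts to the minor/major allele 2x2 table.

    Minor-allele count per arm is ``2*hom_minor + het``.  When any of the
    four cells is zero and ``correction`` is enabled, 0.5 is added to all
    four cells (Haldane-Anscombe) and the table is marked corrected.
    """
    if record.n_cases == 0 and record.n_controls == 0:
        raise DegenerateInputError(f"study {record.study_id!r}: both arms empty")
    cells = [
        float(2 * record.case_hom_minor + record.case_het),
        float(2 * record.case_hom_major + record.case_het),
        float(2 * record.ctrl_hom_minor + record.ctrl_het),
        float(2 * record.ctrl_hom_major + record.ctrl_het),
    ]
    corrected = False
    if correction and min(cells) == 0.0:
        cells = [c + 0.5 for c in cells]
        corrected = True
    return AlleleTable(*cells, corrected=corrected)


def study_odds_ratio(table: AlleleTable, study_id: str = "") -> EffectEstimate:
    """Odds ratio, 95% CI and two-sided normal p for one allele table.

    ``log_or = ln[(case_minor * ctrl_major) / (case_major * ctrl_minor)]`` with
    the Woolf variance ``1/a + 1/b + 1/c + 1/d``.
    """
    cells = (table.case_minor, table.case_major, table.ctrl_minor, table.ctrl_major)
    if min(cells) <= 0:
        raise DegenerateInputError(
            "allele table has a zero cell; enable the continuity correction"
        )
    log_or = math.log(
        (table.case_minor * table.ctrl_major) / (table.case_major * table.ctrl_minor)
    )
    se = math.sqrt(sum(1.0 / c for c in cells))
    z = log_or / se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return EffectEstimate(
        study_id=study_id,
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        z=z,
        p=p,
        corrected=table.corrected,
    )


def study_effect(record: StudyRecord, correction: bool = True) -> EffectEstimate:
    """Convenience: allele table + odds ratio for one study record."""
    return study_odds_ratio(allele_table(record, correction), study_id=record.study_id)


def hwe_test(record: StudyRecord, threshold: float = HWE_THRESHOLD) -> HWEResult:
    """Hardy-Weinberg chi-square test (df=1) on the control genotype counts.

    Expected counts come from the observed control allele frequency.
    Monomorphic controls are untestable and return chi2=0, p=1.
    """
    n = record.n_controls
    if n < 1:
        raise DegenerateInputError(f"study {record.study_id!r}: no controls")
    hom_major, het, hom_minor = record.ctrl_counts
    q = (2 * hom_minor + het) / (2.0 * n)
    if q == 0.0 or q == 1.0:
        return HWEResult(chi2=0.0, df=1, p=1.0, violates=False, testable=False)
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    observed = (hom_major, het, hom_minor)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=chi2, df=1, p=p, violates=p < threshold)


def control_maf(records: Sequence[StudyRecord] | Iterable[StudyRecord]) -> float:
    """Pooled frequency of the labelled minor allele across all control arms.

    The labelled minor allele is reported as-is (no flipping), so values
    above 0.5 are possible when the dataset's label disagrees with the
    pooled sample.
    """
    records = list(records)
    if not records:
        raise DegenerateInputError("control_maf needs at least one record")
    minor = sum(2 * r.ctrl_hom_minor + r.ctrl_het for r in records)
    total = sum(2 * r.n_controls for r in records)
    if total == 0:
        raise DegenerateInputError("zero control alleles")
    return minor / total
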