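"""Batch orchestration and report rendering.

``run_pipeline`` walks every association the grouping rules produce,
meta-analyzes the eligible ones, runs the bias battery, and grades the
significant ones; per-association failures become notes, never batch
aborts.  ``grade_summary_table`` applies the FPRP/credibility machinery to
published summary rows (OR + CI, optional Venice letters) when raw
genotype counts are unavailable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .bias import BiasAssessment, assess_bias
from .config import AnalysisConfig
from .datasets import parse_printed_p
from .errors import IneligibleAssociationError
from .grading import (
    CredibilityRating,
    VeniceGrade,
    combine_credibility,
    fprp,
    fprp_from_summary,
    power_detect_or,
    venice_grade,
)
from .meta import MetaResult, classify_heterogeneity, run_association
from .records import AssociationKey, Dataset, group_by_association

logger = logging.getLogger("credmeta")

REPORT_COLUMNS = (
    "variant_id",
    "alleles",
    "group",
    "disease",
    "maf",
    "k",
    "n_cases",
    "n_controls",
    "or_value",
    "ci_95",
    "p",
    "i2",
    "p_q",
    "venice",
    "fprp",
    "credibility",
)


@dataclass
class AssociationReport:
    key: AssociationKey
    meta: MetaResult
    bias: BiasAssessment
    het_class: str
    rating: CredibilityRating | None = None
    fprp_detail: object | None = None
    major_allele: str = "?"
    minor_allele: str = "?"
    notes: list[str] = field(default_factory=list)


def run_pipeline(
    dataset: Dataset, config: AnalysisConfig | None = None
) -> list[AssociationReport]:
    """Analyze every eligible association under the configured grouping rules."""
    config = config or AnalysisConfig()
    if len(dataset) == 0:
        warnings.warn("empty dataset: no associations to analyze")
        return []

    groups: dict[AssociationKey, list] = {}
    for rule in config.grouping:
        for key, grp in group_by_association(dataset, rule).items():
            groups.setdefault(key, grp.records)

    reports: list[AssociationReport] = []
    for key, records in groups.items():
        try:
            meta = run_association(records, key, config)
        except IneligibleAssociationError as err:
            logger.info("skipping %s: %s", key, err)
            continue
        bias = assess_bias(records, meta, config)
        notes: list[str] = []
        if bias.sensitivity.not_evaluable:
            notes.append(
                "sensitivity scenarios not evaluable: "
                + ", ".join(bias.sensitivity.not_evaluable)
            )
        rating = None
        fprp_detail = None
        if meta.significant:
            grade = venice_grade(
                meta,
                bias,
                small_effect_or=config.small_effect_or,
                amount_a=config.venice_amount_a,
                amount_b=config.venice_amount_b,
                bias_p_threshold=config.bias_p_threshold,
            )
            power = power_detect_or(
                meta.se,
                config.fprp_or0 if meta.or_value >= 1 else 1.0 / config.fprp_or0,
                alpha=meta.p,
            )
            fprp_detail = fprp(
                meta.p,
                power,
                config.fprp_prior,
                or0=config.fprp_or0,
                noteworthy_level=config.fprp_noteworthy,
            )
            rating = combine_credibility(grade, fprp_detail)
        logger.info(
            "%s: k=%d model=%s OR=%.3f p=%.3g i2=%.1f significant=%s",
            key,
            meta.k,
            meta.model,
            meta.or_value,
            meta.p,
            meta.het.i2,
            meta.significant,
        )
        reports.append(
            AssociationReport(
                key=key,
                meta=meta,
                bias=bias,
                het_class=classify_heterogeneity(meta.het.i2),
                rating=rating,
                fprp_detail=fprp_detail,
                major_allele=records[0].major_allele,
                minor_allele=records[0].minor_allele,
                notes=notes,
            )
        )
    if not reports:
        warnings.warn("no eligible association in the dataset")
    return reports


def _fmt_p(p: float, threshold: float = 0.001) -> str:
    return f"<{threshold}" if p < threshold else f"{p:.3f}"


def report_frame(reports: Sequence[AssociationReport]) -> pd.DataFrame:
    """Tabular view of pipeline reports (printed-table column order)."""
    rows = []
    for rep in reports:
        m = rep.meta
        alleles = f"{rep.major_allele}/{rep.minor_allele}"
        rows.append(
            {
                "variant_id": m.key.variant_id,
                "alleles": alleles,
                "group": m.key.group,
                "disease": m.key.disease,
                "maf": round(m.maf, 4),
                "k": m.k,
                "n_cases": m.n_cases,
                "n_controls": m.n_controls,
                "or_value": f"{m.or_value:.3f}",
                "ci_95": f"{m.ci_low:.3f}-{m.ci_high:.3f}",
                "p": _fmt_p(m.p),
                "i2": f"{m.het.i2:.1f}",
                "p_q": _fmt_p(m.het.p_q),
                "venice": rep.rating.venice.as_string if rep.rating else "",
                "fprp": f"{rep.rating.fprp_value:.3f}" if rep.rating else "",
                "credibility": rep.rating.final_level.capitalize() if rep.rating else "",
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def render_report(
    reports: Sequence[AssociationReport],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write reports as TSV (default) or a markdown table.

    Formatting follows the published-table conventions: OR/CI to 3
    decimals, I² to 1 decimal, FPRP to 3 decimals, p-values below 0.001
    printed as "<0.001".
    """
    frame = report_frame(reports)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "markdown":
        path.write_text(frame_to_markdown(frame))
    else:
        raise ValueError(f"format must be 'tsv' or 'markdown', got {format!r}")


def frame_to_markdown(frame: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table."""
    header = "| " + " | ".join(frame.columns) + " |"
    sep = "| " + " | ".join("---" for _ in frame.columns) + " |"
    body = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in frame.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body]) + "\n"


def grade_summary_table(
    frame: pd.DataFrame,
    prior: float = 0.05,
    or0: float = 1.5,
    noteworthy_level: float = 0.20,
    use_printed_fprp: bool = False,
) -> pd.DataFrame:
    """Recompute FPRP (and credibility where Venice letters exist) for summary rows.

    Expects columns ``or_value``, ``ci_low``, ``ci_high`` and optionally
    ``venice`` (three-letter grade) and ``fprp`` (printed value, used
    instead of the recomputed one when ``use_printed_fprp``).  Returns a
    copy with ``fprp_computed``, ``ci_consistent``, ``base_level`` and
    ``final_level`` columns.
    """
    out = frame.copy()
    computed, consistent, base, final = [], [], [], []
    for _, row in out.iterrows():
        res = fprp_from_summary(
            float(row["or_value"]),
            float(row["ci_low"]),
            float(row["ci_high"]),
            prior=prior,
            or0=or0,
            noteworthy_level=noteworthy_level,
        )
        computed.append(res.fprp)
        consistent.append(res.ci_consistent)
        if "venice" in out.columns and isinstance(row["venice"], str):
            value = (
                parse_printed_p(row["fprp"])
                if use_printed_fprp and "fprp" in out.columns
                else res.fprp
            )
            rating = combine_credibility(VeniceGrade.from_string(row["venice"]), value)
            base.append(rating.base_level)
            final.append(rating.final_level)
        else:
            base.append("")
            final.append("")
    out["fprp_computed"] = computed
    out["ci_consistent"] = consistent
    out["base_level"] = base
    out["final_level"] = final
    return out
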