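"""Analysis configuration: thresholds, model-selection rule, grading constants.

Defaults follow the study conventions this pipeline encodes: two-sided 0.05
for association significance, 0.1 for heterogeneity and bias tests, FPRP
prior 0.05 against a detectable OR of 1.5 with noteworthiness at 0.20.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

MODEL_SELECTION_RULES = ("by_heterogeneity", "fixed", "random")


@dataclass
class AnalysisConfig:
    #: two-sided significance level for the pooled association test
    significance: float = 0.05
    #: P_Q below this selects random effects under "by_heterogeneity"
    het_p_threshold: float = 0.1
    #: significance level for Egger/Begg/excess-significance
    bias_p_threshold: float = 0.1
    #: control-HWE violation threshold
    hwe_threshold: float = 0.05
    #: add 0.5 to all four allele cells when any is zero
    continuity_correction: bool = True
    #: "by_heterogeneity" (random when P_Q < het_p_threshold), "fixed", "random"
    model_selection: str = "by_heterogeneity"
    #: minimum independent datasets per association
    min_studies: int = 3
    #: grouping rules executed by the pipeline
    grouping: tuple[str, ...] = ("overall", "by_ethnicity")
    #: FPRP prior probability of a true association
    fprp_prior: float = 0.05
    #: detectable odds ratio against which FPRP power is computed
    fprp_or0: float = 1.5
    #: FPRP noteworthiness level
    fprp_noteworthy: float = 0.20
    #: Venice amount-of-evidence thresholds on combined minor-allele count
    venice_amount_a: int = 1000
    venice_amount_b: int = 100
    #: pooled effects smaller than this (on the max(OR, 1/OR) scale) cannot
    #: be protected from bias
    small_effect_or: float = 1.15
    #: soft bias indicators that map to letter B (default none)
    venice_soft_indicators: tuple[str, ...] = ()
    #: seed threaded to any stochastic step (none in the core analysis)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_selection not in MODEL_SELECTION_RULES:
            raise ValueError(
                f"model_selection must be one of {MODEL_SELECTION_RULES}"
            )
        if isinstance(self.grouping, list):
            self.grouping = tuple(self.grouping)
        if isinstance(self.venice_soft_indicators, list):
            self.venice_soft_indicators = tuple(self.venice_soft_indicators)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["grouping"] = list(self.grouping)
        data["venice_soft_indicators"] = list(self.venice_soft_indicators)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
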