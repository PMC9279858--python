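"""Seeded generator of study collections with the structure the analysis assumes.

Controls are drawn from Hardy-Weinberg genotype proportions at a given
minor-allele frequency (optionally distorted by an inbreeding coefficient
``f``: heterozygosity shrinks by ``1 - f``).  Each study receives its own
allele odds ratio, log-normal around the true OR with between-study
standard deviation ``tau``; cases are drawn under HWE at the odds-
transformed case allele frequency.  Optional significance-dependent
censoring drops non-significant studies with a fixed probability, the
simplest mechanism that induces funnel-plot asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .effects import study_effect
from .errors import DegenerateInputError
from .records import Dataset, StudyRecord


@dataclass
class SimulationConfig:
    """Study-collection generating process.

    Defaults mirror the scale of a typical candidate-gene literature: a
    handful of studies per association with several hundred to a few
    thousand subjects per arm, control MAF 0.30, publication years spanning
    2007-2020.
    """

    n_studies: int = 5
    cases_range: tuple[int, int] = (500, 2500)
    controls_range: tuple[int, int] = (500, 2500)
    control_maf: float = 0.30
    true_or: float = 1.2
    tau: float = 0.0
    inbreeding_f: float = 0.0
    pub_bias_drop: float = 0.0
    ethnicity_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Asian": 0.5, "Caucasian": 0.5}
    )
    year_range: tuple[int, int] = (2007, 2020)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not 0 < self.control_maf <= 0.5:
            raise ValueError("control_maf must be in (0, 0.5]")
        if self.true_or <= 0 or self.tau < 0:
            raise ValueError("true_or must be > 0 and tau >= 0")
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError("inbreeding_f must be in [0, 1)")
        if not 0 <= self.pub_bias_drop < 1:
            raise ValueError("pub_bias_drop must be in [0, 1)")
        total = sum(self.ethnicity_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("ethnicity_mix proportions must sum to 1")
        for lo, hi in (self.cases_range, self.controls_range, self.year_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty")


def _genotype_probs(q: float, f: float) -> tuple[float, float, float]:
    """(hom-major, het, hom-minor) probabilities at minor freq q, inbreeding f."""
    het = 2 * q * (1 - q) * (1 - f)
    return ((1 - q) ** 2 + f * q * (1 - q), het, q**2 + f * q * (1 - q))


def simulate_study(
    config: SimulationConfig,
    draw: np.random.Generator,
    study_index: int = 0,
    variant_id: str = "rs0000001",
    disease: str = "simulated disease",
) -> StudyRecord:
    """Draw one study record from the configured generating process."""
    n_cases = int(draw.integers(config.cases_range[0], config.cases_range[1] + 1))
    n_controls = int(
        draw.integers(config.controls_range[0], config.controls_range[1] + 1)
    )
    q = config.control_maf
    log_or_i = draw.normal(math.log(config.true_or), config.tau)
    case_odds = math.exp(log_or_i) * q / (1 - q)
    q_case = case_odds / (1 + case_odds)

    ctrl = draw.multinomial(n_controls, _genotype_probs(q, config.inbreeding_f))
    case = draw.multinomial(n_cases, _genotype_probs(q_case, 0.0))

    labels = list(config.ethnicity_mix)
    probs = [config.ethnicity_mix[k] for k in labels]
    ethnicity = labels[int(draw.choice(len(labels), p=probs))]
    year = int(draw.integers(config.year_range[0], config.year_range[1] + 1))

    return StudyRecord(
        study_id=f"sim{study_index:03d}",
        first_author=f"Author{study_index:03d}",
        year=year,
        ethnicity=ethnicity,
        disease=disease,
        variant_id=variant_id,
        gene="SIMGENE",
        major_allele="C",
        minor_allele="T",
        case_hom_major=int(case[0]),
        case_het=int(case[1]),
        case_hom_minor=int(case[2]),
        ctrl_hom_major=int(ctrl[0]),
        ctrl_het=int(ctrl[1]),
        ctrl_hom_minor=int(ctrl[2]),
    )


def simulate_association(
    config: SimulationConfig,
    variant_id: str = "rs0000001",
    disease: str = "simulated disease",
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Simulate one association's study collection, reproducible from the seed.

    With ``pub_bias_drop > 0`` each study whose own two-sided allele-test p
    is >= 0.05 is censored with that probability, so the returned dataset
    may hold fewer than ``n_studies`` records.
    """
    draw = np.random.default_rng(config.seed) if rng is None else rng
    records: list[StudyRecord] = []
    for i in range(config.n_studies):
        rec = simulate_study(config, draw, i, variant_id, disease)
        if config.pub_bias_drop > 0:
            p = study_effect(rec).p
            if p >= 0.05 and draw.uniform() < config.pub_bias_drop:
                continue
        records.append(rec)
    if not records:
        import warnings

        warnings.warn("all simulated studies were censored; dataset is empty")
    return Dataset(
        records=records,
        provenance=f"simulated: OR={config.true_or}, tau={config.tau}, "
        f"maf={config.control_maf}, seed={config.seed}",
    )
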