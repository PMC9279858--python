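import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from credmeta import EffectEstimate, StudyRecord

# the factory fixtures are stateless, so sharing them across examples is safe
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def record_factory():
    """Build a valid StudyRecord with overridable genotype counts/metadata."""

    def make(
        case=(50, 40, 10),
        ctrl=(80, 20, 0),
        study_id="s1",
        year=2010,
        ethnicity="Asian",
        **kw,
    ) -> StudyRecord:
        return StudyRecord(
            study_id=study_id,
            first_author="Author",
            year=year,
            ethnicity=ethnicity,
            disease=kw.pop("disease", "lung cancer"),
            variant_id=kw.pop("variant_id", "rs0000001"),
            gene="TERT",
            major_allele="C",
            minor_allele="T",
            case_hom_major=case[0],
            case_het=case[1],
            case_hom_minor=case[2],
            ctrl_hom_major=ctrl[0],
            ctrl_het=ctrl[1],
            ctrl_hom_minor=ctrl[2],
            **kw,
        )

    return make


@pytest.fixture
def effect_factory():
    """Build an EffectEstimate directly from (log_or, se)."""

    def make(log_or: float, se: float, study_id: str = "s") -> EffectEstimate:
        from scipy import stats

        z = log_or / se
        return EffectEstimate(
            study_id=study_id,
            log_or=log_or,
            se=se,
            or_value=math.exp(log_or),
            ci_low=math.exp(log_or - 1.96 * se),
            ci_high=math.exp(log_or + 1.96 * se),
            z=z,
            p=float(min(1.0, 2.0 * stats.norm.sf(abs(z)))),
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
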