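import numpy as np
import pytest

from fieldsynopsis.records import EffectEstimate, StudyRecord


@pytest.fixture
def make_effect():
    def _make(log_or: float, se: float, study_id: str = "s") -> EffectEstimate:
        return EffectEstimate(study_id=study_id, log_or=log_or, se=se)

    return _make


@pytest.fixture
def make_study():
    """StudyRecord factory with sensible defaults (CI-bearing by default)."""

    counter = {"n": 0}

    def _make(**kwargs) -> StudyRecord:
        counter["n"] += 1
        defaults = dict(
            study_id=f"study{counter['n']}",
            first_author=f"Author{counter['n']:02d}",
            year=2000 + counter["n"],
            ancestry="Asian",
            variant_id="rs1",
            gene="GENE",
            n_cases=200,
            n_controls=200,
            reported_or=1.5,
            ci_low=1.1,
            ci_high=2.05,
        )
        defaults.update(kwargs)
        return StudyRecord(**defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
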