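import warnings

import numpy as np
import pytest

from stressbiome.simulate import StudyConfig, simulate_study
from stressbiome import microbiome as mb
from stressbiome.psychometrics import score_stress

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def study():
    """Default study-sized synthetic dataset (38 + 46 participants)."""
    return simulate_study(StudyConfig(seed=7))


@pytest.fixture(scope="session")
def big_likert():
    """Large two-cohort Likert table (independent T2 rows) for
    asymptotic psychometric checks."""
    st = simulate_study(StudyConfig(n_urban=1000, n_suburban=1000, seed=11))
    return st.likert[st.metadata["trimester"] == "T2"]


@pytest.fixture(scope="session")
def invariant_likert():
    """Likert data generated without any planted non-invariance."""
    st = simulate_study(StudyConfig(n_urban=500, n_suburban=500, seed=5,
                                    noninvariant_items=frozenset()))
    return st.likert[st.metadata["trimester"] == "T2"]


@pytest.fixture(scope="session")
def pipeline(study):
    """QC'd counts, CSS normalizer and stress scores for the default study."""
    qc, audit = mb.qc_filter(study.asv_counts)
    norm = mb.CSSNormalizer().fit(qc)
    scores = score_stress(study.likert, retained_items=list("abcdgij"))
    return dict(qc=qc, audit=audit, norm=norm, scores=scores)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
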