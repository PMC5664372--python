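import pytest

from icdpower import CodeAttrition, CohortSpec, GeneticArchitecture

# The worked reference design: a common variant of moderate effect screened
# against a large fixed control pool, with moderate per-code decay rates.
BASELINE = {"q": 0.20, "R": 2.0, "n1": 400.0, "m": 10_000.0, "delta": 0.15, "epsilon": 0.15}


@pytest.fixture
def gen() -> GeneticArchitecture:
    return GeneticArchitecture(q=BASELINE["q"], R=BASELINE["R"])


@pytest.fixture
def cohort() -> CohortSpec:
    return CohortSpec(n1=BASELINE["n1"], m=BASELINE["m"])


@pytest.fixture
def attrition() -> CodeAttrition:
    return CodeAttrition(delta=BASELINE["delta"], epsilon=BASELINE["epsilon"])
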