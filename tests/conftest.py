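import pytest

from oculogas import AtmosphereModel, PairedJudgments, RiskPolicy, VitreousGeometry


@pytest.fixture
def geometry():
    return VitreousGeometry()


@pytest.fixture
def atmosphere():
    return AtmosphereModel()


@pytest.fixture
def policy():
    return RiskPolicy()


@pytest.fixture
def fundus_pairs():
    """Four paired interface judgments from representative fundus photographs."""
    return PairedJudgments(surgeon=(75, 45, 35, 20), patient=(76, 44, 35, 18))
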