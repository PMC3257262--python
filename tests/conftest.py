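import pytest

from nmrtitrate.synthetic import make_ground_truth, emit_observables


@pytest.fixture(scope="session")
def default_truth():
    return make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def default_study(default_truth):
    """The default planted study: 137 residues, prolines 12/38/67,
    nucleation [109, 116], flexible tail [2, 32], six-rung DMSO ladder."""
    return emit_observables(default_truth)


@pytest.fixture(scope="session")
def ged_seq(default_truth):
    return default_truth.seq
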