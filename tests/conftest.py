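import pytest

from neoact import mhc_binding as mb
from neoact import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def trial_fixture():
    return sf.gen_trial_fixture()


@pytest.fixture(scope="session")
def sim_config():
    return sf.SimConfig(seed=7)


@pytest.fixture(scope="session")
def pssm_ensemble(sim_config):
    """Five PSSM predictors differing in pseudocount, trained on one motif."""
    binders = sf.gen_binder_set(sim_config, "HLA-A*11:01", 200)
    return [
        mb.pssm_predictor(mb.train_pssm(binders, 9, pseudocount=pc))
        for pc in (0.5, 1.0, 2.0, 5.0, 10.0)
    ]
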