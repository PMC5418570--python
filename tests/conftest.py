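import numpy as np
import pytest

from contestlearn import features, game, synth


@pytest.fixture(scope="session")
def params():
    return game.default_params()


@pytest.fixture(scope="session")
def default_experiment():
    """The canonical synthetic experiment: 18 pairs x 600 periods x 2 treatments."""
    return synth.generate_experiment(seed=1)


@pytest.fixture(scope="session")
def default_features(default_experiment):
    table, log = features.code_features(default_experiment)
    return table, log


def constant_trajectory(params, action, horizon=300, pair_id=0, treatment="NoInfo",
                        subject_ids=(0, 1)):
    """A pair that sits at a symmetric profile for the whole horizon."""
    from contestlearn.heuristics import Trajectory

    actions = np.full((horizon, 2), float(action))
    pay = game.payoff(action, action, params)
    payoffs = np.full((horizon, 2), pay)
    return Trajectory(
        pair_id=pair_id,
        treatment=treatment,
        actions=actions,
        payoffs_cents=payoffs,
        params=params,
        subject_ids=subject_ids,
    )
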