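import numpy as np
import pytest

from b7h3adc.dose_response import Agent, DoseResponseExperiment, four_pl
from b7h3adc.models import default_config
from b7h3adc.simulate import CONTROL_CURVE, HillParams


@pytest.fixture
def config():
    return default_config(seed=0)


def make_experiment(doses, viability, agent=Agent.TARGETED, model="m",
                    exp_id="exp1"):
    viability = np.asarray(viability, dtype=float)
    if viability.ndim == 1:
        viability = viability[:, None]
    return DoseResponseExperiment(model_id=model, agent=agent,
                                  doses=np.asarray(doses, dtype=float),
                                  viability=viability, experiment_id=exp_id)


def noise_free_pair(hill: HillParams, doses):
    """Targeted curve from `hill` and the standard near-flat control."""
    doses = np.asarray(doses, dtype=float)
    targeted = make_experiment(
        doses, four_pl(doses, hill.top, hill.bottom, hill.ic50, hill.slope))
    control = make_experiment(
        doses, four_pl(doses, CONTROL_CURVE.top, CONTROL_CURVE.bottom,
                       CONTROL_CURVE.ic50, CONTROL_CURVE.slope),
        agent=Agent.CONTROL)
    return targeted, control
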