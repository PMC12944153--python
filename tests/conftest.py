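import numpy as np
import pandas as pd
import pytest

from fluvopbpk import studies
from fluvopbpk.ivive import ClearanceSet
from fluvopbpk.population import AgingModel, Population, PopulationConfig, PopulationSpec

#: single fixed seed for every stochastic fixture in the suite
SEED = 1


@pytest.fixture(scope="session")
def model():
    """Fully calibrated fluvoxamine model (elimination + aging)."""
    return studies.calibrate_model(seed=SEED)


@pytest.fixture(scope="session")
def phenotype_result(model):
    """Steady-state phenotype study at 50 and 100 mg/day (geriatric)."""
    return studies.run_phenotype_study(model, doses=(50.0, 100.0))


@pytest.fixture(scope="session")
def age_result(model):
    """Elderly vs younger steady-state comparison at 100 mg/day."""
    return studies.run_age_comparison(model, doses=(100.0,))


@pytest.fixture(scope="session")
def verification_result(model):
    return studies.run_verification_suite(model)


def toy_population(weights, cl_blood, fh=1.0, q_hepatic=1e6, fu_b=1.0,
                   clint_2d6=None, clint_add=None):
    """Hand-built population + clearance set for engine oracle tests.

    Clearances are supplied directly (not derived from physiology), so
    closed-form one-compartment expectations can be written down exactly.
    """
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    n = weights.size
    spec = PopulationSpec(n_trials=1, subjects_per_trial=n, seed=0)
    data = pd.DataFrame(
        {
            "trial": np.zeros(n, dtype=int),
            "age": np.full(n, 30.0),
            "sex": np.full(n, "M"),
            "weight_kg": weights,
            "height_cm": np.full(n, 176.0),
            "liver_mass_g": np.full(n, 1650.0),
            "mppgl_mg_g": np.full(n, 40.0),
            "q_hepatic_l_h": np.full(n, float(q_hepatic)),
            "phenotype": np.full(n, "EM"),
            "cyp2d6_abundance": np.full(n, 8.0),
            "hepatic_activity_scalar": np.ones(n),
            "aging_clint_scalar": np.ones(n),
        }
    )
    pop = Population(spec=spec, config=PopulationConfig(), aging=AgingModel(), data=data)
    cl = np.full(n, float(cl_blood))
    cs = ClearanceSet(
        clint_2d6_u=np.full(n, 0.0 if clint_2d6 is None else float(clint_2d6)),
        clint_add_u=cl * 10 if clint_add is None else np.full(n, float(clint_add)),
        cl_hepatic_blood=cl,
        fh=np.full(n, float(fh)),
        q_hepatic=np.full(n, float(q_hepatic)),
        fu_b=float(fu_b),
    )
    return pop, cs
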