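import warnings

import numpy as np
import pandas as pd
import pytest

import acqstruct as aq


@pytest.fixture(scope="session")
def bp():
    return aq.build_default_blueprint()


@pytest.fixture(scope="session")
def sim2000(bp):
    """Moderate sample at the calibrated acquiescence scale."""
    cfg = aq.SimulationConfig(n=2000, seed=11)
    truth, resp = aq.simulate(cfg, bp)
    return cfg, truth, resp


@pytest.fixture(scope="session")
def sim5000(bp):
    """Large sample at the calibrated acquiescence scale, with the full
    default generator (secondary loadings, careless responders)."""
    cfg = aq.SimulationConfig(n=5000, seed=1)
    truth, resp = aq.simulate(cfg, bp)
    return cfg, truth, resp


@pytest.fixture(scope="session")
def analysis_acq(bp, sim5000):
    """Full raw+corrected analysis of the acquiescent sample (all schemes)."""
    _, _, resp = sim5000
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aq.run_full_analysis(resp, bp)


@pytest.fixture(scope="session")
def analysis_noacq(bp):
    """Raw+corrected triplet analysis of a sample without acquiescence
    or careless responding."""
    cfg = aq.SimulationConfig(n=5000, seed=1, acq_mean=3.0, acq_sd=0.0,
                              ier_rate=0.0)
    _, resp = aq.simulate(cfg, bp)
    pcfg = aq.PipelineConfig(schemes=("triplet54",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aq.run_full_analysis(resp, bp, pcfg)


@pytest.fixture(scope="session")
def population_solution(bp):
    """ML solution on the exact population indicator correlation matrix."""
    cfg = aq.SimulationConfig()
    R, ind_load = aq.population_indicator_correlation(bp, cfg, "triplet54")
    labels = list(ind_load.index)
    Rdf = pd.DataFrame(R, index=labels, columns=labels)
    sol = aq.extract(Rdf, 5, method="ml")
    return cfg, Rdf, ind_load, sol
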