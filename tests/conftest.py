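import logging

import pytest

from paritysig import preprocess as pp
from paritysig import synthetic_data as sd

logging.getLogger("paritysig").setLevel(logging.ERROR)

#: truth-pattern -> assigned-pattern label correspondence
PATTERN_MAP = {
    "up_transient": "transient",
    "up_longterm_changing": "long_term_changing",
    "up_longterm_constant": "long_term_constant",
    "down_constant": "down_constant",
    "down_transient": "down_transient",
}


@pytest.fixture(scope="session")
def cohort():
    return sd.simulate_cohort(79, 30, seed=1)


@pytest.fixture(scope="session")
def planted_spec():
    return sd.TruthSpec(
        n_up_transient=20,
        n_up_longterm_changing=20,
        n_up_longterm_constant=20,
        n_down_constant=20,
        n_down_transient=20,
        base_log2fc_low=1.2,
        base_log2fc_high=2.0,
        noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def planted_sim(cohort, planted_spec):
    """2000-probe simulation with 20 probes per pattern, batch-adjusted."""
    expr, calls, truth = sd.simulate_expression(cohort, 2000, planted_spec, seed=101)
    adjusted = pp.combat_adjust(expr, cohort.data["batch"]).adjusted
    return {
        "expr": expr,
        "calls": calls,
        "truth": truth,
        "adjusted": adjusted,
        "cohort": cohort,
    }
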