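import numpy as np
import pytest

import toxmir as tm
from toxmir import simulate


@pytest.fixture(scope="session")
def design48():
    return tm.generate_design()


@pytest.fixture(scope="session")
def small_sim():
    """Small planted simulation shared across tests: 40 miRNAs, full design."""
    design = tm.generate_design()
    conds = tm.treated_conditions(design)
    ids = simulate.make_mirna_ids(40)
    truths = [
        simulate.biomarker_effect(ids[0]),
        simulate.constant_effect(ids[1], 1.5, conds),
        simulate.constant_effect(ids[2], -1.5, conds),
    ]
    params = tm.SimulationParams(n_mirnas=40, dispersion=0.1, lib_size_mean=100_000, seed=7)
    counts, truth_df = tm.generate_counts(design, params, truths)
    return {
        "design": design,
        "conditions": conds,
        "ids": ids,
        "truths": truths,
        "counts": counts,
        "truth_df": truth_df,
    }
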