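import pandas as pd
import pytest

import hcdr3 as h


@pytest.fixture(scope="session")
def sim_table():
    """A small simulated repertoire with ground truth (expanded clones, SHM)."""
    cfg = h.SimConfig(
        seed=11,
        n_clones=120,
        shm_rate=0.01,
        isotype_probs={"IgG2b": 0.55, "IgG2c": 0.35, "IgG3": 0.08, "IgG1": 0.02},
    )
    table, truth = h.simulate_repertoire(cfg)
    return table, truth


@pytest.fixture(scope="session")
def annotated(sim_table):
    table, truth = sim_table
    return h.add_loops(h.filter_productive(table)), truth


@pytest.fixture()
def toy_table():
    """Three records, loops IRY / IRY / LADY, two V genes."""
    df = pd.DataFrame(
        {
            "sequence_id": ["s1", "s2", "s3"],
            "junction_aa": ["CTTIRYW", "CTTIRYW", "CARLADYW"],
            "v_call": ["V14-4", "V14-1", "V14-4"],
            "j_call": ["J2", "J2", "J2"],
            "c_call": ["IgG2b", "IgG2b", "IgG2c"],
            "productive": [True, True, True],
        }
    )
    return h.add_loops(h.RepertoireTable(df))
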