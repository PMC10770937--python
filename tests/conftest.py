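import numpy as np
import pandas as pd
import pytest

from trm_spatial import SyntheticConfig, generate_cohort


def make_cells(rows, panel="panel1"):
    """Cell-table DataFrame from compact tuples:
    (pid, region, compartment, x, y, marker_dict)."""
    from trm_spatial.io import PANELS

    markers = PANELS[panel]
    records = []
    for pid, region, comp, x, y, mk in rows:
        rec = {
            "patient_id": pid, "region": region, "compartment": comp,
            "x_um": float(x), "y_um": float(y),
        }
        for m in markers:
            rec[m] = int(mk.get(m, 0))
        records.append(rec)
    return pd.DataFrame(records)


def make_clinical(pids, times=None, events=None, stage=None):
    n = len(pids)
    return pd.DataFrame(
        {
            "patient_id": pids,
            "age_group": ["<=60"] * n,
            "gender": ["male"] * n,
            "smoking": ["non_light"] * n,
            "histology": ["LUAD"] * n,
            "stage": stage if stage is not None else ["I"] * n,
            "dfs_months": times if times is not None else [12.0] * n,
            "dfs_event": events if events is not None else [1] * n,
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny but fully featured synthetic cohort shared across tests."""
    cfg = SyntheticConfig(n_patients=25, cells_per_region=250, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
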