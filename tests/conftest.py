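import numpy as np
import pandas as pd
import pytest

from pvsignal import cohort, faers_io, synth


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic quarter with a planted nivolumab signal,
    combinations and duplicates; shared across read/dedup/cohort tests."""
    cfg = synth.SyntheticConfig(
        n_reports=4000,
        exposure_probs={"nivolumab": 0.06, "ipilimumab": 0.04},
        combo_fraction=0.10,
        background_event_prob=0.01,
        signal_rhos={"nivolumab": 8.0},
        tto_valid_fraction=0.6,
        duplicate_rate=0.08,
        fda_tie_fraction=0.3,
        seed=20240117,
    )
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def small_quarter_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("quarter")
    synth.write_dataset(small_dataset, out)
    return out


@pytest.fixture(scope="session")
def small_store(small_quarter_dir):
    tables = faers_io.read_quarter(small_quarter_dir)
    store, processing = faers_io.build_report_store(tables)
    return tables, store, processing


@pytest.fixture(scope="session")
def dictionary():
    return cohort.DrugDictionary.default()


def demo_frame(rows):
    """DEMO rows from (primaryid, caseid, fda_dt) triples."""
    return pd.DataFrame(
        [{"PRIMARYID": str(p), "CASEID": c, "FDA_DT": f} for p, c, f in rows]
    )
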