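from pathlib import Path

import pandas as pd
import pytest

from plaqrisk import load_config, run_study

REPO = Path(__file__).resolve().parents[1]
REPLICA_CONFIG = REPO / "configs" / "study_replica.yaml"
REPLICA_SEED = 7


@pytest.fixture(scope="session")
def replica_config():
    return load_config(REPLICA_CONFIG)


@pytest.fixture(scope="session")
def replica_run(tmp_path_factory, replica_config):
    """One full study-replica pipeline run shared across the session.

    Returns (out_dir, report).  The render -> quantify -> classify chain runs
    once; tests read the on-disk artifacts it produced.
    """
    out = tmp_path_factory.mktemp("replica_study")
    report = run_study(replica_config, REPLICA_SEED, out)
    return out, report


@pytest.fixture(scope="session")
def replica_table(replica_run):
    out, _ = replica_run
    return pd.read_csv(out / "analysis_table.csv")


@pytest.fixture(scope="session")
def replica_open_view(replica_run):
    out, _ = replica_run
    return pd.read_csv(out / "open_view.csv")
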