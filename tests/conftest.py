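import numpy as np
import pandas as pd
import pytest

from pvsignal.model import CaseSet
from pvsignal.synthetic import GeneratorConfig, generate


def make_caseset(reports=None, drugs=None, events=None, vocabulary=None) -> CaseSet:
    """Build a small CaseSet from compact row tuples.

    reports: (report_id, case_id[, sex]) tuples; drugs: (report_id, name,
    role[, start]); events: (report_id, pt[, onset]).
    """
    rep_rows = []
    for r in (reports or []):
        rid, cid, *rest = r
        sex = rest[0] if rest else "F"
        rep_rows.append(dict(report_id=rid, case_id=cid, receipt_date="20230101",
                             sex=sex, age_years=np.nan, weight_kg=np.nan,
                             country="US", reporter="unknown", outcomes="",
                             quarter="2023Q1", source="FAERS", indication=""))
    drug_rows = [dict(report_id=d[0], drug_name=d[1], role=d[2],
                      start_date=d[3] if len(d) > 3 else "")
                 for d in (drugs or [])]
    ev_rows = [dict(report_id=e[0], pt=e[1], onset_date=e[2] if len(e) > 2 else "")
               for e in (events or [])]
    return CaseSet(
        reports=pd.DataFrame(rep_rows),
        drugs=pd.DataFrame(drug_rows) if drug_rows else CaseSet().drugs,
        events=pd.DataFrame(ev_rows) if ev_rows else CaseSet().events,
        vocabulary=dict(vocabulary or {}),
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Fast study-shaped generator settings shared across ingestion tests."""
    return GeneratorConfig(n_reports=2000, seed=7)


@pytest.fixture(scope="session")
def faers_archive(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("faers")
    truth = generate(small_config, out, dialect="FAERS")
    return out, truth


@pytest.fixture(scope="session")
def jader_archive(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("jader")
    truth = generate(small_config, out, dialect="JADER")
    return out, truth
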