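import numpy as np
import pandas as pd
import pytest

from pvsignal.reports import Provenance, ReportSet
from pvsignal.synthetic import DrugSpec, EventSpec, GeneratorConfig, SignalSpec


def make_universe(rows):
    """Build a ReportSet from compact rows:
    (primaryid, caseid, [(drugname, canonical, role), ...], [pt, ...])
    with default demographics."""
    demo, drugs, events = [], [], []
    for pid, caseid, drug_mentions, pts in rows:
        demo.append({"primaryid": pid, "caseid": caseid, "age": 40.0,
                     "sex": "F", "country": "US"})
        for raw, canon, role in drug_mentions:
            drugs.append({"primaryid": pid, "drugname": raw,
                          "canonical": canon, "role": role})
        for pt in pts:
            events.append({"primaryid": pid, "pt": pt})
    return ReportSet(
        demo=pd.DataFrame(demo, columns=["primaryid", "caseid", "age", "sex", "country"]),
        drugs=pd.DataFrame(drugs, columns=["primaryid", "drugname", "canonical", "role"]),
        events=pd.DataFrame(events, columns=["primaryid", "pt"]),
        provenance=Provenance(raw_reports=len(demo)),
    )


@pytest.fixture
def tiny_universe():
    """Four enumerable reports: drugX/drugY crossed with seizure/nausea."""
    return make_universe([
        (1, 1, [("drugX", "drugX", "PS")], ["Seizure"]),
        (2, 2, [("drugX", "drugX", "PS")], ["Nausea"]),
        (3, 3, [("drugY", "drugY", "PS")], ["Seizure"]),
        (4, 4, [("drugY", "drugY", "PS")], ["Nausea"]),
    ])


#: synonym dictionary matching small_config's catalog
SMALL_SYNONYMS = {"BrandX": "drugX", "drugX": "drugX",
                  "drugY": "drugY", "background": "background"}


@pytest.fixture
def small_config():
    """Two target drugs + background, a planted signal, moderate size."""
    return GeneratorConfig(
        n_reports=5000,
        drugs=(
            DrugSpec("drugX", 0.2, ("BrandX",)),
            DrugSpec("drugY", 0.3, ()),
            DrugSpec("background", 0.5, ()),
        ),
        events=(
            EventSpec("Seizure", 0.02),
            EventSpec("Nausea", 0.30),
            EventSpec("Headache", 0.25),
        ),
        signals=(SignalSpec("drugX", "Seizure", 4.0),),
        duplicate_rate=0.1,
        missing_age_rate=0.2,
        missing_sex_rate=0.1,
        missing_country_rate=0.05,
        seed=1234,
    )
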