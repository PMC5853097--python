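import numpy as np
import pytest

from fattyroc.core_data import MEASURED_ANALYTES, CohortTable, SubjectRecord, compute_derived_table
from fattyroc.synthetic import AnalyteSpec, SyntheticPanelSpec, default_paper_spec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20180314)


def make_record(subject_id, cohort, base=None, **overrides):
    """A SubjectRecord with a plausible measured panel."""
    conc = {
        "AA": 20.0,
        "DGLA": 2.2,
        "DHA": 3.8,
        "EPA": 0.35,
        "elaidic": 0.18,
        "LA": 14.0,
        "oleic": 13.9,
        "palmitelaidic": 0.02,
        "palmitic": 25.4,
        "palmitoleic": 0.21,
        "stearic": 19.5,
    }
    conc.update(base or {})
    return SubjectRecord(subject_id=subject_id, cohort=cohort, concentrations=conc, **overrides)


@pytest.fixture
def small_table():
    """3 ASD + 3 NEU records with metadata and derived measures."""
    records = [
        make_record("a1", "ASD", {"AA": 19.0}, diagnosis_subtype="autism",
                    seafood_meals_per_month=2.0),
        make_record("a2", "ASD", {"DGLA": 2.0}, diagnosis_subtype="Aspergers",
                    seafood_meals_per_month=5.0),
        make_record("a3", "ASD", {"DHA": 4.2}, diagnosis_subtype="PDD_NOS",
                    seafood_meals_per_month=0.0),
        make_record("n1", "NEU", {"AA": 21.0}, seafood_meals_per_month=3.0),
        make_record("n2", "NEU", {"DGLA": 2.4}, seafood_meals_per_month=1.0),
        make_record("n3", "NEU", {"DHA": 3.5}, seafood_meals_per_month=6.0),
    ]
    return compute_derived_table(CohortTable(records=records, provenance="fixture"))


@pytest.fixture(scope="session")
def paper_spec():
    return default_paper_spec(seed=11)


@pytest.fixture(scope="session")
def paper_table(paper_spec):
    """One realization of the default study conditions (63 ASD, 49 NEU)."""
    return generate_cohort(paper_spec)


def null_normal_spec(n_asd=63, n_neu=49, seed=0):
    """All-null spec with normal marginals (for calibration checks)."""
    return SyntheticPanelSpec(
        n_asd=n_asd,
        n_neu=n_neu,
        analytes={
            a: AnalyteSpec(neu_mean=10.0, neu_cv=0.1, cohens_d=0.0, family="normal")
            for a in MEASURED_ANALYTES
        },
        seed=seed,
    )
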