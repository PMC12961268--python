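import pytest

from pvfaers import (Report, DrugRecord, SimConfig, assign_cohorts,
                     bundles_to_reports, deduplicate, generate_dataset)


def make_report(report_id="1", case_id=None, receipt="20230101", sex="F",
                drugs=None, reactions=None, outcomes=(), event_date=None,
                age=None, weight=None, source="CN"):
    """Hand-build a report without going through file ingestion."""
    if drugs is None:
        drugs = [make_drug("semaglutide", "glp1ra", "PS")]
    return Report(
        report_id=report_id,
        case_id=case_id if case_id is not None else report_id,
        receipt_date=receipt,
        sex=sex,
        age_years=age,
        weight_kg=weight,
        report_source=source,
        outcomes=frozenset(outcomes),
        drugs=list(drugs),
        reactions=list(reactions or ["Nausea"]),
        event_date=event_date,
    )


def make_drug(name, class_tag, role, start=None):
    return DrugRecord(verbatim_name=name.upper(), canonical_name=name,
                      class_tag=class_tag, role=role, therapy_start_date=start)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_reports=2000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_reports(small_dataset):
    bundles, _ = small_dataset
    return deduplicate(bundles_to_reports(bundles))


@pytest.fixture(scope="session")
def small_assignments(small_reports):
    return assign_cohorts(small_reports)
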