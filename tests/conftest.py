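import pytest

from faerspv import (
    CaseReport,
    DrugSpec,
    MeddraMap,
    SignalSpec,
    assemble_reports,
    deduplicate,
    default_config,
    generate_quarter,
    parse_date,
)


def _make_report(
    caseid=1,
    primaryid=None,
    fda_dt=20230101,
    sex=None,
    age_years=None,
    occupation_code=None,
    reporter_class="unknown",
    drugs=(("DRUG A", "PS"),),
    reactions=("alpha syndrome",),
    therapy_start="",
    event_date="",
):
    return CaseReport(
        caseid=caseid,
        primaryid=primaryid if primaryid is not None else caseid * 10,
        fda_dt=fda_dt,
        sex=sex,
        age_years=age_years,
        occupation_code=occupation_code,
        reporter_class=reporter_class,
        drugs=tuple(drugs),
        reactions=tuple(reactions),
        therapy_start=parse_date(therapy_start),
        event_date=parse_date(event_date),
        report_year=fda_dt // 10000,
    )


@pytest.fixture
def report_factory():
    """Factory for hand-built CaseReports with sensible defaults."""
    return _make_report


@pytest.fixture
def fixture_map():
    return MeddraMap({
        "fatigue": "General disorders and administration site conditions",
        "alpha syndrome": "Nervous system disorders",
        "beta syndrome": "Nervous system disorders",
        "gamma syndrome": "Cardiac disorders",
    })


def _sim_config():
    return default_config(
        n_background_reports=1500,
        drug_specs=(
            DrugSpec(
                name="alphadrug",
                synonyms=("alphatest",),
                n_ps_reports=300,
                signal_pts=(
                    SignalSpec("alpha syndrome", 8.0, 0.01, "all"),
                    SignalSpec("beta syndrome", 8.0, 0.02, "non_medical"),
                ),
                label_pts=("alpha syndrome",),
                weibull_shape=0.81,
                weibull_scale=325.0,
            ),
            DrugSpec(
                name="betadrug",
                synonyms=("betabrand",),
                n_ps_reports=40,
                weibull_shape=1.48,
                weibull_scale=132.0,
                first_year=2022,
            ),
        ),
        duplicate_rate=0.1,
        seed=20240530,
    )


@pytest.fixture(scope="session")
def sim():
    """One shared synthetic quarter: (config, quarter, truth, deduplicated reports)."""
    config = _sim_config()
    quarter, truth = generate_quarter(config)
    reports = deduplicate(assemble_reports(quarter))
    return config, quarter, truth, reports
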