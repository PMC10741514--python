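import pytest
from hypothesis import settings

from disprop.reports import AdverseEventReport, DrugMention, DrugRole, ReportSet
from disprop.simulate import generate_reports, masking_scenario

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_report(report_id, suspects, reactions, concomitants=(), reasons=None, **kwargs):
    """Terse report constructor for fixtures: names in, validated report out."""
    reasons = reasons or {}
    drugs = [DrugMention(s, DrugRole.SUSPECT, reasons.get(s)) for s in suspects]
    drugs += [DrugMention(c, DrugRole.CONCOMITANT) for c in concomitants]
    return AdverseEventReport(
        report_id=report_id, drugs=tuple(drugs), reactions=tuple(reactions), **kwargs
    )


MFI = "Infertility male"


@pytest.fixture
def toy_reports():
    """Five reports whose 2x2 cells are enumerable by hand (index drug D1)."""
    return ReportSet(
        (
            make_report("R1", ["D1"], [MFI]),
            make_report("R2", ["D1", "D2"], [MFI]),
            make_report("R3", ["D2"], ["Rash"]),
            make_report("R4", ["D1"], ["Headache"]),
            make_report("R5", ["D3"], [MFI]),
        )
    )


@pytest.fixture(scope="session")
def masking_cfg():
    return masking_scenario()


@pytest.fixture(scope="session")
def masking_rs(masking_cfg):
    return generate_reports(masking_cfg)
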