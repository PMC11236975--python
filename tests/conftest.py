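import pytest

from paleoaudit import AuditConfig, ViolationProfile, generate_study
from paleoaudit.cli_report import audit_study

# small files for unit tests; the audit's confidence floor is scaled to match
SMALL_READS = 1200


@pytest.fixture(scope="session")
def small_config():
    return AuditConfig(min_confident_n=150)


@pytest.fixture(scope="session")
def baseline_study(tmp_path_factory):
    """A violation-free synthetic study (bundle + files on disk)."""
    out = tmp_path_factory.mktemp("baseline")
    bundle = generate_study(
        ViolationProfile.of(), seed=11, out_dir=out, n_reads=SMALL_READS
    )
    return bundle, out / bundle.study.accession


@pytest.fixture(scope="session")
def baseline_report(baseline_study, small_config):
    bundle, study_dir = baseline_study
    return audit_study(bundle, data_dir=study_dir, config=small_config)
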