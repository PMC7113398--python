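import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def melanoma_cohort():
    """One melanoma-like synthetic cohort (401 patients, mixed planted effects)."""
    from hlasurv.simulate import default_melanoma_config, simulate_cohort

    cohort, truth = simulate_cohort(default_melanoma_config(seed=11))
    return cohort, truth


@pytest.fixture()
def toy_clinical(tmp_path):
    """Three-patient clinical file; P3 lacks OS months."""
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "patient_id\tage\tgender\tstage\ttumor_status\tbreslow_depth\tos_months\tevent\n"
        "P1\t61\tmale\tIIIa\twith_tumor\t3.5\t24.0\t1\n"
        "P2\t45\tfemale\tI\ttumor_free\t0.8\t60.5\t0\n"
        "P3\t70\tmale\tII\ttumor_free\t2.0\t\t1\n"
    )
    return path


@pytest.fixture()
def toy_alleles(tmp_path):
    path = tmp_path / "alleles.tsv"
    path.write_text(
        "patient_id\tallele\n"
        "P1\tHLA-A*01:01\n"
        "P1\tHLA-A*01:02\n"
        "P1\tHLA-B*08:01\n"
        "P2\tA*01:03\n"
        "P2\tHLA-DRB1*12:01\n"
        "P3\tHLA-B*55:01\n"
    )
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
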