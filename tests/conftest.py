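import pytest

from ctcpheno.panel import make_default_panel
from ctcpheno.pipeline import PipelineConfig, run_pipeline
from ctcpheno.simulate import CohortConfig, DonorEntry, GeneratorParams, PatientEntry


@pytest.fixture(scope="session")
def panel():
    return make_default_panel()


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


def make_small_cohort(**overrides) -> CohortConfig:
    """A two-patient cohort scaled for fast unit tests."""
    defaults = dict(carrier_count=800, control_count=200, enriched_count=300,
                    debris_fraction=0.05)
    defaults.update(overrides)
    patients = [
        PatientEntry("A", 60, "M", "3", "0", "0", "III", "Oral", "S", 80,
                     mixture=(0.25, 0.5, 0.25)),
        PatientEntry("B", 55, "F", "2", "0", "0", "II", "Oral", "S", 0),
    ]
    donors = [DonorEntry("HD", 0)]
    return CohortConfig(patients=patients, healthy_donors=donors, **defaults)


@pytest.fixture()
def small_cohort():
    return make_small_cohort()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default seeded cohort; shared across tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(output_dir=str(out), seed=1)
    return run_pipeline(cfg)
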