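import pytest

from ervtrace.io import Individual, Pedigree
from ervtrace.simulate import FamilyModel, SimConfig, generate_cohort


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        [
            Individual(id="sire1", sex="M", vital_status="deceased"),
            Individual(id="dam1", sex="F"),
            Individual(id="joey1", sire="sire1", dam="dam1", sex="F"),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deep-coverage cohort with fixed-frequency KoRV sites (fast, reused)."""
    cfg = SimConfig(
        seed=11,
        mean_coverage=60.0,
        families=(
            FamilyModel(name="KoRV", founder_aaf=("uniform", 0.3, 0.9), n_sites=6),
        ),
    )
    return generate_cohort(cfg, 6, 2)
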