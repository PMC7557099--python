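import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgxstrat import Cohort, PGxAnnotation, SimConfig, VariantRecord, simulate_cohort

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim():
    """Default three-group admixed cohort (300/group, 1000 variants)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture()
def tiny_cohort():
    """Hand-built 5-sample x 3-variant cohort with one PGx annotation."""
    variants = [
        VariantRecord("rs1", "1", 100, "A", "G",
                      PGxAnnotation("additive", "warfarin", "dosage", "higher dose")),
        VariantRecord("rs2", "1", 200, "T", "C",
                      PGxAnnotation("dominant", "codeine", "toxicity", "")),
        VariantRecord("rs3", "2", 50, "G", "C"),
    ]
    genotypes = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, np.nan, 1],
            [1, 0, 2],
            [0, 2, np.nan],
        ],
        dtype=float,
    )
    ancestry = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.9, 0.1, 0.0],
            [0.1, 0.9, 0.0],
            [0.0, 0.8, 0.2],
            [0.6, 0.03, 0.37],
        ]
    )
    sire = np.array(["White", "White", "Black", "Black", "Hispanic"], dtype=object)
    return Cohort(["s1", "s2", "s3", "s4", "s5"], genotypes, variants,
                  sire_labels=sire, ancestry=ancestry)
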