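import numpy as np
import pytest

from famshare.cohort import FamilyCohort, GenomeAsset, Role, Sample, Sex
from famshare.simulate import SimulationConfig, generate_cohort


def make_sample(sample_id, family_id, role="other", ethnicity="E1",
                sex="M", age=30.0, region="R1"):
    return Sample(sample_id, family_id, Role(role), ethnicity, Sex(sex),
                  float(age), region)


def make_genome(genome_id, sample_id="s1", species="sp1", sequence="ACGT",
                completeness=90.0, contamination=1.0, contig=None):
    return GenomeAsset(
        genome_id=genome_id,
        sample_id=sample_id,
        species_label=species,
        contigs={contig or genome_id: sequence},
        completeness=completeness,
        contamination=contamination,
    )


def random_sequence(length, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture
def family_cohort():
    """Two 2-member families plus one singleton."""
    return FamilyCohort(
        [
            make_sample("s1", "F1", "father", sex="M", age=40),
            make_sample("s2", "F1", "mother", sex="F", age=38),
            make_sample("s3", "F2", "father", sex="M", age=45),
            make_sample("s4", "F2", "child", sex="F", age=8),
            make_sample("s5", "F3", "other", sex="M", age=30),
        ]
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with transmissions planted in every family for sp1."""
    cfg = SimulationConfig(
        n_families=5,
        members_per_family=2,
        n_species=2,
        genome_length=5000,
        substitution_rate_within_species=0.02,
        transmission_pairs=[(f"F{i + 1:02d}", "sp1") for i in range(5)],
        transmission_divergence=1e-4,
        residual_het_rate=2e-3,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort with a family abundance effect, no transmissions."""
    cfg = SimulationConfig(
        n_families=8,
        members_per_family=(2, 3),
        n_species=3,
        genome_length=3000,
        family_effect_size=1.5,
        residual_het_rate=2e-3,
        seed=3,
    )
    return generate_cohort(cfg)
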