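import pytest

from plastocompare.synthetic_data import (SynthSpec, TwintronPlant,
                                          generate_plastome,
                                          generate_reference_set)


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    """A quick-to-build genome: 12 genes, IR present, two planted twintrons."""
    return SynthSpec(
        seed=42, genome_id="fixture1", n_pcg=12, intron_rate=1.0,
        ir_copies=2, spacer_len=300,
        twintron_plants=(TwintronPlant("psbC", 1, 10, 100),
                         TwintronPlant("psbE", 2, 5, 150)),
        maturases=("mat1", "mat2"))


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return generate_plastome(small_spec)


@pytest.fixture(scope="session")
def small_refs(small_spec, small_genome):
    _, truth = small_genome
    return generate_reference_set(small_spec, truth)
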