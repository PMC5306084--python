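import pytest

from stoptox.synthetic import (
    PlantedCompound,
    SynthConfig,
    generate_batch_effect_matrix,
    generate_dataset,
)

# planted-batch-effect fixture used by the preprocess and acceptance tests
make_batch_matrix = generate_batch_effect_matrix


@pytest.fixture(scope="session")
def strong_dataset():
    """Small study with strong planted effects: D=200, T=40, O=20, N=2000."""
    config = SynthConfig(
        n_probes=2000,
        d_up=100,
        d_down=100,
        compounds=[
            PlantedCompound(
                name="toxA", t_up=20, t_down=20, overlap=20, antagonism_fraction=0.8
            )
        ],
        log2fc_range=(1.5, 3.3),
        seed=11,
    )
    return generate_dataset(config)
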