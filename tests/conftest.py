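import numpy as np
import pandas as pd
import pytest

import gi_refine as gr


@pytest.fixture(scope="session")
def small_config():
    """A fast small-screen configuration used by most integration tests."""
    return gr.SynthConfig(
        n_cells=120,
        n_target_genes=60,
        n_mutated_genes=4,
        n_reference_noise_pairs=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return gr.generate(small_config)


@pytest.fixture(scope="session")
def small_gi(small_screen):
    mm = gr.call_functional_mutations(small_screen.variants)
    recurrent = gr.select_recurrent_genes(mm)
    gi = gr.characterize_gis(
        small_screen.depletion, small_screen.expression, mm, recurrent, gr.TestConfig()
    )
    return gi


@pytest.fixture()
def toy_depletion():
    genes = ["G1", "G2", "G3"]
    cells = [f"ACH-{i:06d}" for i in range(1, 9)]
    rng = np.random.default_rng(0)
    return gr.ScoreMatrix(
        pd.DataFrame(rng.normal(0, 1, (3, 8)), index=genes, columns=cells),
        role="depletion",
    )
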