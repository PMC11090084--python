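import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lumigene.protein_screen import default_motif_pssm, default_pts1_model, make_aligner
from lumigene.simulate import SynthConfig


@pytest.fixture(scope="session")
def aligner():
    return make_aligner()


@pytest.fixture(scope="session")
def blosum62(aligner):
    return aligner.substitution_matrix


@pytest.fixture(scope="session")
def motif_pssm():
    return default_motif_pssm()


@pytest.fixture(scope="session")
def pts1_model():
    return default_pts1_model()


@pytest.fixture()
def small_cfg():
    """A compact study configuration: 5 loci on a single short scaffold."""
    return SynthConfig(
        seed=7,
        n_scaffolds=1,
        scaffold_length_range=(40_000, 40_000),
        n_loci=5,
        track_noise=0.0,
    )


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """The shipped demo dataset, generated once per session."""
    from lumigene.pipeline import demo_dataset

    out = tmp_path_factory.mktemp("demo")
    config, truth = demo_dataset(out, seed=11)
    return config, truth
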