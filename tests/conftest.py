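import pytest

from ehrformer.harness import SplitSpec
from ehrformer.pipeline import prepare_cohort
from ehrformer.synthetic import SimConfig, generate_cohort
from ehrformer.tokenizer import build_vocab, fit_transforms, tokenize_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """~80 stays with panels, missingness, and every downstream feature."""
    return generate_cohort(SimConfig(n_patients=70, seed=42))


@pytest.fixture(scope="session")
def small_vocab(small_cohort):
    return build_vocab([s.events for s in small_cohort])


@pytest.fixture(scope="session")
def small_artifacts(small_cohort, small_vocab):
    return fit_transforms(small_cohort, small_vocab)


@pytest.fixture(scope="session")
def small_tokenized(small_cohort, small_vocab, small_artifacts):
    return tokenize_cohort(small_cohort, small_vocab, small_artifacts)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    return prepare_cohort(small_cohort, SplitSpec(seed=0))
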