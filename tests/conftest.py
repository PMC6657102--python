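import pytest
from hypothesis import settings

from smokereg.classifier import TrainConfig, fit
from smokereg.corpus import Corpus
from smokereg.extraction import RuleSet
from smokereg.synth import SynthConfig, generate

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet.load()


@pytest.fixture(scope="session")
def synth_corpus() -> Corpus:
    """The study-condition synthetic corpus: 500 notes, fixed seed."""
    return generate(SynthConfig(n_notes=500, seed=7))


def split_corpus(corpus: Corpus, n_train: int) -> tuple[Corpus, Corpus]:
    train_notes = corpus.notes[:n_train]
    test_notes = corpus.notes[n_train:]
    return (
        Corpus(
            notes=train_notes,
            annotations={n.note_id: corpus.annotations[n.note_id] for n in train_notes},
        ),
        Corpus(
            notes=test_notes,
            annotations={n.note_id: corpus.annotations[n.note_id] for n in test_notes},
        ),
    )


@pytest.fixture(scope="session")
def synth_split(synth_corpus) -> tuple[Corpus, Corpus]:
    """400 training / 100 held-out notes."""
    return split_corpus(synth_corpus, 400)


@pytest.fixture(scope="session")
def trained_model(synth_split):
    train, _ = synth_split
    return fit(train, TrainConfig(seed=0))
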