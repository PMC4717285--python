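import pytest

from trialtalk import dialog, synth


@pytest.fixture(scope="session")
def small_corpus():
    """60 synthetic trials with their gold subjective labels."""
    return synth.generate_corpus(synth.CorpusConfig(n_trials=60, seed=3))


@pytest.fixture(scope="session")
def engine(small_corpus):
    records, gold = small_corpus
    return dialog.DialogEngine(
        dialog.default_script(), records, gold, dialog.default_lexicon()
    )
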