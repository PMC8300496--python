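import pytest

from causaltext.annotation import LexiconTagger, lexicon_tag
from causaltext.extraction import EffectLexicon


@pytest.fixture(scope="session")
def tagger():
    return LexiconTagger()


@pytest.fixture(scope="session")
def effect_lexicon():
    return EffectLexicon(modifier_weights={"slightly": 0.5})


@pytest.fixture(scope="session")
def tag_one():
    """Tag a single sentence with the base lexicon tagger."""

    def _tag(text, lexicon=None):
        sentences = lexicon_tag(text, lexicon)
        assert len(sentences) == 1
        return sentences[0]

    return _tag
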