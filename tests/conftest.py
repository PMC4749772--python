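import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper module

from chemseg import Lexicon, LexiconSet, TokenizerConfig


@pytest.fixture(scope="session")
def builtin_lexica() -> LexiconSet:
    return LexiconSet.builtin()


@pytest.fixture()
def cfg() -> TokenizerConfig:
    return TokenizerConfig()


@pytest.fixture()
def empty_lexica() -> LexiconSet:
    return LexiconSet.empty()


def make_lexicon(entries, policy="sensitive", name="test"):
    return Lexicon.from_iterable(entries, policy, name)
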