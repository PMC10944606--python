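import pytest

from designminer import GeneratorConfig, RuleEngine, generate, load_lexicon, load_rules


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def engine(lexicon, rules):
    return RuleEngine(rules=rules, lexicon=lexicon)


@pytest.fixture(scope="session")
def synthetic_500(lexicon):
    """The fixed 500-abstract synthetic corpus used by pipeline-level tests."""
    return generate(GeneratorConfig(n_abstracts=500, seed=7), lexicon)
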