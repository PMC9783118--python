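import pytest

from substex import load_lexicons
from substex.model import Record, Status, Substance
from substex.pipeline import run_record


@pytest.fixture(scope="session")
def lex():
    return load_lexicons()


@pytest.fixture(scope="session")
def classify(lex):
    """Run the full pipeline on a snippet; return per-substance status values."""

    def _classify(text, **kwargs):
        result = run_record(Record("snippet", text), lex, **kwargs)
        return {sub.json_key: result.results[sub].status.value for sub in Substance}

    return _classify


@pytest.fixture(scope="session")
def attributes_of(lex):
    """Run the pipeline on a snippet; return {(substance, kind, text), ...}."""

    def _attrs(text, **kwargs):
        result = run_record(Record("snippet", text), lex, **kwargs)
        return {
            (sub.json_key, a.kind.value, a.text)
            for sub in Substance
            for a in result.results[sub].attributes
        }

    return _attrs
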