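from importlib import resources

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from termspectrum.lexicons import LexiconSet, load_default_lexicons
from termspectrum.ngram_spectrum import NGramKey, NGramRecord, TagSummary


@pytest.fixture(scope="session")
def lex() -> LexiconSet:
    return load_default_lexicons()


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("termspectrum").joinpath(f"data/regression/{name}").read_text(
        encoding="utf-8"
    )
    return [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@pytest.fixture(scope="session")
def strict_filter_cases() -> list[list[str]]:
    return _read_tsv("strict_filter_cases.tsv")


@pytest.fixture(scope="session")
def cascade_cases() -> list[list[str]]:
    return _read_tsv("cascade_cases.tsv")


def make_record(
    tokens: list[str],
    pos: list[str],
    oscar: list[str] | None = None,
    comp: bool = False,
    has_rubbish: bool = False,
    f_T: dict[str, int] | None = None,
) -> NGramRecord:
    """Build an n-gram record directly, bypassing extraction."""
    words = tuple(t.upper().replace(" ", "_") for t in tokens)
    rec = NGramRecord(key=NGramKey(n=len(words), key=" ".join(words)))
    rec.f_T.update(f_T or {"doc": 1})
    rec.tag_summary = TagSummary(
        has_rubbish=has_rubbish,
        oscar={o for o in (oscar or []) if o and o != "-"},
        comp=comp,
        pos_seq=tuple(pos),
    )
    return rec
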