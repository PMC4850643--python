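"""Deterministic fixture corpora with planted terminology and ground truth.

The generator emits small synthetic document sets in which chosen
term-like phrases are planted a known number of times per document,
surrounded by general-English filler and optional planted rubbish
tokens.  Alongside the corpus it returns the exact expected frequency
table (f_T per document and f_A) and the expected term-like key set, so
end-to-end runs can be asserted against ground truth.

Planted phrases are placed between commas, which fence n-gram windows;
a planted phrase therefore forms its own extraction segment and no
longer n-gram can swallow it, making the expected frequencies exact.
The filler vocabulary is drawn from the general-English lexicon and is
disjoint from all planted words.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from termspectrum.document_model import Corpus, RawDocument
from termspectrum.evaluation import canonical_phrase

#: phrase inventory for default fixtures: representative term-like phrases
DEFAULT_TERMS = (
    "Raman spectroscopy",
    "nickel catalyst",
    "temperature-programmed adsorption",
    "concentration gradient",
    "X-ray fluorescence spectrometer",
)

#: strings that strict filtering must tag rubbish
DEFAULT_RUBBISH = ("VIEWPOINT", "FQM-3994", "KJMOL-1", "215KMTA", "SELECTIVITY%")

DEFAULT_FILLER = (
    "system method window margin corner library budget schedule committee "
    "network journal market office project region sector session strategy "
    "summary survey"
).split()


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_docs: int = 3
    planted_terms: tuple[tuple[str, dict[str, int]], ...] = ()
    planted_rubbish: tuple[str, ...] = DEFAULT_RUBBISH
    filler_vocab: tuple[str, ...] = tuple(DEFAULT_FILLER)


@dataclass(frozen=True)
class FixtureExpectation:
    """Ground truth emitted with a generated corpus."""

    term_f_T: dict[str, dict[str, int]]  # canonical phrase key -> doc -> count
    term_f_A: dict[str, int]
    term_like_keys: frozenset[str]
    rubbish_tokens: tuple[str, ...]


def default_fixture_spec(seed: int = 0, n_docs: int = 3) -> FixtureSpec:
    """Plant every default phrase with seed-dependent per-document counts
    (1..3 occurrences in roughly two thirds of the documents)."""
    rng = random.Random(seed)
    doc_ids = [f"doc{i:02d}" for i in range(1, n_docs + 1)]
    planted = []
    for phrase in DEFAULT_TERMS:
        counts = {}
        for doc_id in doc_ids:
            if rng.random() < 0.7:
                counts[doc_id] = rng.randint(1, 3)
        if not counts:
            counts[rng.choice(doc_ids)] = 1
        planted.append((phrase, counts))
    return FixtureSpec(seed=seed, n_docs=n_docs, planted_terms=tuple(planted))


def generate_fixture_corpus(spec: FixtureSpec) -> tuple[Corpus, FixtureExpectation]:
    """Build the corpus and its ground truth; byte-deterministic per seed."""
    if not spec.planted_terms:
        spec = FixtureSpec(
            seed=spec.seed,
            n_docs=spec.n_docs,
            planted_terms=default_fixture_spec(spec.seed, spec.n_docs).planted_terms,
            planted_rubbish=spec.planted_rubbish,
            filler_vocab=spec.filler_vocab,
        )
    rng = random.Random(spec.seed)
    doc_ids = [f"doc{i:02d}" for i in range(1, spec.n_docs + 1)]
    sentences: dict[str, list[str]] = {d: [] for d in doc_ids}

    def filler() -> str:
        return rng.choice(spec.filler_vocab)

    term_f_T: dict[str, dict[str, int]] = {}
    for phrase, counts in spec.planted_terms:
        key = canonical_phrase(phrase)
        for doc_id, count in sorted(counts.items()):
            if count < 1:
                raise ValueError(f"planted count for {phrase!r} must be >= 1")
            if doc_id not in sentences:
                raise ValueError(f"unknown doc_id {doc_id!r} in planted counts")
            term_f_T.setdefault(key, {})[doc_id] = (
                term_f_T.get(key, {}).get(doc_id, 0) + count
            )
            for _ in range(count):
                sentences[doc_id].append(
                    f"The {filler()} and the {filler()} appeared , "
                    f"the {phrase} , and the {filler()} remained ."
                )
    for i, rubbish in enumerate(spec.planted_rubbish):
        doc_id = doc_ids[i % len(doc_ids)]
        sentences[doc_id].append(
            f"The {filler()} showed the value {rubbish} in the {filler()} record ."
        )
    for doc_id in doc_ids:
        sentences[doc_id].append(
            f"The {filler()} of the {filler()} was visible in the {filler()} ."
        )
        rng.shuffle(sentences[doc_id])

    docs = tuple(
        RawDocument(doc_id=d, body=" ".join(sentences[d]), title=f"Fixture {d}")
        for d in doc_ids
    )
    expectation = FixtureExpectation(
        term_f_T=term_f_T,
        term_f_A={k: sum(v.values()) for k, v in term_f_T.items()},
        term_like_keys=frozenset(term_f_T),
        rubbish_tokens=tuple(spec.planted_rubbish),
    )
    return Corpus(documents=docs), expectation
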