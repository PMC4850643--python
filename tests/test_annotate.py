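"""Tokenizer, chemical merging, sentence splitting, tagging, lemmatization."""

import pytest

from termspectrum.annotate import (
    Token,
    annotate_corpus,
    annotate_sentence,
    default_chem_recognizer,
    default_contract,
    default_pos_tagger,
    lemmatize_plural_noun,
    merge_chem_tokens,
    split_sentences,
    tokenize,
)
from termspectrum.document_model import Corpus, RawDocument


def toks(text: str) -> list[str]:
    return [t.surface for t in tokenize(text)]


class TestTokenize:
    def test_hyphenated_words_stay_single(self):
        assert toks("temperature-programmed adsorption") == [
            "temperature-programmed",
            "adsorption",
        ]

    def test_terminal_punctuation_split(self):
        assert toks("Raman spectroscopy.") == ["Raman", "spectroscopy", "."]

    def test_empty_input(self):
        assert tokenize("") == []

    def test_slash_and_colon_become_tokens(self):
        assert toks("water/oil") == ["water", "/", "oil"]
        assert toks("Pd:Al") == ["Pd", ":", "Al"]

    def test_balanced_brackets_kept(self):
        assert toks("Pt(111), bulk") == ["Pt(111)", ",", "bulk"]
        assert toks("(see text)") == ["(", "see", "text", ")"]

    def test_offsets_exact(self):
        text = "The Pd/Al2O3 catalyst."
        for t in tokenize(text):
            assert text[t.start : t.end] == t.surface


def mk(parts: list[str]) -> list[Token]:
    out, pos = [], 0
    for p in parts:
        out.append(Token(p, pos, pos + len(p)))
        pos += len(p)
    return out


class TestMergeChemTokens:
    def test_composition_with_percent_prefixes(self):
        tokens = mk(["2.7 %CO", "/", "10.0 %H2O", "/", "He"])
        merged = merge_chem_tokens(tokens)
        assert [t.surface for t in merged] == ["2.7 %CO/10.0 %H2O/He"]
        assert merged[0].comp is True
        assert merged[0].oscar == "CM"

    def test_non_chemical_slash_run_unchanged(self):
        tokens = mk(["water", "/", "oil"])
        merged = merge_chem_tokens(tokens)
        assert [t.surface for t in merged] == ["water", "/", "oil"]
        assert not any(t.comp for t in merged)

    def test_supported_catalyst_notation(self):
        tokens = mk(["Pd", "/", "Al2O3"])
        merged = merge_chem_tokens(tokens, chem_tags=["CM", None, "CM"])
        assert [t.surface for t in merged] == ["Pd/Al2O3"]
        assert merged[0].comp is True
        # oracle: re-split on "/" and check each part against element symbols
        from termspectrum.annotate import looks_like_formula

        for part in merged[0].surface.split("/"):
            assert looks_like_formula(part)

    def test_merge_preserves_character_content(self):
        text = "flow of 2.7 %CO/10.0 %H2O/He here"
        tokens = tokenize(text)
        tags = default_chem_recognizer([t.surface for t in tokens])
        merged = merge_chem_tokens(tokens, tags)
        for t in merged:
            assert text[t.start : t.end] == t.surface

    def test_number_percent_absorbed_from_raw_tokens(self):
        tokens = tokenize("with 2.7 %CO/10.0 %H2O/He flow")
        tags = default_chem_recognizer([t.surface for t in tokens])
        merged = merge_chem_tokens(tokens, tags)
        surfaces = [t.surface for t in merged]
        assert "2.7 %CO/10.0 %H2O/He" in surfaces


class TestSplitSentences:
    def test_two_sentences(self):
        sents = split_sentences(tokenize("A reaction occurs. B follows."))
        assert len(sents) == 2
        assert [s.index for s in sents] == [0, 1]

    def test_no_terminal_punctuation_single_sentence(self):
        sents = split_sentences(tokenize("no terminal punctuation here"))
        assert len(sents) == 1

    def test_abbreviation_does_not_split(self):
        sents = split_sentences(tokenize("Seen by Smith et al. in later work."))
        assert len(sents) == 1

    def test_every_token_in_exactly_one_sentence(self):
        tokens = tokenize("One here. Two there. Three.")
        sents = split_sentences(tokens)
        assert sum(len(s.tokens) for s in sents) == len(tokens)


class TestAnnotateSentence:
    def test_every_token_has_pos_and_lemma(self):
        corpus = Corpus((RawDocument("d", "The catalysts showed epoxidation of glass."),))
        (doc,) = annotate_corpus(corpus)
        for sent in doc.sentences:
            for tok in sent.tokens:
                assert tok.pos
                assert tok.lemma

    def test_reaction_and_ontology_tags(self):
        corpus = Corpus((RawDocument("d", "The epoxidation of glass was studied."),))
        (doc,) = annotate_corpus(corpus)
        by_surface = {t.surface: t for s in doc.sentences for t in s.tokens}
        assert by_surface["epoxidation"].oscar == "RN"
        assert by_surface["glass"].oscar == "ONT"
        assert by_surface["The"].oscar is None
        assert by_surface["The"].pos == "DT"

    def test_entity_span_tag_propagation(self):
        corpus = Corpus((RawDocument("d", "Heating cobalt acetate gave residue."),))
        (doc,) = annotate_corpus(corpus)
        by_surface = {t.surface: t for s in doc.sentences for t in s.tokens}
        assert by_surface["cobalt"].oscar == by_surface["acetate"].oscar == "CM"

    def test_wrong_length_tagger_is_contract_error(self, lex):
        from termspectrum.annotate import AnnotatorContract, Sentence

        bad = AnnotatorContract(
            pos_tagger=lambda s: ["NN"],
            chem_recognizer=lambda s: [None] * len(s),
        )
        sent = Sentence("d", 0, tokenize("two tokens"))
        with pytest.raises(ValueError):
            annotate_sentence(sent, bad, lex)


class TestDefaultPosTagger:
    @pytest.mark.parametrize(
        "word,tag",
        [
            ("the", "DT"),
            ("of", "IN"),
            ("reforming", "VBG"),
            ("supported", "VBN"),
            ("carbonaceous", "JJ"),
            ("catalysts", "NNS"),
            ("catalyst", "NN"),
            ("12.5", "CD"),
            ("MgO", "NNP"),
            ("Na2CO3", "NNP"),
        ],
    )
    def test_word_classes(self, word, tag):
        assert default_pos_tagger(["start", word])[1] == tag

    def test_one_tag_per_token(self):
        surfaces = "The quick catalyst shows MgO .".split()
        assert len(default_pos_tagger(surfaces)) == len(surfaces)


class TestLemmatizePluralNoun:
    @pytest.mark.parametrize(
        "surface,pos,lemma",
        [
            ("catalysts", "NNS", "catalyst"),
            ("processes", "NNS", "process"),
            ("studies", "NNS", "study"),
            ("gases", "NNS", "gas"),
            ("analyses", "NNS", "analysis"),
            ("species", "NNS", "species"),
            ("reforming", "VBG", "reforming"),  # gerunds never reduced
            ("catalysts", "VBG", "catalysts"),  # only NNS/NNPS touched
            ("glass", "NN", "glass"),
        ],
    )
    def test_lemmas(self, surface, pos, lemma):
        assert lemmatize_plural_noun(surface, pos) == lemma
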