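"""Accept/reject cascades, tag assignment, subsumption, spectrum building."""

import pytest

from conftest import make_record
from termspectrum.annotate import annotate_corpus
from termspectrum.document_model import Corpus, RawDocument
from termspectrum.ngram_spectrum import NGramKey, SpectrumConfig
from termspectrum.strict_filter import tag_corpus_rubbish
from termspectrum.term_rules import (
    Decision,
    SpectrumEntry,
    build_spectrum,
    classify_ngram,
    read_spectrum_tsv,
    spectrum_to_tsv,
    subsumption_filter,
)


class TestCascadeRegression:
    def test_all_cases(self, cascade_cases, lex):
        """Every regression phrase classifies as recorded (accept/reject)."""
        failures = []
        for phrase, pos, oscar, comp, rubbish, expected, rule in cascade_cases:
            rec = make_record(
                phrase.split("|"),
                pos.split(","),
                oscar=oscar.split(","),
                comp=bool(int(comp)),
                has_rubbish=bool(int(rubbish)),
            )
            d = classify_ngram(rec, lex)
            if d.outcome != expected or d.rule_id != rule:
                failures.append((phrase, expected, rule, d.outcome, d.rule_id))
        assert not failures, failures

    def test_deterministic(self, cascade_cases, lex):
        for phrase, pos, oscar, comp, rubbish, _, _ in cascade_cases[:20]:
            rec = make_record(phrase.split("|"), pos.split(","),
                              oscar=oscar.split(","), comp=bool(int(comp)),
                              has_rubbish=bool(int(rubbish)))
            assert classify_ngram(rec, lex) == classify_ngram(rec, lex)

    def test_dictionary_term_survives_rubbish_tag(self, lex):
        # the dictionary accept rule precedes the strict-filtering reject
        rec = make_record(["concentration", "gradient"], ["NN", "NN"],
                          has_rubbish=True)
        assert classify_ngram(rec, lex).rule_id == "GeneralChemTermRule"

    def test_rubbish_rejects_everything_else(self, lex):
        rec = make_record(["nickel", "catalyst"], ["NN", "NN"], has_rubbish=True)
        d = classify_ngram(rec, lex)
        assert d.outcome == "reject" and d.rule_id == "StrictFilteringTagRule"


def entry(words, f_A, term_like=True):
    key = NGramKey(len(words), " ".join(words))
    tags = {"term_like"} if term_like else set()
    return SpectrumEntry(key=key, tags=tags, f_A=f_A, f_T={"d": f_A},
                         decision=Decision("accept" if term_like else "reject",
                                           "x"))


def brute_force_subsumption(entries):
    """Oracle: containment scan over all ordered pairs."""
    keep = []
    for s in entries:
        removed = False
        if s.term_like:
            for l in entries:
                if not l.term_like or l.key.n <= s.key.n or l.f_A != s.f_A:
                    continue
                sw, lw = s.key.words, l.key.words
                if any(lw[i : i + len(sw)] == sw for i in range(len(lw))):
                    removed = True
                    break
        if not removed:
            keep.append(s)
    return keep


class TestSubsumptionFilter:
    def test_equal_frequency_subphrase_removed(self):
        entries = [entry(("RAMAN",), 4), entry(("RAMAN", "SPECTROSCOPY"), 4)]
        out = subsumption_filter(entries)
        assert [e.key.key for e in out] == ["RAMAN SPECTROSCOPY"]

    def test_unequal_frequency_kept(self):
        entries = [entry(("RAMAN",), 6), entry(("RAMAN", "SPECTROSCOPY"), 4)]
        assert len(subsumption_filter(entries)) == 2

    def test_uncontained_entry_kept(self):
        entries = [entry(("NICKEL",), 3), entry(("RAMAN", "SPECTROSCOPY"), 3)]
        assert len(subsumption_filter(entries)) == 2

    def test_non_contiguous_not_subsumed(self):
        entries = [
            entry(("ALPHA", "GAMMA"), 2),
            entry(("ALPHA", "BETA", "GAMMA"), 2),
        ]
        assert len(subsumption_filter(entries)) == 2

    def test_matches_brute_force_oracle(self):
        words = ["A1", "B2", "C3", "D4"]
        entries = []
        for i in range(len(words)):
            for j in range(i + 1, len(words) + 1):
                for fa in (2, 3):
                    entries.append(entry(tuple(words[i:j]), fa))
        got = {(e.key.key, e.f_A) for e in subsumption_filter(entries)}
        want = {(e.key.key, e.f_A) for e in brute_force_subsumption(entries)}
        assert got == want

    def test_rejected_entries_never_subsume(self):
        entries = [
            entry(("RAMAN",), 4),
            entry(("RAMAN", "SPECTROSCOPY"), 4, term_like=False),
        ]
        assert len(subsumption_filter(entries)) == 2


class TestBuildSpectrum:
    def _entries(self, text, **cfg_kwargs):
        corpus = Corpus((RawDocument("d", text),))
        docs = annotate_corpus(corpus)
        from termspectrum.lexicons import load_default_lexicons

        lex = load_default_lexicons()
        tag_corpus_rubbish(docs, lex)
        return build_spectrum(docs, lex, SpectrumConfig(**cfg_kwargs))

    def test_supported_mgo_in_spectrum(self):
        # second occurrence keeps the bigram's frequency above that of the
        # longer phrases, so subsumption leaves it in place
        entries = self._entries(
            "Raman spectroscopy of the supported MgO catalyst. "
            "The supported MgO powder was examined."
        )
        keys = {e.key.key for e in entries}
        assert "SUPPORTED MGO" in keys

    def test_stop_words_only_empty_termlike(self):
        entries = self._entries("Typically the example literature viewpoint.")
        assert [e for e in entries if e.term_like] == []

    def test_chem_entity_tag_propagates_to_phrase(self):
        entries = self._entries("The anchored Al2O3 stayed, the anchored Al2O3 moved.")
        by_key = {e.key.key: e for e in entries}
        e = by_key.get("ANCHORED AL2O3")
        assert e is not None and "chem_entity" in e.tags

    def test_general_chem_term_implies_term_like(self):
        entries = self._entries("A radial concentration gradient appeared here.")
        for e in entries:
            if "general_chem_term" in e.tags:
                assert "term_like" in e.tags
        assert any("general_chem_term" in e.tags for e in entries)

    def test_no_term_like_entry_contains_rubbish(self):
        entries = self._entries("The VIEWPOINT nickel catalyst was studied.")
        keys = {e.key.key for e in entries if e.term_like}
        assert all("VIEWPOINT" not in k for k in keys)
        assert "NICKEL CATALYST" in keys

    def test_nmax_respected(self):
        entries = self._entries(
            "Raman spectroscopy of the supported MgO catalyst.", n_max=2
        )
        assert all(e.key.n <= 2 for e in entries)

    def test_empty_corpus_empty_spectrum(self, lex):
        assert build_spectrum([], lex) == []

    def test_sorted_by_n_then_frequency_then_key(self):
        entries = self._entries(
            "nickel catalyst here. nickel catalyst there. anchored lysine once."
        )
        keys = [(e.key.n, -e.f_A, e.key.key) for e in entries]
        assert keys == sorted(keys)


class TestSpectrumRoundTrip:
    def test_tsv_round_trip(self, tmp_path, lex):
        corpus = Corpus((RawDocument("d", "The nickel catalyst and Raman spectroscopy."),))
        docs = tag_corpus_rubbish(annotate_corpus(corpus), lex)
        entries = build_spectrum(docs, lex)
        path = tmp_path / "spec.tsv"
        spectrum_to_tsv(entries, path)
        back = read_spectrum_tsv(path)
        assert [(e.key.key, e.f_A, sorted(e.tags)) for e in back] == [
            (e.key.key, e.f_A, sorted(e.tags)) for e in entries
        ]
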