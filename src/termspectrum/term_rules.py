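"""Accept/reject cascades that turn the n-gram spectrum into terminology.

Every n-gram is pushed through a rule cascade fixed per length class
(unigrams / bigrams / n >= 3).  Rules are applied consecutively; the
first rule that fires decides, and a unigram surviving every rule is
accepted by default.  Accepted n-grams carry tag subsets of
{term_like, general_chem_term, chem_entity, comp}:

* ``general_chem_term`` — accepted by the dictionary criterion
  (all words of one compendium term in any order, or n-1 words of a
  term plus one word known elsewhere in the dictionary);
* ``chem_entity`` — at least one constituent token carries a chemical
  tag (CM/RN/ONT); the phrase inherits it;
* ``comp`` — contains a merged composition token.

A final subsumption pass removes a short term-like phrase that occurs
only inside a longer one: S is dropped when its token sequence is a
contiguous part of a longer term-like phrase L with the same absolute
frequency.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from termspectrum.annotate import AnnotatedDocument
from termspectrum.lexicons import LexiconSet, is_general_english, match_general_chem_term, units_suffix_match
from termspectrum.ngram_spectrum import (
    NGramKey,
    NGramRecord,
    SpectrumConfig,
    aggregate,
)


@dataclass(frozen=True)
class Decision:
    outcome: str  # accept | reject
    rule_id: str
    detail: Optional[str] = None

    def __post_init__(self) -> None:
        if self.outcome not in ("accept", "reject"):
            raise ValueError(f"bad outcome {self.outcome!r}")


@dataclass
class SpectrumEntry:
    key: NGramKey
    tags: set[str]
    f_A: int
    f_T: dict[str, int]
    decision: Decision

    @property
    def term_like(self) -> bool:
        return "term_like" in self.tags


# --- POS tag sets of the morphological patterns ---------------------------

UNIGRAM_POS = frozenset({"VBG", "NN", "NNPS", "NNS"})
BIGRAM_FIRST = frozenset({"JJ", "JJR", "FW", "VBG", "VBD", "VBN", "NN", "NNP", "NNPS", "NNS"})
BIGRAM_SECOND = frozenset({"FW", "VBG", "NN", "NNP", "NNPS", "NNS"})
BIGRAM_EXCEPTIONS = frozenset({("VBG", "VBG"), ("VBG", "FW"), ("NNP", "FW")})
MULTI_FIRST = frozenset({"NN", "NNP", "VBG", "VBD", "VBN", "JJ", "JJR", "RB", "RBS", "FW"})
MULTI_MIDDLE = MULTI_FIRST | {"IN", "DT"}
MULTI_LAST = frozenset({"VBG", "NN", "NNP", "NNPS", "NNS"})
# participle-led phrases torn from their verbal context: a gerund or past
# participle directly followed by a noun, preposition or adjective
MULTI_EXCEPTION_FIRST = frozenset({"VBG", "VBN"})
MULTI_EXCEPTION_SECOND = frozenset({"NN", "IN", "JJ"})

#: ions, signs, axis captions and formula fragments rejected for unigrams
_ADD_RULES = tuple(
    re.compile(p)
    for p in (
        r"\d\+$",                                 # BA2+, CU2+, MO6+
        r"\(\d*\+\)$",                            # CE(3+)
        r"^[A-Za-z]{1,2}\(\w{1,3}\+?\)$",         # M(O2), G(D), TI(V), P(X)
        r"^[A-Za-z]{1,2}\d+(\.\d+)?$",            # PW91, GA15.6, PT0, CH3
        r"^[A-Za-z]{1,2}\d?-[A-Za-z]{1,2}\d?$",   # Et-CP, GC-MS, Zn-Al
    )
)


def _units_match_ngram(words: tuple[str, ...], lex: LexiconSet) -> bool:
    """Any token ends with a unit, including units spanning two tokens
    (a unit like "g/h" may arrive split across tokens)."""
    if any(units_suffix_match(w, lex) for w in words):
        return True
    return any(
        units_suffix_match(a + "/" + b, lex) or units_suffix_match(a + b, lex)
        for a, b in zip(words, words[1:])
    )


def classify_unigram(rec: NGramRecord, lex: LexiconSet) -> Decision:
    """Accept/reject cascade for 1-grams."""
    word = rec.key.words[0]
    ts = rec.tag_summary
    if match_general_chem_term([word], lex):
        return Decision("accept", "GeneralChemTermRule")
    if ts.has_rubbish:
        return Decision("reject", "StrictFilteringTagRule")
    if len(word) < 3:
        return Decision("reject", "ShortTokensRule")
    if units_suffix_match(word, lex):
        return Decision("reject", "UnitsRule")
    pos = ts.pos_seq[0] if ts.pos_seq else ""
    if (ts.oscar and pos in ("FW", "NNP")) or ts.comp:
        return Decision("accept", "ChemUnigramRule")
    if is_general_english(word, lex):
        return Decision("reject", "GeneralEnglishDictRule")
    if pos not in UNIGRAM_POS:
        return Decision("reject", "UnigramPOSRule")
    if any(p.search(word) for p in _ADD_RULES):
        return Decision("reject", "UnigramAddRules")
    return Decision("accept", "default_accept")


def _shared_prefix_rules(rec: NGramRecord, lex: LexiconSet) -> Optional[Decision]:
    words = rec.key.words
    if match_general_chem_term(list(words), lex):
        return Decision("accept", "GeneralChemTermRule")
    if rec.tag_summary.has_rubbish:
        return Decision("reject", "StrictFilteringTagRule")
    if all(len(w) < 3 for w in words):
        return Decision("reject", "ShortTokensRule")
    if len(set(words)) < len(words):
        return Decision("reject", "IdenticalTokensRule")
    if _units_match_ngram(words, lex):
        return Decision("reject", "UnitsRule")
    return None


def classify_bigram(rec: NGramRecord, lex: LexiconSet) -> Decision:
    """Accept/reject cascade for 2-grams."""
    early = _shared_prefix_rules(rec, lex)
    if early is not None:
        return early
    p1, p2 = (rec.tag_summary.pos_seq + ("", ""))[:2]
    if p1 in BIGRAM_FIRST and p2 in BIGRAM_SECOND:
        if (p1, p2) in BIGRAM_EXCEPTIONS:
            return Decision("reject", "BiGramPOSRule", detail="exception")
        return Decision("accept", "BiGramPOSRule")
    return Decision("reject", "BiGramPOSRule", detail="pattern not matched")


def classify_multigram(rec: NGramRecord, lex: LexiconSet) -> Decision:
    """Accept/reject cascade for n-grams with n >= 3."""
    early = _shared_prefix_rules(rec, lex)
    if early is not None:
        return early
    pos = rec.tag_summary.pos_seq
    n = rec.key.n
    if len(pos) != n:
        return Decision("reject", "ManyGramPOSRule", detail="missing POS")
    matches = (
        pos[0] in MULTI_FIRST
        and all(p in MULTI_MIDDLE for p in pos[1:-1])
        and pos[-1] in MULTI_LAST
    )
    if not matches:
        return Decision("reject", "ManyGramPOSRule", detail="pattern not matched")
    if pos[0] in MULTI_EXCEPTION_FIRST and pos[1] in MULTI_EXCEPTION_SECOND:
        return Decision("reject", "ManyGramPOSRule", detail="exception")
    return Decision("accept", "ManyGramPOSRule")


def classify_ngram(rec: NGramRecord, lex: LexiconSet) -> Decision:
    if rec.key.n == 1:
        return classify_unigram(rec, lex)
    if rec.key.n == 2:
        return classify_bigram(rec, lex)
    return classify_multigram(rec, lex)


# --- spectrum assembly ----------------------------------------------------

def _entry_for(rec: NGramRecord, decision: Decision) -> SpectrumEntry:
    tags: set[str] = set()
    if decision.outcome == "accept":
        tags.add("term_like")
        if decision.rule_id == "GeneralChemTermRule":
            tags.add("general_chem_term")
        if rec.tag_summary.oscar:
            tags.add("chem_entity")
        if rec.tag_summary.comp:
            tags.add("comp")
    return SpectrumEntry(
        key=rec.key, tags=tags, f_A=rec.f_A, f_T=dict(rec.f_T), decision=decision
    )


def _contiguous_subsequence(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    k = len(short)
    return any(long[i : i + k] == short for i in range(len(long) - k + 1))


def subsumption_filter(entries: list[SpectrumEntry]) -> list[SpectrumEntry]:
    """Drop a term-like phrase contained in a longer equally frequent one.

    S is removed iff some longer term-like L contains S's word sequence
    contiguously and f_A(S) = f_A(L) — i.e. S never occurs on its own.
    """
    term_like = [e for e in entries if e.term_like]
    removed: set[NGramKey] = set()
    for s in term_like:
        for l in term_like:
            if (
                l.key.n > s.key.n
                and l.f_A == s.f_A
                and _contiguous_subsequence(s.key.words, l.key.words)
            ):
                removed.add(s.key)
                break
    return [e for e in entries if e.key not in removed]


def build_spectrum(
    docs: list[AnnotatedDocument],
    lex: LexiconSet,
    cfg: SpectrumConfig | None = None,
    include_rejected: bool = False,
) -> list[SpectrumEntry]:
    """End-to-end terminology spectrum of an annotated, rubbish-tagged corpus.

    Extraction and aggregation, the per-length cascade, tag assignment,
    the subsumption filter and threshold filtering, in that order;
    output sorted by (n, -f_A, key).
    """
    cfg = cfg or SpectrumConfig()
    spectrum = aggregate(docs, cfg)
    entries = [_entry_for(rec, classify_ngram(rec, lex)) for rec in spectrum.values()]
    entries = subsumption_filter(entries)
    entries = [
        e
        for e in entries
        if e.f_A >= cfg.min_f_A and (not e.f_T or max(e.f_T.values()) >= cfg.min_f_T)
    ]
    if not include_rejected:
        entries = [e for e in entries if e.term_like]
    entries.sort(key=lambda e: (e.key.n, -e.f_A, e.key.key))
    return entries


# --- exports ----------------------------------------------------------------

_TSV_FIELDS = ("key", "n", "tags", "decision_rule", "f_A", "f_T")


def spectrum_to_tsv(entries: list[SpectrumEntry], path: str | Path) -> None:
    # fields never contain tabs or newlines, so plain joins are safe and
    # keep the JSON frequency column unescaped
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_TSV_FIELDS) + "\n")
        for e in entries:
            fh.write(
                "\t".join(
                    [
                        e.key.key,
                        str(e.key.n),
                        ",".join(sorted(e.tags)),
                        e.decision.rule_id,
                        str(e.f_A),
                        json.dumps(e.f_T, sort_keys=True),
                    ]
                )
                + "\n"
            )


def read_spectrum_tsv(path: str | Path) -> list[SpectrumEntry]:
    entries = []
    with open(path, encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
        header = lines[0].split("\t")
        for line in lines[1:]:
            row = dict(zip(header, line.split("\t")))
            key = NGramKey(n=int(row["n"]), key=row["key"])
            tags = set(filter(None, row["tags"].split(",")))
            f_t = {k: int(v) for k, v in json.loads(row["f_T"]).items()}
            entries.append(
                SpectrumEntry(
                    key=key,
                    tags=tags,
                    f_A=int(row["f_A"]),
                    f_T=f_t,
                    decision=Decision(
                        "accept" if "term_like" in tags else "reject",
                        row["decision_rule"],
                    ),
                )
            )
    return entries


def spectrum_to_json(entries: list[SpectrumEntry], path: str | Path) -> None:
    records = [
        {
            "key": e.key.key,
            "n": e.key.n,
            "tags": sorted(e.tags),
            "decision_rule": e.decision.rule_id,
            "f_A": e.f_A,
            "f_T": e.f_T,
        }
        for e in entries
    ]
    Path(path).write_text(
        json.dumps(records, ensure_ascii=False, indent=1), encoding="utf-8"
    )
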