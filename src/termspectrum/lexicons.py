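"""The six recognition dictionaries and their query operations.

Six lexicon kinds drive token and n-gram classification:

``general_english``
    Common English words (with words that occur in scientific
    terminology deliberately excluded); membership rejects unigrams.
``goldbook``
    General chemistry/physics/mathematics scientific terms in the style
    of the IUPAC compendium; used by the general-scientific-term
    matching criterion (:func:`match_general_chem_term`).
``stoplist``
    Words and abbreviations that can never be part of a term-like
    phrase.
``isotopes`` / ``elements``
    Stable-isotope and element-symbol lists used by the digit-run
    filtering exceptions.
``units``
    Measurement-unit strings matched as token suffixes.

All entries are stored uppercased; files are UTF-8, one entry per line,
``#`` comments allowed.  The shipped defaults are curated subsets that
cover the package's rule set and tests; full-size lists are drop-in
replaceable files with the same names.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

KINDS = ("general_english", "goldbook", "stoplist", "isotopes", "elements", "units")

#: fixed file name per lexicon kind inside a lexicon directory
KIND_FILENAMES = {k: f"{k}.txt" for k in KINDS}


@dataclass(frozen=True)
class Lexicon:
    """A normalized word/term list of one kind.

    ``word_index`` (goldbook only) maps each single word to the set of
    multi/single-word terms whose whitespace-split words contain it.
    """

    kind: str
    entries: frozenset[str]
    word_index: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, item: str) -> bool:
        return item.upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class LexiconSet:
    """One lexicon per kind; the full dictionary complement of a run."""

    lexicons: dict[str, Lexicon]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in KINDS if k not in self.lexicons]
        if missing:
            raise ValueError(f"missing lexicon kind(s): {missing}")

    def __getitem__(self, kind: str) -> Lexicon:
        return self.lexicons[kind]

    @property
    def general_english(self) -> Lexicon:
        return self.lexicons["general_english"]

    @property
    def goldbook(self) -> Lexicon:
        return self.lexicons["goldbook"]

    @property
    def stoplist(self) -> Lexicon:
        return self.lexicons["stoplist"]

    @property
    def isotopes(self) -> Lexicon:
        return self.lexicons["isotopes"]

    @property
    def elements(self) -> Lexicon:
        return self.lexicons["elements"]

    @property
    def units(self) -> Lexicon:
        return self.lexicons["units"]


def _parse_lines(lines: Iterable[str]) -> list[str]:
    out = []
    for line in lines:
        line = line.split("#", 1)[0].strip() if line.lstrip().startswith("#") else line.strip()
        if line:
            out.append(line.upper())
    return out


def _build_word_index(entries: Iterable[str]) -> dict[str, frozenset[str]]:
    index: dict[str, set[str]] = {}
    for term in entries:
        for word in term.split():
            index.setdefault(word, set()).add(term)
    return {w: frozenset(ts) for w, ts in index.items()}


def load_lexicon(path: str | Path, kind: str) -> Lexicon:
    """Load one lexicon file: one entry per line, ``#`` comments allowed."""
    if kind not in KINDS:
        raise ValueError(f"unknown lexicon kind: {kind!r}")
    raw = Path(path).read_text(encoding="utf-8")
    entries = _parse_lines(raw.splitlines())
    if not entries:
        raise ValueError(f"lexicon file {path} has no entries")
    entry_set = frozenset(entries)
    word_index = _build_word_index(entry_set) if kind == "goldbook" else {}
    return Lexicon(kind=kind, entries=entry_set, word_index=word_index)


def load_lexicon_set(directory: str | Path) -> LexiconSet:
    """Load all six kinds from ``directory`` using the fixed file names."""
    directory = Path(directory)
    lexicons, provenance = {}, {}
    for kind, fname in KIND_FILENAMES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"lexicon file for kind {kind!r} missing: {path}")
        lexicons[kind] = load_lexicon(path, kind)
        provenance[kind] = f"{path}:{hashlib.sha256(path.read_bytes()).hexdigest()[:12]}"
    return LexiconSet(lexicons=lexicons, provenance=provenance)


def load_default_lexicons() -> LexiconSet:
    """Load the lexicons shipped with the package."""
    base = resources.files("termspectrum").joinpath("data/lexicons")
    lexicons, provenance = {}, {}
    for kind, fname in KIND_FILENAMES.items():
        text = base.joinpath(fname).read_text(encoding="utf-8")
        entries = frozenset(_parse_lines(text.splitlines()))
        word_index = _build_word_index(entries) if kind == "goldbook" else {}
        lexicons[kind] = Lexicon(kind=kind, entries=entries, word_index=word_index)
        provenance[kind] = f"packaged:{fname}"
    return LexiconSet(lexicons=lexicons, provenance=provenance)


# --- query operations ----------------------------------------------------

def is_general_english(word: str, lex: LexiconSet) -> bool:
    """True iff ``word`` is a general-English word.

    Words that belong to scientific terminology are absent from the
    shipped list by construction, so they return False here.
    """
    if not word:
        raise ValueError("word must be non-empty")
    return word.upper() in lex.general_english.entries


def units_suffix_match(token_text: str, lex: LexiconSet) -> bool:
    """True iff the token ends with a measurement-unit string.

    Matching is case-insensitive suffix comparison: "KJMOL-1" matches
    the unit entry "MOL-1" even without a character boundary, which is
    how unit tails appear in run-together tokens.
    """
    if not token_text:
        raise ValueError("token_text must be non-empty")
    upper = token_text.upper()
    return any(upper.endswith(u) for u in lex.units.entries)


def match_general_chem_term(tokens: list[str], lex: LexiconSet) -> bool:
    """General-scientific-term criterion for an n-gram of lemma words.

    An n-gram is a general scientific term when either

    (a) all of its words are words of one single dictionary term,
        regardless of order ("content catalytic activity" matches the
        term "catalytic activity content"); or
    (b) n-1 of its words coincide with the n-1 words of a dictionary
        term and the remaining word occurs among the words of some
        *other* dictionary term ("radial concentration gradient":
        "concentration gradient" is a term and "radial" occurs in
        "radial development").

    For n = 1 both criteria collapse to exact entry membership.
    Words are compared as uppercased sets; an n-gram that repeats a
    word never matches (dictionary terms do not repeat words).
    """
    if not tokens or len(tokens) > 7:
        raise ValueError("n-gram must have 1..7 words")
    words = frozenset(w.upper() for w in tokens)
    if len(words) < len(tokens):
        return False  # dictionary terms never repeat a word
    gb = lex.goldbook
    if len(tokens) == 1:
        return next(iter(words)) in gb.entries

    term_words = {term: frozenset(term.split()) for term in gb.entries}
    # (a) all words inside one term
    for tw in term_words.values():
        if words <= tw:
            return True
    # (b) n-1 words form a full term, last word known elsewhere
    n = len(tokens)
    for term, tw in term_words.items():
        if len(tw) == n - 1 and tw <= words:
            remaining = words - tw
            if len(remaining) != 1:
                continue
            (rest,) = remaining
            containing = gb.word_index.get(rest, frozenset())
            if containing - {term}:
                return True
    return False
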