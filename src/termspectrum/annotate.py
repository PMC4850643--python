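"""Chemical-aware tokenization, sentence splitting and token tagging.

The tokenizer never splits on hyphens (hyphen splitting breaks compound
terms such as "temperature-programmed"), splits "/" and ":" into
separate tokens, and strips sentence punctuation into tokens of their
own.  A merging pass then re-joins slash/colon-separated runs whose
parts are chemical (recognizer-tagged CM or parseable as element
formulas) and absorbs leading "number %" tokens, producing single
composition tokens carrying the COMP tag — e.g.
"2.7 %CO/10.0 %H2O/He" becomes one token.

POS tagging and chemical-entity recognition are pluggable through
:class:`AnnotatorContract`; the defaults are deterministic rule/lexicon
taggers (closed-class word table + suffix rules for Penn-Treebank tags;
element-symbol/formula/suffix heuristics mapping to the three chemical
tags CM, RN, ONT).  Every token leaves annotation with a ``pos`` and a
``lemma`` tag; lemmatization touches plural nouns only, so gerunds like
"reforming" keep their surface form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from termspectrum.document_model import Corpus, normalize_text
from termspectrum.lexicons import LexiconSet, load_default_lexicons


@dataclass
class Token:
    """An annotated lexical unit with character offsets into its document."""

    surface: str
    start: int
    end: int
    pos: str | None = None
    lemma: str | None = None
    oscar: str | None = None  # CM (chemical matter) / RN (reaction) / ONT
    comp: bool = False
    rubbish: bool | None = None
    exception: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.surface):
            raise ValueError(
                f"offsets [{self.start},{self.end}) disagree with surface {self.surface!r}"
            )


@dataclass
class Sentence:
    doc_id: str
    index: int
    tokens: list[Token]


@dataclass(frozen=True)
class AnnotatorContract:
    """Pluggable tagging engines.

    ``pos_tagger`` maps the list of token surfaces of one sentence to
    exactly one Penn-Treebank tag per token; ``chem_recognizer`` maps it
    to an optional chemical tag (CM/RN/ONT) per token, with every token
    of a recognized multi-token entity carrying the entity's tag.
    """

    pos_tagger: Callable[[Sequence[str]], list[str]]
    chem_recognizer: Callable[[Sequence[str]], list[Optional[str]]]


@dataclass
class AnnotatedDocument:
    doc_id: str
    body: str  # normalized text the token offsets point into
    sentences: list[Sentence]


# --- element-formula parsing (case sensitive, for merge/recognition) -----

_ELEMENTS_CS = (
    "He Li Be Ne Na Mg Al Si Cl Ar Ca Sc Ti Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd "
    "Tb Dy Ho Er Tm Yb Lu Hf Ta Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa "
    "Np Pu Am Cm Bk Cf Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og "
    "H B C N O F P S K V W I U Y"
).split()

_FORMULA_RE = re.compile(
    r"^(?:\d+(?:\.\d+)?|%|[().+\-])*"
    r"(?:(?:" + "|".join(_ELEMENTS_CS) + r")(?:\d+(?:\.\d+)?|[().+\-]|%)*)+$"
)

#: element symbols that double as common English words; a bare symbol of
#: these is not taken as chemical matter without further evidence
_AMBIGUOUS_SYMBOLS = {"In", "As", "At", "No", "I", "He", "Be", "U", "K", "Y", "W"}


def looks_like_formula(surface: str) -> bool:
    """Case-sensitive test that a token parses as an element formula."""
    if not surface or not any(c.isupper() for c in surface):
        return False
    return bool(_FORMULA_RE.match(surface))


# --- tokenization --------------------------------------------------------

_TRAIL_PUNCT = '.,;:!?"\''
_CHUNK = re.compile(r"\S+")


def tokenize(text: str) -> list[Token]:
    """Split normalized text into tokens with exact character offsets.

    Hyphenated words stay single tokens; terminal punctuation, quotes,
    unbalanced brackets and internal "/" / ":" separators become tokens
    of their own.
    """
    tokens: list[Token] = []
    for m in _CHUNK.finditer(text):
        _split_chunk(m.group(), m.start(), tokens)
    return tokens


def _split_chunk(chunk: str, offset: int, out: list[Token]) -> None:
    # peel leading quotes / unbalanced opening brackets
    lead = 0
    while lead < len(chunk):
        c = chunk[lead]
        if c in "\"'" or (c == "(" and chunk.count("(") > chunk.count(")")):
            lead += 1
        else:
            break
    # peel trailing sentence punctuation / unbalanced closing brackets
    trail = len(chunk)
    while trail > lead:
        c = chunk[trail - 1]
        if c in _TRAIL_PUNCT or (
            c == ")" and chunk[lead:trail].count(")") > chunk[lead:trail].count("(")
        ):
            trail -= 1
        else:
            break
    for i in range(lead):
        out.append(Token(chunk[i], offset + i, offset + i + 1))
    core = chunk[lead:trail]
    if core:
        _split_separators(core, offset + lead, out)
    for i in range(trail, len(chunk)):
        out.append(Token(chunk[i], offset + i, offset + i + 1))


def _split_separators(core: str, offset: int, out: list[Token]) -> None:
    # "/" and ":" are token separators (re-joined later for chemistry)
    pos = 0
    for m in re.finditer(r"[/:]", core):
        if m.start() > pos:
            part = core[pos : m.start()]
            out.append(Token(part, offset + pos, offset + m.start()))
        out.append(Token(m.group(), offset + m.start(), offset + m.end()))
        pos = m.end()
    if pos < len(core):
        out.append(Token(core[pos:], offset + pos, offset + len(core)))


# --- chemical token merging ----------------------------------------------

_NUMBER = re.compile(r"^\d+(\.\d+)?$")


def _chemish(tok: Token) -> bool:
    if tok.oscar == "CM" or tok.comp:
        return True
    surface = tok.surface
    if surface.startswith("%"):
        surface = surface[1:]
    # a "number %X" pair already absorbed keeps an internal space
    surface = surface.split()[-1] if surface else surface
    if surface.startswith("%"):
        surface = surface[1:]
    return looks_like_formula(surface)


def merge_chem_tokens(
    tokens: list[Token], chem_tags: Sequence[Optional[str]] | None = None
) -> list[Token]:
    """Re-join composition tokens split by the tokenizer.

    Runs joined by "/" or ":" merge into one token when the joined
    parts are CM-tagged or contain element symbols; a leading
    "number %X" pair is absorbed first.  Merged tokens get ``comp=True``
    and the CM tag, and span the original character range, so the
    concatenated character content of the sentence never changes.
    """
    toks = [replace(t) for t in tokens]
    if chem_tags is not None:
        if len(chem_tags) != len(toks):
            raise ValueError("chem_tags length mismatch")
        for t, tag in zip(toks, chem_tags):
            if tag and t.oscar is None:
                t.oscar = tag

    changed = True
    while changed:
        changed = False
        # pass B: absorb "number" + "%X" pairs
        i = 0
        while i < len(toks) - 1:
            a, b = toks[i], toks[i + 1]
            if (
                _NUMBER.match(a.surface)
                and b.surface.startswith("%")
                and _chemish(b)
                and b.start >= a.end
            ):
                toks[i : i + 2] = [_join(a, b)]
                changed = True
            else:
                i += 1
        # pass A: join X "/" Y (or ":") when both sides are chemical
        i = 0
        while i < len(toks) - 2:
            a, sep, b = toks[i], toks[i + 1], toks[i + 2]
            if sep.surface in ("/", ":") and _chemish(a) and _chemish(b):
                toks[i : i + 3] = [_join(a, sep, b)]
                changed = True
            else:
                i += 1
    return toks


def _join(*parts: Token) -> Token:
    surface = parts[0].surface
    end = parts[0].end
    for p in parts[1:]:
        gap = p.start - end
        surface += " " * max(gap, 0) + p.surface
        end = p.end
    tok = Token(surface=surface, start=parts[0].start, end=end)
    tok.comp = True
    tok.oscar = "CM"
    return tok


# --- sentence splitting ---------------------------------------------------

_DEFAULT_ABBREVIATIONS: frozenset[str] | None = None


def _default_abbreviations() -> frozenset[str]:
    global _DEFAULT_ABBREVIATIONS
    if _DEFAULT_ABBREVIATIONS is None:
        lex = load_default_lexicons()
        _DEFAULT_ABBREVIATIONS = frozenset(
            e for e in lex.stoplist.entries if e.endswith(".")
        )
    return _DEFAULT_ABBREVIATIONS


def split_sentences(
    tokens: list[Token],
    doc_id: str = "",
    abbreviations: frozenset[str] | None = None,
) -> list[Sentence]:
    """Group tokens into sentences at terminal punctuation.

    A "." directly after a known abbreviation ("ca.", "fig.", "al.", …)
    is not a boundary.  Text without terminal punctuation forms a single
    sentence.
    """
    if abbreviations is None:
        abbreviations = _default_abbreviations()
    sentences: list[Sentence] = []
    current: list[Token] = []
    for tok in tokens:
        current.append(tok)
        if tok.surface in (".", "!", "?"):
            prev = current[-2] if len(current) >= 2 else None
            if (
                tok.surface == "."
                and prev is not None
                and (prev.surface.upper() + ".") in abbreviations
            ):
                continue
            sentences.append(Sentence(doc_id=doc_id, index=len(sentences), tokens=current))
            current = []
    if current:
        sentences.append(Sentence(doc_id=doc_id, index=len(sentences), tokens=current))
    return sentences


# --- default POS tagger ---------------------------------------------------

_CLOSED_CLASS = {
    **{w: "DT" for w in "a an the this that these those each every all both some any no another".split()},
    **{w: "IN" for w in (
        "of in on at by with from for into onto during under over between among within "
        "without through after before against about via upon across toward towards since"
    ).split()},
    **{w: "CC" for w in "and or but nor".split()},
    "to": "TO",
    **{w: "MD" for w in "can could may might must shall should will would".split()},
    **{w: "PRP" for w in "it we they he she i you".split()},
    **{w: "VBZ" for w in "is has does".split()},
    **{w: "VBP" for w in "are have do".split()},
    **{w: "VBD" for w in "was were did".split()},
    **{w: "RB" for w in (
        "very highly however also then thus therefore more most only not rather quite "
        "almost nearly inside here there still further well"
    ).split()},
    **{w: "FW" for w in "etc situ vitro vivo ibid".split()},
}

_JJ_SUFFIXES = ("ous", "ic", "ical", "ive", "able", "ible", "al", "ar", "ary", "less", "ful")


def default_pos_tagger(surfaces: Sequence[str]) -> list[str]:
    """Deterministic Penn-Treebank tagger: closed-class table + suffixes."""
    tags = []
    for idx, s in enumerate(surfaces):
        tags.append(_tag_word(s, sentence_initial=(idx == 0)))
    return tags


def _tag_word(s: str, sentence_initial: bool = False) -> str:
    if not any(c.isalnum() for c in s):
        return s if s in (".", ",", ":", "(", ")") else "SYM"
    low = s.lower()
    if _NUMBER.match(s):
        return "CD"
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if s[0].isdigit():
        return "CD"
    if any(c.isdigit() for c in s):
        return "NNP"
    if any(c.isupper() for c in s[1:]):
        return "NNP"  # MgO, UV-VIS, EXAF
    if s[0].isupper() and not sentence_initial:
        return "NNP"
    if low.endswith("ing") and len(low) >= 5:
        return "VBG"
    if low.endswith("ed") and len(low) >= 5:
        return "VBN"
    if low.endswith("ly") and len(low) >= 4:
        return "RB"
    for suf in _JJ_SUFFIXES:
        if low.endswith(suf) and len(low) >= len(suf) + 3:
            return "JJ"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) >= 4:
        return "NNS"
    return "NN"


# --- default chemical recognizer ------------------------------------------

_RN_SUFFIXES = ("GENATION", "OXIDATION", "YLATION", "OLYSIS", "YSIS", "IZATION")
_ONT_WORDS = frozenset(
    "glass adsorption desorption cation anion sintering slurry vacancy".split()
)
_CM_SUFFIXES = ("ENE", "ANE", "YNE", "OL", "IDE", "ATE", "ITE", "IUM", "OSE", "AMIDE", "AMINE")
_ACRONYM = re.compile(r"^[A-Z]{3,6}$")

#: small gazetteer of multi-token chemical entities; all tokens of a
#: recognized entity inherit the entity tag
_ENTITY_GAZETTEER = {
    ("cobalt", "acetate"): "CM",
    ("sodium", "chloride"): "CM",
    ("acetic", "acid"): "CM",
    ("carbon", "dioxide"): "CM",
    ("carbon", "monoxide"): "CM",
}


def default_chem_recognizer(surfaces: Sequence[str]) -> list[Optional[str]]:
    """Baseline CM/RN/ONT tagging from element symbols, formula shapes and
    name-suffix heuristics."""
    tags: list[Optional[str]] = [None] * len(surfaces)
    lowers = [s.lower() for s in surfaces]
    for span, tag in _ENTITY_GAZETTEER.items():
        k = len(span)
        for i in range(len(surfaces) - k + 1):
            if tuple(lowers[i : i + k]) == span:
                for j in range(i, i + k):
                    tags[j] = tag
    for i, s in enumerate(surfaces):
        if tags[i] is not None:
            continue
        upper = s.upper()
        if lowers[i] in _ONT_WORDS:
            tags[i] = "ONT"
        elif any(upper.endswith(suf) for suf in _RN_SUFFIXES):
            tags[i] = "RN"
        elif s in _ELEMENTS_CS and s not in _AMBIGUOUS_SYMBOLS:
            tags[i] = "CM"
        elif looks_like_formula(s) and (any(c.isdigit() for c in s) or len(s) > 2):
            tags[i] = "CM"
        elif _ACRONYM.match(s):
            tags[i] = "CM"
        elif any(upper.endswith(suf) for suf in _CM_SUFFIXES) and len(s) >= 5:
            tags[i] = "CM"
    return tags


def default_contract() -> AnnotatorContract:
    return AnnotatorContract(
        pos_tagger=default_pos_tagger, chem_recognizer=default_chem_recognizer
    )


# --- lemmatization ---------------------------------------------------------

_IRREGULAR_PLURALS = {
    "analyses": "analysis",
    "bases": "base",
    "gases": "gas",
    "species": "species",
    "series": "series",
    "hypotheses": "hypothesis",
    "syntheses": "synthesis",
    "spectra": "spectrum",
    "phenomena": "phenomenon",
    "criteria": "criterion",
    "media": "medium",
    "data": "data",
    "indices": "index",
    "matrices": "matrix",
    "vertices": "vertex",
    "nuclei": "nucleus",
    "radii": "radius",
    "foci": "focus",
}


def lemmatize_plural_noun(surface: str, pos: str) -> str:
    """Singularize plural nouns (NNS/NNPS); all other tokens unchanged.

    Lemmatization beyond plural nouns loses meaning ("reforming" must
    not become "reform"), so gerunds and verbs keep their surface form.
    """
    if pos not in ("NNS", "NNPS"):
        return surface
    low = surface.lower()
    if low in _IRREGULAR_PLURALS:
        lemma = _IRREGULAR_PLURALS[low]
        return lemma.capitalize() if surface[0].isupper() else lemma
    if low.endswith(("sses", "xes", "zes", "ches", "shes")):
        return surface[:-2]
    if low.endswith("ies") and len(low) > 4:
        return surface[:-3] + "y"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return surface[:-1]
    return surface


# --- sentence / corpus annotation ------------------------------------------

def annotate_sentence(
    sent: Sentence, contract: AnnotatorContract, lex: LexiconSet | None = None
) -> Sentence:
    """Attach pos, lemma and chemical tags to every token of a sentence."""
    surfaces = [t.surface for t in sent.tokens]
    pos_tags = list(contract.pos_tagger(surfaces))
    if len(pos_tags) != len(surfaces):
        raise ValueError(
            f"pos_tagger returned {len(pos_tags)} tags for {len(surfaces)} tokens"
        )
    chem_tags = list(contract.chem_recognizer(surfaces))
    if len(chem_tags) != len(surfaces):
        raise ValueError(
            f"chem_recognizer returned {len(chem_tags)} tags for {len(surfaces)} tokens"
        )
    for tok, pos, chem in zip(sent.tokens, pos_tags, chem_tags):
        tok.pos = pos
        if tok.oscar is None and chem is not None:
            tok.oscar = chem
        tok.lemma = lemmatize_plural_noun(tok.surface, pos)
    return sent


def annotate_corpus(
    corpus: Corpus,
    contract: AnnotatorContract | None = None,
    lex: LexiconSet | None = None,
) -> list[AnnotatedDocument]:
    """Normalize, tokenize, merge, sentence-split and tag a whole corpus."""
    contract = contract or default_contract()
    docs = []
    for doc in corpus:
        body = normalize_text(doc.body)
        tokens = tokenize(body)
        chem_tags = contract.chem_recognizer([t.surface for t in tokens])
        merged = merge_chem_tokens(tokens, chem_tags)
        sentences = split_sentences(merged, doc_id=doc.doc_id)
        for sent in sentences:
            annotate_sentence(sent, contract, lex)
        docs.append(AnnotatedDocument(doc_id=doc.doc_id, body=body, sentences=sentences))
    return docs
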