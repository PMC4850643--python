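"""Strict filtering: tag tokens that can never be part of a term-like phrase.

A token is "rubbish" when one of six filtering rules fires — unusual
special symbols, stop-list membership, runs of four / three digits,
leading digits, or a measurement-unit tail — *unless* the token matches
one of eleven exception patterns that protect legitimate chemistry:
crystallographic facet/Miller indexes (Ru(0001), Pt(111)), isotope-
labelled species (13C, 12C16O-13C16O), digit-prefixed substance names
(5-pentanediol), decimal catalyst compositions (1.5Au/C), merged
composition tokens (COMP tag), crystalline hydrates (…*6H2O),
1D/2D/3D method names, diacritic proper names (Brønsted) and bracketed
complexes carrying a chemical-entity tag.

Exceptions are checked first and exempt globally: an exempt token is
never rubbish regardless of which rule would have fired.  Within each
group the first match (in a fixed order) wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from termspectrum.annotate import AnnotatedDocument, Token
from termspectrum.lexicons import LexiconSet, units_suffix_match

RULES = (
    "SpecialSymbolsRule",
    "StopListRule",
    "4DigitRule",
    "3DigitRule",
    "2DigitRule",
    "UnitsRule",
)

EXCEPTIONS = (
    "facet_index_4digits",
    "miller_index_3digits",
    "substances_3digits",
    "isotopes",
    "substances_2digits",
    "catalysts",
    "comp",
    "cryst_hydrates",
    "spatial_dimension",
    "names",
    "oscar_tags",
)


@dataclass(frozen=True)
class FilterOutcome:
    rubbish: bool
    fired_rule: Optional[str] = None
    exception: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rubbish and (self.fired_rule is None or self.exception is not None):
            raise ValueError("rubbish outcome requires a rule and no exception")
        if self.exception is not None and self.rubbish:
            raise ValueError("exempt token cannot be rubbish")


# characters a token may contain without tripping SpecialSymbolsRule;
# "{"/"}" are included because Miller indexes are printed both ways
_ALLOWED_SYMBOLS = set(". -,/:()[]+=@®{}") - {" "}
_DIGITS4 = re.compile(r"\d{4}")
_DIGITS3 = re.compile(r"\d{3}")
_LEADING_DIGITS = re.compile(r"^\d")

#: name suffixes of the digit-prefixed substance classes the
#: substances_2digits exception protects (polyols, esters/carboxylates,
#: N-heterocycles, sugars, amines/amides); reconstruction from examples
_SUBSTANCE_SUFFIXES = ("DIOL", "TRIOL", "OLE", "ATE", "OSE", "AMINE", "AMIDE", "OXY")

_GREEK = re.compile(r"[Ͱ-Ͽἀ-῿]")


@lru_cache(maxsize=8)
def _element_patterns(elements: frozenset[str]):
    alt = "|".join(sorted(elements, key=len, reverse=True))
    return {
        # element (optionally with stoichiometry / closing bracket) followed
        # by a parenthesized or braced 4- or 3-digit surface index
        "facet4": re.compile(rf"(?:{alt})\d*[)\]}}]?[({{]\d{{4}}[)}}]"),
        "miller3": re.compile(rf"(?:{alt})\d*[)\]}}]?[({{]\d{{3}}[)}}]"),
        # run of element symbols interleaved with up to 3-digit counts,
        # optionally led by an isotope-style digit prefix
        "elemseq": re.compile(rf"^\d{{0,3}}(?:(?:{alt})\d{{0,3}})+$"),
        "anyelem": re.compile(rf"(?:{alt})"),
    }


@lru_cache(maxsize=8)
def _isotope_pattern(isotopes: frozenset[str]):
    alt = "|".join(sorted(isotopes, key=len, reverse=True))
    return re.compile(rf"^(?:{alt})(?:[-/]?(?:{alt}))*$")


def _is_substance_3digits(upper: str, pats) -> bool:
    if not _DIGITS3.search(upper):
        return False
    parts = re.split(r"[-/]", upper)
    core_found = False
    for part in parts:
        if pats["elemseq"].match(part) or re.fullmatch(r"[A-Z]+", part):
            if _DIGITS3.search(part) and pats["elemseq"].match(part):
                core_found = True
        else:
            return False
    return core_found


def _is_substance_2digits(upper: str) -> bool:
    m = re.match(r"^\d{1,2}-(.+)$", upper)
    if not m:
        return False
    rest = m.group(1)
    if not re.fullmatch(r"[A-Z0-9,()\-]+", rest):
        return False
    return rest.endswith(_SUBSTANCE_SUFFIXES)


def _is_catalyst_composition(upper: str, pats) -> bool:
    if "%" in upper or " " in upper:
        return False
    if not re.search(r"\d\.[\d\-]", upper):
        return False
    return bool(pats["anyelem"].search(upper))


def _is_cryst_hydrate(upper: str) -> bool:
    if "%" in upper or " " in upper:
        return False
    return len(upper) >= 5 and upper.endswith("H2O") and upper[0].isalpha()


def _is_spatial_dimension(upper: str) -> bool:
    return bool(re.match(r"^[123]D([- ]|$)", upper))


def _is_diacritic_name(surface: str) -> bool:
    if not surface:
        return False
    if _GREEK.search(surface):
        return False
    if not all(c.isalpha() or c in " -" for c in surface):
        return False
    return any(c.isalpha() and ord(c) > 127 for c in surface)


def _is_oscar_structural(tok: Token, upper: str) -> bool:
    if tok.oscar is None:
        return False
    return bool(re.search(r"-[A-Z]{2}", upper)) or upper.startswith("[")


def check_exceptions(tok: Token, lex: LexiconSet) -> Optional[str]:
    """Return the first matching exception id, or None.

    Matchers are tried in a fixed order; the comp exception
    consumes the COMP tag set at token merging, the oscar_tags exception
    requires a chemical-entity tag.
    """
    upper = tok.surface.upper()
    pats = _element_patterns(lex.elements.entries)
    iso = _isotope_pattern(lex.isotopes.entries)
    if pats["facet4"].search(upper):
        return "facet_index_4digits"
    if pats["miller3"].search(upper):
        return "miller_index_3digits"
    if _is_substance_3digits(upper, pats):
        return "substances_3digits"
    if iso.match(upper):
        return "isotopes"
    if _is_substance_2digits(upper):
        return "substances_2digits"
    if _is_catalyst_composition(upper, pats):
        return "catalysts"
    if tok.comp:
        return "comp"
    if _is_cryst_hydrate(upper):
        return "cryst_hydrates"
    if _is_spatial_dimension(upper):
        return "spatial_dimension"
    if _is_diacritic_name(tok.surface):
        return "names"
    if _is_oscar_structural(tok, upper):
        return "oscar_tags"
    return None


def _fired_rule(tok: Token, lex: LexiconSet) -> Optional[str]:
    upper = tok.surface.upper()
    for c in upper:
        if not (c.isascii() and c.isalnum()) and c not in _ALLOWED_SYMBOLS:
            return "SpecialSymbolsRule"
    if upper in lex.stoplist.entries:
        return "StopListRule"
    if _DIGITS4.search(upper):
        return "4DigitRule"
    if _DIGITS3.search(upper):
        return "3DigitRule"
    if _LEADING_DIGITS.match(upper):
        return "2DigitRule"
    if units_suffix_match(upper, lex):
        return "UnitsRule"
    return None


def apply_strict_filter(tok: Token, lex: LexiconSet) -> FilterOutcome:
    """Decide rubbish/valid for one annotated token.

    A token is rubbish iff some filtering rule fires and no exception
    exempts it; the outcome is a pure function of the token's fields
    and the lexicons.
    """
    exception = check_exceptions(tok, lex)
    if exception is not None:
        return FilterOutcome(rubbish=False, exception=exception)
    rule = _fired_rule(tok, lex)
    if rule is not None:
        return FilterOutcome(rubbish=True, fired_rule=rule)
    return FilterOutcome(rubbish=False)


def tag_corpus_rubbish(
    docs: list[AnnotatedDocument], lex: LexiconSet
) -> list[AnnotatedDocument]:
    """Set the rubbish/exception fields on every token of every document.

    Mutates and returns the given documents; idempotent.
    """
    for doc in docs:
        for sent in doc.sentences:
            for tok in sent.tokens:
                outcome = apply_strict_filter(tok, lex)
                tok.rubbish = outcome.rubbish
                tok.exception = outcome.exception
    return docs
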