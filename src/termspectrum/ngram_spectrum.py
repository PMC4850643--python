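"""Sentence-internal n-gram extraction and frequency aggregation.

An n-gram is a window of n consecutive tokens inside one sentence,
moved token by token, after dropping the definite/indefinite articles
(a/an/the) and with punctuation tokens acting as window fences (no
n-gram spans a comma, period or a stray slash).  Each distinct n-gram,
keyed by its uppercased lemma string, accumulates

* ``f_T(T_i)`` — its textual frequency: occurrences within document T_i,
* ``f_A``     — its absolute frequency: occurrences over the whole
  corpus, so that f_A = Σ_i f_T(T_i) always holds,

giving the frequency vector F(T) = {f_T(T_1), …, f_T(T_m)} used for
threshold filtering and downstream trend analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from termspectrum.annotate import AnnotatedDocument, Sentence, Token


@dataclass(frozen=True)
class NGramKey:
    n: int
    key: str  # uppercased lemmas joined by single spaces

    def __post_init__(self) -> None:
        if len(self.key.split(" ")) != self.n:
            raise ValueError(f"key {self.key!r} does not have {self.n} parts")

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.key.split(" "))


@dataclass(frozen=True)
class Occurrence:
    doc_id: str
    sentence_index: int
    token_span: tuple[int, int]  # [start, end) indexes into sentence tokens


@dataclass
class TagSummary:
    has_rubbish: bool = False
    oscar: set[str] = field(default_factory=set)
    comp: bool = False
    pos_seq: tuple[str, ...] = ()


@dataclass
class NGramRecord:
    key: NGramKey
    occurrences: list[Occurrence] = field(default_factory=list)
    f_T: dict[str, int] = field(default_factory=dict)
    tag_summary: TagSummary = field(default_factory=TagSummary)

    @property
    def f_A(self) -> int:
        return sum(self.f_T.values())


@dataclass(frozen=True)
class SpectrumConfig:
    n_max: int = 7
    article_skip: frozenset[str] = frozenset({"a", "an", "the"})
    min_f_A: int = 0
    min_f_T: int = 0

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.min_f_A < 0 or self.min_f_T < 0:
            raise ValueError("thresholds must be >= 0")


def _is_window_token(tok: Token, cfg: SpectrumConfig) -> bool | None:
    """True: participates in windows; False: skipped (article);
    None: fences windows (punctuation/symbol tokens)."""
    if not any(c.isalnum() for c in tok.surface):
        return None
    if tok.surface.lower() in cfg.article_skip:
        return False
    return True


def canonical_words(tokens: Iterable[Token]) -> tuple[str, ...]:
    # merged composition tokens carry internal spaces; fold them to "_"
    # so a canonical key always has exactly n space-separated parts
    return tuple((t.lemma or t.surface).upper().replace(" ", "_") for t in tokens)


def extract_ngrams(
    sent: Sentence, n: int, cfg: SpectrumConfig | None = None
) -> list[tuple[tuple[str, ...], Occurrence, list[Token]]]:
    """All n-token windows of one sentence after article omission.

    Returns (canonical words, occurrence, window tokens) triples; the
    occurrence records the original token span (article positions
    included in the span bounds).
    """
    cfg = cfg or SpectrumConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    # segments of participating token indexes, fenced at punctuation
    segments: list[list[int]] = [[]]
    for i, tok in enumerate(sent.tokens):
        status = _is_window_token(tok, cfg)
        if status is None:
            if segments[-1]:
                segments.append([])
        elif status:
            segments[-1].append(i)
    out = []
    for seg in segments:
        for w in range(len(seg) - n + 1):
            idxs = seg[w : w + n]
            toks = [sent.tokens[i] for i in idxs]
            occ = Occurrence(
                doc_id=sent.doc_id,
                sentence_index=sent.index,
                token_span=(idxs[0], idxs[-1] + 1),
            )
            out.append((canonical_words(toks), occ, toks))
    return out


def aggregate(
    docs: list[AnnotatedDocument], cfg: SpectrumConfig | None = None
) -> dict[NGramKey, NGramRecord]:
    """Extract all n-grams (n = 1..n_max) and aggregate their frequencies.

    The tag summary is the union over occurrences for rubbish/oscar/comp
    and the POS sequence of the first occurrence (the canonical one).
    """
    cfg = cfg or SpectrumConfig()
    spectrum: dict[NGramKey, NGramRecord] = {}
    for doc in docs:
        for sent in doc.sentences:
            for n in range(1, cfg.n_max + 1):
                for words, occ, toks in extract_ngrams(sent, n, cfg):
                    key = NGramKey(n=n, key=" ".join(words))
                    rec = spectrum.get(key)
                    if rec is None:
                        rec = NGramRecord(key=key)
                        rec.tag_summary.pos_seq = tuple(t.pos or "" for t in toks)
                        spectrum[key] = rec
                    rec.occurrences.append(occ)
                    rec.f_T[occ.doc_id] = rec.f_T.get(occ.doc_id, 0) + 1
                    ts = rec.tag_summary
                    ts.has_rubbish = ts.has_rubbish or any(t.rubbish for t in toks)
                    ts.comp = ts.comp or any(t.comp for t in toks)
                    ts.oscar.update(t.oscar for t in toks if t.oscar)
    return spectrum


def threshold_filter(
    spectrum: dict[NGramKey, NGramRecord], cfg: SpectrumConfig
) -> dict[NGramKey, NGramRecord]:
    """Drop records below the f_A / max-f_T thresholds (0 = keep all)."""
    return {
        key: rec
        for key, rec in spectrum.items()
        if rec.f_A >= cfg.min_f_A
        and (not rec.f_T or max(rec.f_T.values()) >= cfg.min_f_T)
    }
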