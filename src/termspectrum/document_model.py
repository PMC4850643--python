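"""Document/corpus data model and character-level text normalization.

Raw scientific text arrives with typographic variance that breaks
token-level rules downstream: half a dozen Unicode dashes, curly quotes,
super-/subscript digits, and spaces inserted before crystallographic
surface indexes ("Ru (0001)" for "Ru(0001)").  :func:`normalize_text`
maps all of these onto a single canonical spelling before tokenization.
The maps are explicit codepoint tables so the transformation is auditable
and idempotent.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class ValidationError(ValueError):
    """Raised when an input document or corpus violates its contract."""


@dataclass(frozen=True)
class RawDocument:
    """One input text: a unit T_i of the text set T = {T_1, ..., T_m}."""

    doc_id: str
    body: str
    title: str | None = None
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")
        if not self.body or not self.body.strip():
            raise ValidationError(f"document {self.doc_id!r}: body is empty")


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of documents; ``m`` is the number of texts."""

    documents: tuple[RawDocument, ...]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate doc_id(s): {sorted(dupes)}")

    @property
    def m(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


# --- character unification tables ---------------------------------------

#: every dash/hyphen/minus variant collapses to ASCII "-"
DASH_VARIANTS = {
    "‐",  # hyphen
    "‑",  # non-breaking hyphen
    "‒",  # figure dash
    "–",  # en dash
    "—",  # em dash
    "―",  # horizontal bar
    "−",  # minus sign
    "­",  # soft hyphen
    "﹣",  # small hyphen-minus
    "－",  # fullwidth hyphen-minus
}

#: typographic quotation marks collapse to ASCII '"'
QUOTE_VARIANTS = {
    "‘",  # left single
    "’",  # right single / apostrophe
    "‚",
    "‛",
    "“",  # left double
    "”",  # right double
    "„",
    "‟",
    "′",  # prime
    "″",  # double prime
    "«",  # guillemets
    "»",
    "‹",
    "›",
    "`",  # grave accent used as quote
    "´",  # acute accent used as quote
}

#: super-/subscript digits become plain ASCII digits (H_2_O prints as H₂O)
_SCRIPT_DIGITS = {
    "⁰": "0", "¹": "1", "²": "2", "³": "3",
    "⁴": "4", "⁵": "5", "⁶": "6", "⁷": "7",
    "⁸": "8", "⁹": "9",
    "₀": "0", "₁": "1", "₂": "2", "₃": "3",
    "₄": "4", "₅": "5", "₆": "6", "₇": "7",
    "₈": "8", "₉": "9",
}

_TRANSLATE = {ord(c): "-" for c in DASH_VARIANTS}
_TRANSLATE.update({ord(c): '"' for c in QUOTE_VARIANTS})
_TRANSLATE.update({ord(k): v for k, v in _SCRIPT_DIGITS.items()})

# "Ru (0001)" -> "Ru(0001)": a space before a parenthesized 3-4 digit run
# directly following a letter is a typesetting artifact of crystal indexes.
_CRYSTAL_SPACE = re.compile(r"(?<=[A-Za-z]) +(\(\d{3,4}\))")


def normalize_text(raw: str) -> str:
    """Unify special symbols in ``raw``.  Total and idempotent."""
    text = raw.translate(_TRANSLATE)
    return _CRYSTAL_SPACE.sub(r"\1", text)


# --- corpus I/O ----------------------------------------------------------

def read_documents(path: str | Path, format: str = "plain") -> Corpus:
    """Read a corpus from a ``.txt`` directory/file or a JSON array file.

    Plain format: one document per ``*.txt`` file, ``doc_id`` = file stem.
    JSON format: an array of ``{"doc_id", "title", "body", "meta"}``
    objects (``title``/``meta`` optional).  Documents are ordered by
    ``doc_id`` for stable downstream numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format == "plain":
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        docs = []
        for f in files:
            try:
                body = f.read_text(encoding="utf-8")
            except OSError as exc:
                raise OSError(f"cannot read {f}: {exc}") from exc
            docs.append(RawDocument(doc_id=f.stem, body=body))
    elif format == "json":
        records = json.loads(Path(path).read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise ValidationError("json corpus must be an array of objects")
        docs = []
        for rec in records:
            doc_id = rec.get("doc_id")
            if not doc_id:
                raise ValidationError("json record missing doc_id")
            if "body" not in rec or not str(rec["body"]).strip():
                raise ValidationError(f"json record {doc_id!r} missing body")
            docs.append(
                RawDocument(
                    doc_id=str(doc_id),
                    body=rec["body"],
                    title=rec.get("title"),
                    source_meta=rec.get("meta", {}),
                )
            )
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    if not docs:
        raise ValidationError(f"no documents found under {path}")
    docs.sort(key=lambda d: d.doc_id)
    return Corpus(documents=tuple(docs))


def write_documents(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as the JSON array format (round-trips with read)."""
    records = [
        {"doc_id": d.doc_id, "title": d.title, "body": d.body, "meta": d.source_meta}
        for d in corpus
    ]
    Path(path).write_text(
        json.dumps(records, ensure_ascii=False, indent=1), encoding="utf-8"
    )


def pdf_to_text_stub(path: str | Path) -> str:  # pragma: no cover
    """Placeholder for a PDF ingestion front end.

    Structural analysis of PDFs (title/author/reference block
    classification) is venue-specific and out of scope; plug a converter
    in here and feed its output to :func:`normalize_text`.
    """
    raise NotImplementedError(
        "PDF ingestion is not implemented; convert to plain text or the "
        "JSON document format externally and use read_documents()."
    )
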