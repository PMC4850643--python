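"""Precision / recall / F1 of retrieved term-like phrases vs expert gold lists.

Precision is the fraction of system phrases that coincide with
expert-selected ones, recall the fraction of expert phrases the system
retrieved, F1 their harmonic mean:

    P  = coincidences / n_system
    R  = coincidences / n_gold
    F1 = 2PR / (P + R)

Coincidence is exact equality of canonical phrase strings (uppercased,
plural nouns lemma-folded — the same canonicalization as n-gram keys).
Metrics are kept at full precision internally; display values round
half-up to two decimals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from termspectrum.term_rules import SpectrumEntry


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    phrases: frozenset[str]


@dataclass(frozen=True)
class EvalReport:
    n_system: int
    n_gold: int
    n_coincidences: int
    P: float
    R: float
    F1: float

    def rounded(self, digits: int = 2) -> tuple[float, float, float]:
        """(P, R, F1) rounded half-up to ``digits`` decimals for display."""
        q = Decimal(10) ** -digits
        return tuple(
            float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for v in (self.P, self.R, self.F1)
        )

    def as_dict(self) -> dict:
        p, r, f1 = self.rounded()
        return {
            "n_system": self.n_system,
            "n_gold": self.n_gold,
            "n_coincidences": self.n_coincidences,
            "precision": p,
            "recall": r,
            "f1": f1,
        }


def canonical_phrase(phrase: str) -> str:
    return " ".join(phrase.upper().split())


def count_coincidences(system: set[str], gold: set[str]) -> int:
    """Number of phrases present in both sets (exact canonical match)."""
    return len({canonical_phrase(p) for p in system} & {canonical_phrase(p) for p in gold})


def compute_prf(n_coincidences: int, n_system: int, n_gold: int) -> EvalReport:
    """Build the metric report from raw counts.

    F1 is computed from the unrounded P and R; when P + R = 0, F1 = 0.
    """
    if min(n_coincidences, n_system, n_gold) < 0:
        raise ValueError("counts must be non-negative")
    if n_system == 0 and n_coincidences > 0:
        raise ValueError("coincidences cannot exceed an empty system set")
    if n_coincidences > n_system or n_coincidences > n_gold:
        raise ValueError("coincidences cannot exceed either set size")
    p = n_coincidences / n_system if n_system else 0.0
    r = n_coincidences / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return EvalReport(
        n_system=n_system, n_gold=n_gold, n_coincidences=n_coincidences, P=p, R=r, F1=f1
    )


def read_gold_tsv(path: str | Path) -> dict[str, GoldAnnotation]:
    """Per-document gold phrases from a (doc_id, phrase) TSV; duplicates
    are collapsed so counts refer to unique expert phrases."""
    phrases: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"gold TSV row must be (doc_id, phrase): {row!r}")
            doc_id, phrase = row
            phrases.setdefault(doc_id, set()).add(canonical_phrase(phrase))
    return {
        doc_id: GoldAnnotation(doc_id=doc_id, phrases=frozenset(ps))
        for doc_id, ps in phrases.items()
    }


def evaluate_spectrum(
    entries: list[SpectrumEntry], gold: dict[str, GoldAnnotation]
) -> dict:
    """Compare the term-like spectrum against gold lists.

    Returns a report dict with overall metrics and a per-document
    breakdown (a phrase counts for a document when it occurs there).
    """
    system_all = {e.key.key for e in entries if e.term_like}
    gold_all = set().union(*(g.phrases for g in gold.values())) if gold else set()
    overall = compute_prf(
        count_coincidences(system_all, gold_all), len(system_all), len(gold_all)
    )
    per_doc = {}
    for doc_id, g in sorted(gold.items()):
        system_doc = {
            e.key.key for e in entries if e.term_like and e.f_T.get(doc_id, 0) > 0
        }
        per_doc[doc_id] = compute_prf(
            count_coincidences(system_doc, g.phrases), len(system_doc), len(g.phrases)
        ).as_dict()
    return {"overall": overall.as_dict(), "per_document": per_doc}


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1), encoding="utf-8")
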