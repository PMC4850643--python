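# Methods

This note documents the models, rules and numerical choices behind
`termspectrum`: what each stage assumes, where the design was genuinely open
and which way it was decided, what the synthetic fixtures do and do not show,
and known limitations.

## Scope and assumptions

The package consumes already-extracted plain text (UTF-8) or a simple JSON
document format.  PDF structural analysis — classifying title, author and
reference blocks — is venue-specific, depends on per-conference tuning and is
deliberately not implemented; `document_model.pdf_to_text_stub` marks the
plug-in point.  All downstream stages assume one body string per document and
treat the document set T = {T₁, …, T_m} as the unit over which frequencies
are aggregated.

## Character normalization

Unification maps are explicit codepoint tables (ten dash/hyphen/minus
variants → `-`; sixteen typographic quote variants → `"`; Unicode
super-/subscript digits → ASCII digits), applied via `str.translate`, plus a
single regular expression that removes a space between a letter and a
parenthesized 3–4-digit run (crystal surface indexes, `Ru (0001)` →
`Ru(0001)`).  The full symbol set unified by the original conversion step is
not published anywhere, so the shipped table is a judgment call: it covers
every variant that the rule set downstream is sensitive to.  The
transformation is idempotent by construction (no output character is in any
map's domain), and a property test checks idempotence over arbitrary text.

## Tokenization and merging

The tokenizer never splits on hyphens: hyphen splitting destroys compound
terms ("temperature-programmed").  It does split `/` and `:` into separate
tokens, strips terminal sentence punctuation, quotes and *unbalanced*
brackets into tokens of their own, and keeps balanced bracket expressions
(`Pt(111)`) intact.  A merging pass then reverses the slash/colon splits for
chemistry: a `X / Y` triple merges when both sides are chemical — carrying a
CM tag or parsing (case-sensitively) as an element formula — and a leading
"number" + "%X" pair is absorbed into the following composition.  Merged
tokens get `comp=True` and the CM tag and span the original character range,
so the concatenated character content of a sentence never changes.  The
case-sensitive formula parser is what keeps "water/oil" unmerged while
"Pd/Al2O3" merges.

Sentence boundaries are terminal `.`/`!`/`?` tokens, except directly after a
known abbreviation; the abbreviation inventory is exactly the stop-list
entries that end in a period ("ca.", "fig.", "al.", …).

## Tagging contract and defaults

POS tagging and chemical-entity recognition are pluggable
(`AnnotatorContract`): any callable returning one Penn-Treebank tag per token
and any callable returning an optional CM/RN/ONT tag per token can be
substituted, e.g. wrappers around external engines.  The cascade rules only
consume the tag values, so the contract is the stable surface.

The default POS tagger is a deterministic closed-class table plus suffix
rules (-ing → VBG, -ed → VBN, -ly → RB, adjective suffixes → JJ, plural -s →
NNS, internal capitals or mid-sentence capitalization → NNP, leading digit →
CD, default NN).  It is intentionally desk-scale: adequate for the fixture
corpora and examples, not a general tagger, and statistical taggers will
disagree with it on genuinely ambiguous tokens.  The default chemical
recognizer combines exact element-symbol match (with an ambiguity guard for
symbols that double as English words: In, As, I, He, …), the formula parser,
short all-caps acronyms, reaction-name suffixes (-olysis, -ysis, -oxidation,
-genation, -ylation, -ization → RN), a small ontology word list (glass,
adsorption, cation, … → ONT) and substance-name suffixes (-ene, -ol, -ide,
-ate, -ium, … → CM).  A small gazetteer of multi-word entities exercises tag
propagation: every token of a recognized entity span carries the entity's
tag.  Overlapping entity spans are resolved longest-leftmost; the gazetteer
is scanned in fixed order, so the result is deterministic.

Lemmatization touches plural nouns (NNS/NNPS) only — irregulars table, then
-sses/-xes/-ches/-shes, -ies, -s rules.  Reducing further (gerunds,
derivations) loses domain meaning: "reforming" must not become "reform".

## Strict filtering

Six rules can mark a token rubbish: special symbols outside the allowed set
`. -,/:()[]+=@®{}` (braces are included because Miller indexes are printed
both `Pt(111)` and `Au{111}`; the space character is *not* allowed — merged
composition tokens that contain spaces are exempted by their COMP tag), stop
list, ≥4 consecutive digits, 3 consecutive digits, leading 1–2 digits, and a
measurement-unit suffix.  Digit rules test longest runs first so the 4-digit
rule subsumes the 3-digit rule.  Unit matching is case-insensitive suffix
comparison without a boundary requirement: run-together tokens like
`KJMOL-1` must match the entry `MOL-1`.  The unit lexicon therefore contains
no entries short enough to clip ordinary word endings (no single letters, no
`M`/`G`/`H`).

Eleven exception matchers are checked *before* the rules, in fixed order,
first match wins; exemption is global (an exempt token is never rubbish no
matter which rule would have fired).  Two matchers deserve comment:

* **substances with leading digits** — the regression inventory partitions
  structurally identical tokens into both classes (`2-PROPANOL` filtered,
  `5-PENTANEDIOL` kept); no surface pattern fully separates these, which
  points at an unpublished substance dictionary behind the rule.  The
  implemented matcher requires the `\d{1,2}-` prefix plus a name-class
  suffix (-diol, -ole, -ate, -ose, -amine, -amide, -oxy) and reproduces
  every regression case; it is a heuristic reconstruction, not a substance
  dictionary.
* **structural patterns on chemically tagged tokens** — only fragments of
  a structural pattern list are available; the implemented matcher (tagged
  token containing `-XX` letter pairs or leading `[`) covers the regression
  term examples and is flagged as an approximation.

Diacritic proper names (Brønsted, Mössbauer) are recognized as letters-only
tokens containing a non-ASCII letter, excluding Greek letters — otherwise
thermodynamic symbols like `ΔGADS` would be exempted.

The shipped regression table (`data/regression/strict_filter_cases.tsv`,
127 cases) records token, tags, expected outcome and expected rule/exception
id, and doubles as documentation of every rule and exception.

## The n-gram spectrum

An n-gram is a window of n consecutive tokens within one sentence, advanced
token by token.  Only the articles a/an/the are skipped (the skip list is
configurable); punctuation and symbol tokens *fence* windows — no n-gram
spans a comma, period or stray slash.  This fencing is an interpretation:
genuine term-like phrases do not cross punctuation in practice, and without
it the spectrum fills with fragments of adjacent clauses.  Canonical keys are
uppercased lemmas joined by single spaces; internal spaces of merged
composition tokens are folded to `_` so a key always has exactly n
space-separated parts.

Frequencies: f_T(T_i) counts occurrences within document T_i; f_A = Σ_i
f_T(T_i).  Threshold filtering on f_A and max_i f_T is available but both
thresholds default to 0 (no published values exist; the full spectrum is the
point).

## Accept/reject cascades

Rules run in fixed order per length class; the first that fires decides.

* The dictionary (general-chemistry-term) accept rule precedes the rubbish
  reject rule, so a compendium term survives even when a constituent token
  was rubbish-tagged; this ordering is deliberate.
* The dictionary criterion: an n-gram matches if (a) all its words are words
  of one term, in any order, or (b) n−1 words are exactly the words of an
  (n−1)-word term and the remaining word occurs in some other term.  An
  n-gram that repeats a word never matches (terms do not repeat words), which
  lets the identical-tokens rule claim pairs like "catalyst catalyst".
* POS patterns: for n ≥ 2 a pattern non-match *rejects* (the patterns
  enumerate the permissible structures); only unigrams have a default-accept
  after surviving every rule.
* The n ≥ 3 exception is implemented as first ∈ {VBG, VBN} with second ∈
  {NN, IN, JJ} ("doping …", "used during …" style fragments torn from verbal
  context).  A narrower pair list (VBG→{NN,IN}, VBN→{NN,JJ}) fails to reject
  the canonical filtered examples in the regression table; the implemented
  set rejects all of them.
  The cost is that a prenominal participle reading ("catalyzed oxidation of
  NO") requires the JJ tag for its first word — linguistically standard for
  adjectival participles, and the regression table encodes it that way.
* Multi-token measurement units are detected by joining adjacent word pairs
  (directly and with `/`) before unit suffix matching.

Accepted entries carry `term_like`, plus `general_chem_term` (dictionary
rule), `chem_entity` (any constituent token chemically tagged — the phrase
inherits the tag), and `comp` (contains a merged composition token).

The subsumption filter removes a term-like phrase S when a longer term-like
phrase L contains S's word sequence contiguously with f_A(S) = f_A(L):
equality of absolute frequencies means S never occurs outside L.  Output is
sorted (n, −f_A, key) for reproducible exports; all tie-breaks in the
package are lexicographic.

## Evaluation

P = coincidences/n_system, R = coincidences/n_gold, F₁ = 2PR/(P+R) with
F₁ = 0 when P + R = 0.  Coincidence is exact equality of canonical phrase
strings; no fuzzy or partial-overlap credit.  F₁ is computed from unrounded
P and R; display rounding is half-up to two decimals.  The reference
five-text evaluation reproduces from its raw counts at two decimals for
four texts and the totals; the fifth text's quoted precision (0.50)
disagrees with its own counts (106/215 = 0.493 → 0.49, hence F₁ 0.62 vs
the quoted 0.63) and the tests assert the recomputed values, recording the
discrepancy.

## Synthetic fixtures

`fixtures.generate_fixture_corpus` plants chosen term-like phrases with known
per-document counts inside general-English filler sentences, plus known
rubbish tokens.  Planted phrases sit between commas, which fence extraction
windows, so the phrase forms its own segment: no longer n-gram can swallow
it and the expected f_T/f_A are exact.  Generation is byte-deterministic per
seed.

What passing fixture tests shows: frequency bookkeeping, strict filtering,
cascade decisions and subsumption behave exactly as specified on controlled
input.  What it does not show: tagger accuracy on real prose, recall on
phrase structures outside the template inventory, or robustness to PDF
extraction noise — real-corpus performance depends on the pluggable tagger
and full-size lexicons.

## Lexicon subsets

The shipped dictionaries are curated subsets: ~1300 general-English words
(scientific vocabulary excluded), ~170 general chemistry terms, the full
118-symbol periodic table, ~180 stable isotopes, ~40 stop-list entries and
~35 measurement units.  They cover every token the rule set and regression
tables reference.  Full-size lists (tens of thousands of English words,
thousands of compendium terms) are drop-in replaceable files with the same
names; results on real corpora will depend on that coverage, most visibly
the general-English reject rule for unigrams.

## Known limitations

* The default POS tagger is rule-based and desk-scale; POS-pattern decisions
  on real text inherit its errors.  The contract makes swapping in a
  statistical tagger trivial.
* The strict-filter exceptions for digit-prefixed substances and for tagged
  structural tokens are reconstructions of partially published patterns.
* Sentence splitting relies on the abbreviation inventory of the stop list;
  unseen abbreviations ("approx.") split sentences early.
* Corpus-scale statistics (millions of n-grams) are computed with plain
  Python dictionaries; the design favours auditability over throughput.
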