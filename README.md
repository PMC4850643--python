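# termspectrum

Rule-based extraction of a **terminology spectrum** — the indexed list of all
term-like phrases, general chemistry terms and chemical entities — from
collections of natural-language chemistry text (conference abstracts, papers),
with frequency weights per phrase and a precision/recall/F₁ evaluation harness
against expert-selected gold phrase lists.

A *term-like phrase* is one or more consecutive tokens that convey a specific
scientific meaning with unchanged spelling, as actually used in the text —
deliberately broader than thesaurus terms or top-k keyphrases.  The package
retrieves **all** such phrases rather than a ranked shortlist, which makes the
output usable for term indexing, trend analysis over conference years and
document-similarity work in cheminformatics.

## Method

The pipeline runs five deterministic stages over each document:

1. **Normalization** — dash/quote variants, super-/subscript digits and
   crystal-index spacing (`Ru (0001)` → `Ru(0001)`) are unified.
2. **Chemical-aware annotation** — tokenization that never splits hyphens,
   re-merging of slash/colon-separated composition tokens
   (`2.7 %CO/10.0 %H2O/He` becomes one token with a `COMP` tag), sentence
   splitting, Penn-Treebank POS tags, plural-noun-only lemmatization and
   chemical-entity tags (`CM` chemical matter, `RN` reaction, `ONT` ontology
   term).  The POS tagger and chemical recognizer are pluggable; deterministic
   rule/lexicon defaults ship with the package.
3. **Strict filtering** — six rules mark tokens that can never belong to a
   term (stray symbols, stop-list words, digit runs, measurement-unit tails)
   unless one of eleven exceptions protects legitimate chemistry:
   facet/Miller indexes `Pt(111)`, isotopes `13C`, digit-prefixed substances
   `5-PENTANEDIOL`, catalyst compositions `1.5Au/C`, crystalline hydrates,
   `2D-SAXS`-style method names, diacritic proper names (`Brønsted`), …
4. **n-gram spectrum** — all within-sentence token windows for n = 1..7
   (articles skipped, punctuation fences windows), aggregated into canonical
   uppercase-lemma keys with textual frequency f_T(T_i) per document and
   absolute frequency f_A = Σ_i f_T(T_i).
5. **Accept/reject cascades** — per length class, rules applied in fixed
   order (dictionary term ▸ rubbish ▸ short/identical tokens ▸ units ▸
   POS-pattern with exceptions), then a subsumption filter removes a shorter
   term-like phrase contained in an equally frequent longer one.

Evaluation uses `P = coincidences / n_system`, `R = coincidences / n_gold`,
`F1 = 2PR/(P+R)` over canonical phrase strings.

## Worked example

```python
from termspectrum import (
    Corpus, RawDocument, SpectrumConfig, annotate_corpus,
    build_spectrum, load_default_lexicons, tag_corpus_rubbish,
)

corpus = Corpus((
    RawDocument("abs1", "Raman spectroscopy of the supported MgO catalyst "
                        "showed a radial concentration gradient. "
                        "The supported MgO powder gave 2.7 %CO/10.0 %H2O/He flow."),
    RawDocument("abs2", "A radial concentration gradient appeared again, "
                        "and Raman spectroscopy confirmed it."),
))
lex = load_default_lexicons()
docs = tag_corpus_rubbish(annotate_corpus(corpus), lex)
for e in build_spectrum(docs, lex, SpectrumConfig()):
    print(f"n={e.key.n}  {e.key.key:44s} f_A={e.f_A}  f_T={e.f_T}  "
          f"tags={','.join(sorted(e.tags))}")
```

prints

```
n=1  2.7_%CO/10.0_%H2O/HE                         f_A=1  f_T={'abs1': 1}  tags=chem_entity,comp,term_like
n=2  RAMAN SPECTROSCOPY                           f_A=2  f_T={'abs1': 1, 'abs2': 1}  tags=term_like
n=2  SUPPORTED MGO                                f_A=2  f_T={'abs1': 2}  tags=chem_entity,term_like
n=3  RADIAL CONCENTRATION GRADIENT                f_A=2  f_T={'abs1': 1, 'abs2': 1}  tags=general_chem_term,term_like
n=4  SUPPORTED MGO POWDER GAVE                    f_A=1  f_T={'abs1': 1}  tags=chem_entity,term_like
n=5  RADIAL CONCENTRATION GRADIENT APPEARED AGAIN f_A=1  f_T={'abs2': 1}  tags=term_like
n=6  RAMAN SPECTROSCOPY OF SUPPORTED MGO CATALYST f_A=1  f_T={'abs1': 1}  tags=chem_entity,term_like
n=7  SUPPORTED MGO CATALYST SHOWED RADIAL CONCENTRATION GRADIENT f_A=1  f_T={'abs1': 1}  tags=chem_entity,term_like
```

Reading the output: the merged composition token survives strict filtering
through its `COMP` exception and is accepted as a chemical unigram;
`RADIAL CONCENTRATION GRADIENT` is recognized as a *general chemistry term*
because "concentration gradient" is a dictionary term and "radial" occurs in
another dictionary term; phrases inheriting a chemical tag from any
constituent token carry `chem_entity`.  Unigrams such as `RAMAN` or `MGO` were
removed by the subsumption filter because they only occur inside longer,
equally frequent term-like phrases.

The same pipeline is available from the shell:

```bash
termspectrum fixtures --seed 5 --out-dir corpus/      # synthetic demo corpus
termspectrum build --input corpus/ --out spectrum.tsv
termspectrum eval --spectrum spectrum.tsv --gold gold.tsv --report report.json
```

## Lexicons

Six dictionaries drive recognition (general English words with scientific
vocabulary excluded, general chemistry terms, stop list, stable isotopes,
element symbols, measurement units).  The shipped files under
`src/termspectrum/data/lexicons/` are curated subsets sufficient for the rule
set and tests; each is a plain one-entry-per-line UTF-8 file and can be
replaced wholesale with a full-size list (`--lexicons DIR`).

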