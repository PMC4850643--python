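# Stop list: words/abbreviations that can never be part of a term-like
# phrase.  Entries ending in "." double as non-boundary abbreviations for
# sentence splitting.
literature
viewpoint
percent
present
importance
fundamental
conclusion
typically
example
introduction
abstract
acknowledgement
acknowledgements
references
keywords
de
ca.
fig.
figs.
al.
co-exist
et
etc.
i.e.
e.g.
vs.
resp.
ref.
refs.
ltd
inc.
cf.
viz.
ibid.
anyway
moreover
nevertheless
furthermore
whatever
whereas
hereby
thereof
therein
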