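"""Parse Oracc-style tokens and filter a small corpus by metadata tags.

Tokens use the ``lemma[guideword]EPOS`` notation; ``_`` marks a broken or
unlemmatizable sign.  Documents carry language and period tags used to select
the analysis corpus.
"""

import io

from emobody import filter_corpus, parse_token, read_corpus

tok = parse_token("ezēzu[be(come)-angry]V")
print(f"lemma={tok.lemma!r} guideword={tok.guideword!r} epos={tok.epos!r}")
print("round-trips:", tok.key() == "ezēzu[be(come)-angry]V")
print("broken sign:", parse_token("_").is_empty)

docs = [
    "#id: tablet1\n#language: Akkadian\n#period: Neo-Assyrian\n"
    "libbu[interior]N _ ḫadû[be(come)-joyful]V",
    "#id: tablet2\n#language: Sumerian\n#period: Ur III\n"
    "a[x]N b[y]V",
]
corpus = read_corpus([io.StringIO(d) for d in docs])
print(f"\nread {len(corpus)} documents, {corpus.token_count} tokens")

kept = filter_corpus(corpus, languages=["Akkadian"], periods=["Neo-Assyrian"])
print(f"after tag filtering: {len(kept)} document(s):",
      [d.id for d in kept])
# The filter keeps exactly the documents whose language AND period tags match;
# tablet2 (Sumerian, Ur III) is dropped.
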