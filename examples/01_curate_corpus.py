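"""Curate a SMILES corpus: canonicalize, filter, deduplicate, blocklist.

Builds a small synthetic corpus, injects a few records that violate the
curation rules, and shows the per-rule removal report.
"""

from gruchem.corpus import CurationReport, build_vocabulary, canonicalize, filter_corpus
from gruchem.synthdata import CorpusSpec, gen_corpus

corpus = gen_corpus(CorpusSpec(n=200, seed=1))
# pollute it: an unparseable string, a too-small molecule, a duplicate,
# and a molecule we will blocklist (e.g. a known active held out of training)
blocked = corpus[0].canonical
polluted = corpus + [
    canonicalize("C("),          # invalid -> dropped
    canonicalize("CCO"),         # 3 heavy atoms -> below the 10-atom floor
    canonicalize(corpus[1].raw), # duplicate -> dropped
]

report = CurationReport()
kept = filter_corpus(polluted, blocklist=[blocked], report=report)
vocab = build_vocabulary(kept)

print(report.to_json())
print(f"kept {len(kept)} molecules; vocabulary of {len(vocab)} tokens")
# The report counts why each record was removed: 1 invalid, 1 outside the
# 10-100 heavy-atom window, 1 duplicate canonical string, 1 blocklisted.
# Every kept molecule tokenizes with the printed vocabulary and round-trips
# encode -> decode exactly.
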