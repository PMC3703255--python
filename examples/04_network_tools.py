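"""Corpus-level reports: statistics, dead-end metabolites, metabolite fate."""

import json

from pathcards import (
    corpus_stats,
    dead_end_metabolites,
    metabolite_fate,
    paper_fixtures,
)

corpus = paper_fixtures()["arginase"]

print(corpus_stats(corpus).to_string(index=False))
# One row per database with distinct gene / EC / reaction / pathway counts.

for db in corpus.db_names():
    for rep in dead_end_metabolites(corpus, db):
        print(db, rep.metabolite_class, rep.status, rep.witness_reactions)
# In this tiny corpus every non-currency metabolite is a dead-end:
# l-arginine is only consumed, ornithine and urea only produced.  Water is
# not reported -- currency species are excluded by default.

print(json.dumps(metabolite_fate(corpus, "urea"), indent=2))
# Per database: the reactions urea participates in, plus its dead-end flag.
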