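"""Query a reaction across databases with a mismatch budget.

Builds the two-database arginine-hydrolysis corpus, in which one database
writes the product as generic 'ornithine' and the other as 'l-ornithine'
under a different compound identifier, then asks for the reaction while
allowing one mismatched metabolite.
"""

from pathcards import paper_fixtures, reaction_card, render_card

corpus = paper_fixtures()["arginase"]
card = reaction_card(
    corpus, "l-arginine + H2O -> ornithine + urea", mismatch_budget=1
)
print(render_card(card, "tsv"))

# The 100-rows are exact matches to the query; the 66-rows match on 2 of 3
# non-currency metabolites (l-ornithine sits in a different identity class
# than ornithine), yet agree on EC number and genes -- a granularity
# conflict, not a biological disagreement.
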