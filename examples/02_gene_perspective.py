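"""Gene-perspective card: which functions do databases give one gene?

The CTP-synthase corpus encodes a classic protonation conflict: two
databases use ammonia (NH3), another uses ammonium, so the amine-dependent
reactions never match at the reaction level -- but the gene perspective
lists them side by side.
"""

from pathcards import gene_card, paper_fixtures, render_card

corpus = paper_fixtures()["ctps"]
card = gene_card(corpus, "CTPS")
print(render_card(card, "tsv"))

# Expect 2 reactions for EHMN and KEGG, 1 glutamine-dependent reaction for
# Reactome and HumanCyc, and 1 ammonium-dependent reaction for Recon1.
# In the similarity section, the four glutamine-dependent variants score
# 100 against each other; the ammonia vs ammonium variants only 83.
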