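"""EC-number perspective: consensus reactions and alternative substrates.

Succinate-CoA ligase (EC 6.2.1.4): all five databases agree on the
GDP-forming reaction, but two also include an IDP/ITP variant.  The
second part relaxes the fourth EC component to pull in sibling
activities that different databases assigned to the same conversion.
"""

from pathcards import ec_card, paper_fixtures, render_card

fixtures = paper_fixtures()

card = ec_card(fixtures["succinate_coa_ligase"], "6.2.1.4")
print(render_card(card, "tsv"))
# 7 rows: the consensus reaction in 5 databases plus the ITP variant in 2.

relaxed = ec_card(fixtures["cmpk1_ec"], "2.7.4.14", fourth_wildcard=True)
print(render_card(relaxed, "tsv"))
# One identical phosphotransfer reaction carrying three different EC
# numbers (2.7.4.4 / 2.7.4.14 / 2.7.4.22): the wildcard query reveals the
# disagreement that a literal EC match would hide.
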