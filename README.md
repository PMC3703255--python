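# pathcards

Cross-database consensus and conflict overviews for metabolic networks.

The metabolic network of a well-studied organism is typically described in
several independently curated pathway databases (for human: EHMN, Recon 1,
HumanCyc, and the metabolic subsets of KEGG and Reactome), and those
descriptions agree far less than one would hope.  Some disagreements are
real biology (a gene linked to different reactions, an extra substrate),
others are representational: different metabolite granularity (ornithine
vs l-ornithine), different protonation states (ammonia vs ammonium),
one-step versus two-step descriptions of the same conversion.
`pathcards` is for curators and modellers who need to see — per gene, per
EC number, or per reaction — exactly where the databases agree and where
they do not, before merging their content into a consensus reconstruction.

## What it computes

Given a *corpus* (one TSV interchange directory per source database),
the library:

1. **Resolves entity identity across databases.**  Genes match on Entrez
   and/or Ensembl ids, with HGNC symbols bridging records that share no
   genome database.  Metabolites match primarily on the KEGG Compound id,
   then on KEGG Glycan / ChEBI / PubChem Compound / CAS, then by
   normalized name backed by an H-insensitive chemical-formula
   comparison.  Pairwise matches are closed transitively: if A~B and B~C
   then A~C.  EC numbers compare literally — an unassigned `-` component
   is never a wildcard.
2. **Scores reaction agreement.**  Each reaction is reduced to its
   per-side sets of metabolite identity classes, with currency species
   (e⁻, H⁺, H₂O) excluded, and pairs are scored side-respecting but
   direction-ignoring:

   ```
   overlap % = matching metabolites / max(|R1|, |R2|) × 100
   ```

   Displayed values are floored integers (2 of 3 → 66); reactions at
   exactly 100% merge into exact-match classes.
3. **Assembles cards.**  A card is centered at a gene, an EC number, or a
   reaction and lists one row per (reaction, pathway, database) with that
   database's EC numbers, Boolean gene association (`or` = isozymes,
   parenthesized `and` = complexes, commas = unstated semantics) and
   pathway, plus overlap annotations and identifier panels.
4. **Runs network utilities.**  Metabolite fate, per-database dead-end
   detection, gene/metabolite–pathway membership tables, content
   statistics and cross-database presence matrices.

A synthetic-corpus generator (`pathcards.fixtures`) replicates a base
network across databases and injects the conflict classes above at
configurable rates, returning the ground-truth classes for recovery
checks; six hand-coded mini-corpora encode the canonical case studies.

## Worked example

```python
from pathcards import paper_fixtures, reaction_card, render_card

corpus = paper_fixtures()["arginase"]
card = reaction_card(corpus, "l-arginine + H2O -> ornithine + urea",
                     mismatch_budget=1)
print(render_card(card, "tsv"))
```

```
Database	Reaction	Overlap(%)	EC number	Gene(s)	Pathway
Reactome	l-arginine[c] + water[c] → l-ornithine[c] + urea[c]	66	3.5.3.1	ARG1	Urea Cycle
Reactome	l-arginine[m] + water[m] → l-ornithine[m] + urea[m]	66	3.5.3.1	ARG2	Urea Cycle
Recon1	l-arginine[c] + H2O[c] → ornithine[c] + urea[c]	100	3.5.3.1	ARG1	Urea cycle / amino group metabolism
Recon1	l-arginine[m] + H2O[m] → ornithine[m] + urea[m]	100	3.5.3.1	ARG2	Urea cycle / amino group metabolism
```

The 100-rows match the query on all three non-currency metabolites
(water is excluded); the 66-rows match on 2 of 3 because `l-ornithine`
carries a different compound identifier and name than generic
`ornithine`.  Since EC number and genes agree, the 66 flags a
representational granularity difference rather than a biological
conflict.  The `examples/` directory holds one short script per
capability (gene and EC perspectives, network tools, synthetic-corpus
recovery).

## Command line

The same operations are exposed as a thin CLI:

```sh
pathcards fixtures paper --name arginase --out corpus/
pathcards ingest corpus/
pathcards card reaction "l-arginine + H2O -> ornithine + urea" \
    --corpus corpus/ --mismatches 1
pathcards tools deadends --corpus corpus/
pathcards tools export-all --corpus corpus/ --out cards/
```

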