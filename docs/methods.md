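# Methods

## Problem setting

Several pathway databases describe the metabolic network of the same
organism, each with its own identifier vocabulary, naming conventions,
protonation conventions and granularity choices.  `pathcards` harmonizes
such descriptions far enough to *quantify* their agreement without ever
merging them: every statement a source database makes is preserved and
attributed, and consensus/conflict is reported, not resolved.  The unit
of reporting is the card — a per-gene, per-EC-number or per-reaction
table with one row per (reaction, pathway, database).

## Identity model

**Genes.**  Two gene records match iff they carry equal Entrez ids, or
equal Ensembl ids, or — only when the two records share neither
namespace (no both-present Entrez pair and no both-present Ensembl
pair) — their HGNC symbol sets intersect.  The HGNC fallback is
deliberately restricted: a shared symbol must never override an explicit
identifier disagreement.  UniProt ids are stored for display but not
matched on; in the source databases they serve to retrieve the genome
ids upstream, not as an independent identity axis.

**Metabolites.**  A three-step cascade:

1. If both records carry a (non-obsolete) KEGG Compound id, that id
   decides and the cascade stops.  A KEGG Compound conflict therefore
   vetoes all other evidence; requiring *both* sides prevents a merely
   absent id from vetoing anything.
2. Otherwise any of KEGG Glycan, ChEBI, PubChem Compound, or CAS present
   in both and equal is a match.  If ids are present but all unequal the
   cascade still proceeds — the secondary namespaces have or-semantics
   with the name rule.
3. Otherwise a name collision counts: any name or synonym of one record
   equals (case-insensitively, ignoring all non-alphanumeric characters)
   any name or synonym of the other, **and** both chemical formulas
   parse and match.  Formula comparison ignores hydrogen counts, because
   databases state metabolites at different pH and are inconsistently
   balanced for protons.  A missing or unparseable formula (polymer
   notation, R-groups) blocks name-based matching entirely.

PubChem Substance ids are depositor-specific and never used for
matching; a CID–SID table can add the corresponding Compound ids.
Identifier-update tables transfer stale ids/ECs to current values
(flagged `transferred`, previous value retained) or flag them `obsolete`,
which removes them from every matching step.

**EC numbers** compare literally on all four components; `2.4.2.-` never
matches `2.4.2.1`.  Incomplete ECs are ambiguous (not-yet-assigned vs
not-assignable), so wildcard semantics would manufacture matches.  A
separate *family* rule compares only the first three components — the
fourth merely enumerates substrate specificities — and backs the
optional widened EC-card query.

**Transitive closure.**  Each pairwise rule induces a match graph whose
connected components are the identity classes (via networkx; tests
verify against an independent BFS oracle).  Class ids are the
lexicographically smallest member key, so all outputs are deterministic.
The closure runs over all records including same-database pairs; a
database that contains duplicates will see them merged into one class,
which is itself a curation signal.

## Reaction similarity

A reaction's *signature* is its pair of per-side metabolite-class sets
after removing currency classes (seeded from names/ids of e⁻, H⁺, H₂O;
extensible).  Stoichiometric coefficients, compartments and duplicate
participants are all ignored — the comparison counts metabolites, not
molecules.  Two signatures are scored

    percent = matches / max(size1, size2) × 100,

with `matches` maximized over the parallel (L·L + R·R) and antiparallel
(L·R + R·L) side pairings so that direction conventions cannot cause
spurious mismatches.  Internal percentages are exact rationals; display
values are floored to integers, fixed by the 2-of-3 ⇒ 66 convention.
Two empty signatures score 0, not 100: degenerate reactions must not
cluster.  The mismatch count of a pair is `max(size1, size2) − matches`,
which is 0 exactly when the overlap is 100; queries accept a mismatch
budget and are monotone in it.  Reactions join an exact-match class only
at precisely 100% overlap — partial overlaps are reported on cards but
never merged.

The per-side counting convention means a metabolite appearing on both
sides of both reactions contributes to the match count once per side.

## Cards

Rows are ordered by database name, then reaction local id, then pathway
name; a reaction in *k* pathways yields *k* rows and missing elements
render as an em dash.  Gene associations render with HGNC display
symbols (multiple symbols joined by `__`; fallback Entrez → Ensembl →
local id), isozymes as `A or B`, complexes as `(A and B)`, and unstated
semantics (databases with no Boolean syntax) as comma lists.  Directions
render `→`, `<==>`, and `|==|` for unknown.  Gene and EC cards attach an
all-pairs similarity table over their rows; reaction cards annotate each
row with its overlap against the focus.  Gene queries resolving to
several identity classes raise an explicit disambiguation error rather
than picking silently.  Source links are produced from configurable
per-database URL templates, defaulting to opaque `db:id` text.  The JSON
card schema is versioned and reserves an `extensions` field for
downstream annotation systems.

## Network utilities

Dead-end status (only-produced / only-consumed) is computed per database
over metabolite *classes*, so synonym records cannot split a
metabolite's production from its consumption.  Reversible and
unknown-direction reactions count as both producing and consuming every
participant — absence of direction evidence should not create dead-ends.
The currency exclusion applies by default (water is not a meaningful
dead-end) and can be switched off; both modes are exposed because the
right choice depends on the downstream gap-filling question.

## Interchange format and determinism

A corpus is a directory of per-database TSV tables (UTF-8, header row,
empty string = absent); records are written sorted by (database, local
id), making exports byte-stable and write→read a record-identical round
trip.  Status flags from identifier updates persist in dedicated
columns.  Update tables must be pre-flattened; chains (a→b→c) are
rejected at load so application is single-pass and idempotent.

## Synthetic corpora

The generator replicates a base network — a linear chain of metabolites
with ~30% branching back to earlier nodes, ~30% of reactions carrying a
water participant, ~30% reversible — across up to five databases, then
injects conflicts per reaction at the configured rates: granularity
splits (a database-private intermediate turns one step into two),
protonation variants (disjoint ids, new name, formula ±1 H), alternative
co-substrates (an extra variant reaction in two databases), missing
genes, isozyme-vs-complex divergence, identifier sparsity and
synonym-only naming.  Defaults (5 databases, 12 reactions, all rates 0)
model the idealized case of perfectly concordant curation; rates are the
experiment dial and all randomness flows from one `random.Random(seed)`,
so equal configs produce byte-identical corpora.

What the generator does *not* emulate: genome-scale size and topology,
realistic stoichiometry, compartments with biological meaning, partial
identifier vocabularies that differ systematically per database, or
correlated curation errors.  Passing recovery tests therefore shows the
identity and comparison machinery is correct under the stated conflict
model, not that real databases would be resolved at any particular rate.

Six hand-coded mini-corpora encode canonical conflict patterns at the
scale of a handful of reactions (ornithine granularity, ammonia/ammonium
protonation, EC disagreement on one conversion, one-vs-two-step
descriptions, IDP/ITP alternative substrates, and a five-way EC/gene
disagreement with a missing gene).  They are fixtures *and* documentation:
each is asserted against the exact card structure it should produce.

## Numerical and design choices

- Exact `Fraction` arithmetic for percentages; floor for display.  The
  behaviour at exact halves is thereby fixed (66.5 → 66) and documented
  rather than left to float rounding.
- Name normalization treats every non-alphanumeric character as
  punctuation (dashes, commas, parentheses, primes, Greek-letter
  prefixes survive as their alphanumeric parts).
- Formula parsing accepts Hill-style element–count tokens and strips
  trailing charge tokens, both attached (`NH4+`, `CHO2-`) and
  space-separated (`HPO4 2-`); anything else (polymers, R-groups as part
  of larger tokens) is unparseable and never matches.  A lone `R` does
  parse as a pseudo-element — harmless, since it can only match another
  lone `R`.
- Query signatures resolve terms by normalized name/synonym, external id
  value, or explicit `db:local_id`; side-free queries match term sets
  against the union of both reaction sides.
- Multi-compartment duplicates (same chemistry, different compartment)
  are distinct records; they naturally land in the same exact-match
  class because compartments never enter signatures.
- Problem sizes in the test suite (10⁴ random signature pairs, 100
  random match graphs, 100 random corpora of 1–3 databases × 3–10
  reactions) were chosen to exercise the combinatorics thoroughly while
  keeping the default suite fast on one CPU.

## Known limitations

- Pairwise matching is O(n²) per entity kind; adequate for corpora of
  thousands of records, not for millions.  Blocking on match keys would
  be the natural next step.
- No structure-based metabolite matching: InChI/SMILES are stored and
  displayed, never compared.  Likewise no fuzzy name similarity — both
  would trade precision for recall in ways a curator should opt into.
- No mass-balance checking, atom mapping, compartment-aware matching, or
  gap-filling; the dead-end reports are pointers for manual curation,
  not an automated repair tool.
- Native database dumps (BioPAX, KGML, BioCyc flat files, SBML) are out
  of scope; converting them into the TSV interchange format is the
  user's (scriptable) responsibility.
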