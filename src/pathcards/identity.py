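"""Cross-database entity resolution for genes, metabolites and EC numbers.

Independently curated pathway databases rarely agree on identifiers, so
records are matched by a cascade of rules and then merged into equivalence
classes by transitive closure: if database A matches B (say on an Entrez
id) and B matches C (say on an Ensembl id), then A matches C as well.

Matching rules, in brief:

- **Genes** match on equal Entrez or equal Ensembl ids; records that share
  no genome-database namespace may still match via a common HGNC symbol.
- **Metabolites** match primarily on the KEGG Compound id.  When that id is
  not available on both sides, any of four secondary identifiers (KEGG
  Glycan, ChEBI, PubChem Compound, CAS) decides, and failing those a
  case/punctuation-insensitive name match backed by an H-insensitive
  chemical-formula comparison.  Reactions are inconsistently balanced for
  protons across databases (curated at different pH), hence the hydrogen
  allowance.
- **EC numbers** compare literally; an unassigned ``-`` component is never
  a wildcard.  A separate family rule compares only the first three
  components, since the fourth merely enumerates substrate specificities.

Obsolete-flagged identifiers are excluded from every rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx

from .model import ECNumber, GeneRecord, MetaboliteRecord

__all__ = [
    "normalize_name",
    "parse_formula",
    "formulas_match",
    "metabolite_pair_match",
    "gene_pair_match",
    "ec_equal",
    "ec_family_equal",
    "EquivalenceClasses",
    "build_equivalence",
    "metabolite_classes",
    "gene_classes",
]

Key = tuple[str, str]

# Secondary identifier namespaces tried when KEGG Compound is unavailable.
SECONDARY_NAMESPACES = ("kegg_glycan", "chebi", "pubchem_compound", "cas")

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize_name(name: str) -> str:
    """Casefold and strip everything that is not a letter or digit.

    Name comparison is case-insensitive and ignores spaces and punctuation
    (dashes, commas, parentheses, primes, ...).  Idempotent and total.
    """
    return _NON_ALNUM.sub("", name.casefold())


# ---------------------------------------------------------------------------
# Chemical formulas

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# charge tokens: space-separated ("HPO4 2-") or sign-led suffix ("NH4+",
# "CHO2-", "Fe+3"); a bare trailing digit belongs to the last element count
_CHARGE_SEPARATED_RE = re.compile(r"\s+\d*[+-]\d*$")
_CHARGE_ATTACHED_RE = re.compile(r"[+-]\d*$")


def parse_formula(text: Optional[str]) -> Optional[dict[str, int]]:
    """Parse a Hill-style formula into element counts.

    Trailing charge tokens (``+``, ``-``, ``2-``, ``+2``) are stripped.
    Returns ``None`` for formulas outside the grammar (polymer notation
    like ``(C5H8)n``, R-groups, ...); an unparseable formula never
    satisfies a formula match.
    """
    if text is None:
        return None
    s = text.strip()
    if not s:
        return None
    s = _CHARGE_SEPARATED_RE.sub("", s)
    s = _CHARGE_ATTACHED_RE.sub("", s)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _ELEMENT_RE.match(s, pos)
        if not m or m.start() != pos or not m.group(1):
            return None
        element, digits = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts or None


def formulas_match(f1: Optional[dict[str, int]], f2: Optional[dict[str, int]]) -> bool:
    """Element counts equal for every element except hydrogen.

    Databases state metabolites at different protonation states, so a
    difference in the number of H atoms is ignored.  Unparseable formulas
    (``None``) never match.
    """
    if f1 is None or f2 is None:
        return False
    a = {e: n for e, n in f1.items() if e != "H"}
    b = {e: n for e, n in f2.items() if e != "H"}
    return a == b


# ---------------------------------------------------------------------------
# Pairwise rules


def metabolite_pair_match(m1: MetaboliteRecord, m2: MetaboliteRecord) -> bool:
    """Decision cascade for metabolite identity across databases.

    1. If both records carry a (non-obsolete) KEGG Compound id, that id
       decides and the cascade stops — a KEGG Compound disagreement cannot
       be overridden by any other evidence.
    2. Otherwise any secondary id (KEGG Glycan, ChEBI, PubChem Compound,
       CAS) present in both and equal produces a match.
    3. Otherwise a normalized name/synonym collision counts, but only when
       both formulas parse and match (H-insensitively).

    PubChem Substance ids are depositor-specific and never consulted.
    """
    k1 = m1.usable_id("kegg_compound")
    k2 = m2.usable_id("kegg_compound")
    if k1 and k2:
        return k1 == k2
    for ns in SECONDARY_NAMESPACES:
        v1 = m1.usable_id(ns)
        v2 = m2.usable_id(ns)
        if v1 and v2 and v1 == v2:
            return True
    names1 = {normalize_name(n) for n in m1.all_names()} - {""}
    names2 = {normalize_name(n) for n in m2.all_names()} - {""}
    if names1 & names2:
        return formulas_match(
            parse_formula(m1.chemical_formula), parse_formula(m2.chemical_formula)
        )
    return False


def gene_pair_match(g1: GeneRecord, g2: GeneRecord) -> bool:
    """Genes match on Entrez and/or Ensembl id; records linked to neither
    common genome database may match via a shared HGNC symbol."""
    e1, e2 = g1.usable_id("entrez"), g2.usable_id("entrez")
    if e1 and e2 and e1 == e2:
        return True
    n1, n2 = g1.usable_id("ensembl"), g2.usable_id("ensembl")
    if n1 and n2 and n1 == n2:
        return True
    shares_namespace = (e1 and e2) or (n1 and n2)
    if not shares_namespace and (g1.hgnc_symbols & g2.hgnc_symbols):
        return True
    return False


def ec_equal(e1: ECNumber, e2: ECNumber) -> bool:
    """Literal four-component equality; ``-`` is not a wildcard."""
    return e1 == e2


def ec_family_equal(e1: ECNumber, e2: ECNumber) -> bool:
    """Equality on the first three components (sub-subclass level).

    The fourth component only distinguishes substrate specificities, so a
    relaxed query may ignore it.  Requires the first three components of
    both numbers to be assigned."""
    a = (e1.c1, e1.c2, e1.c3)
    b = (e2.c1, e2.c2, e2.c3)
    if None in a or None in b:
        return False
    return a == b


# ---------------------------------------------------------------------------
# Transitive closure


@dataclass
class EquivalenceClasses:
    """Partition of entity records into cross-database identity classes.

    ``class_of`` maps each record key ``(source_db, local_id)`` to its class
    id; ``members`` maps class ids to frozen member sets.  Class ids are the
    ``"db:local_id"`` rendering of the lexicographically smallest member, so
    output is deterministic.
    """

    kind: str
    class_of: dict[Key, str] = field(default_factory=dict)
    members: dict[str, frozenset[Key]] = field(default_factory=dict)

    def class_members(self, key: Key) -> frozenset[Key]:
        return self.members[self.class_of[key]]

    def same_class(self, k1: Key, k2: Key) -> bool:
        return self.class_of[k1] == self.class_of[k2]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"kind": self.kind, "class_id": cid, "source_db": db, "local_id": lid}
            for cid in sorted(self.members)
            for (db, lid) in sorted(self.members[cid])
        ]
        return pd.DataFrame(rows, columns=["kind", "class_id", "source_db", "local_id"])


def class_id_for(members: Iterable[Key]) -> str:
    db, lid = min(members)
    return f"{db}:{lid}"


def build_equivalence(
    records: Sequence,
    pair_rule: Callable,
    kind: str = "entity",
) -> EquivalenceClasses:
    """Connected components of the pairwise match graph.

    ``pair_rule`` must be symmetric.  Every record lands in exactly one
    class; unmatched records form singletons.  The closure is idempotent:
    re-running it on its own classes changes nothing.
    """
    graph = nx.Graph()
    recs = list(records)
    for r in recs:
        graph.add_node(r.key)
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            if pair_rule(a, b):
                graph.add_edge(a.key, b.key)
    eq = EquivalenceClasses(kind=kind)
    for component in nx.connected_components(graph):
        cid = class_id_for(component)
        eq.members[cid] = frozenset(component)
        for key in component:
            eq.class_of[key] = cid
    return eq


def metabolite_classes(corpus) -> EquivalenceClasses:
    """Corpus-level metabolite identity classes (cached on the corpus)."""
    cached = corpus.cache_get("metabolite_classes")
    if cached is None:
        cached = build_equivalence(
            list(corpus.iter_metabolites()), metabolite_pair_match, kind="metabolite"
        )
        corpus.cache_set("metabolite_classes", cached)
    return cached


def gene_classes(corpus) -> EquivalenceClasses:
    """Corpus-level gene identity classes (cached on the corpus)."""
    cached = corpus.cache_get("gene_classes")
    if cached is None:
        cached = build_equivalence(
            list(corpus.iter_genes()), gene_pair_match, kind="gene"
        )
        corpus.cache_set("gene_classes", cached)
    return cached
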