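"""Reaction signatures and the percentage-of-overlap similarity.

A reaction is reduced to its *signature*: the set of metabolite identity
classes on each side, with currency species (electrons, protons, water)
removed — reactions are not consistently balanced for those across
databases.  Two signatures are compared side-respecting but
direction-ignoring:

    overlap % = matching metabolites / max(|R1|, |R2|) x 100

where the matching count is maximized over the parallel (left-left,
right-right) and antiparallel (left-right, right-left) orientations, so
that two databases writing the same conversion in opposite directions
still score 100.  Compartments and stoichiometric coefficients never
enter the comparison.

Displayed percentages are floored to integers (2 of 3 metabolites shows
as 66); internal values stay exact rationals.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from . import identity
from .model import Corpus, ParseError, ReactionRecord, ValidationError
from .identity import EquivalenceClasses, class_id_for, normalize_name

__all__ = [
    "ReactionSignature",
    "OverlapResult",
    "OverlapMatrix",
    "currency_classes",
    "make_signature",
    "signature_index",
    "overlap",
    "display_percent",
    "mismatch_count",
    "parse_equation",
    "resolve_metabolite_terms",
    "query_reactions",
    "all_pairwise",
    "exact_reaction_classes",
]

Key = tuple[str, str]

# Names and KEGG Compound ids that seed the default currency-species
# exclusion list (configurable and extensible by class id).
CURRENCY_NAMES = {
    "h2o", "water",
    "h", "hplus", "proton", "hydrogenion",
    "e", "eminus", "electron",
}
CURRENCY_KEGG_IDS = {"C00001", "C00080", "C05359"}


@dataclass(frozen=True)
class ReactionSignature:
    """Per-side metabolite-class sets of one reaction, post-exclusion."""

    key: Key
    left: frozenset[str]
    right: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.left) + len(self.right)

    def swapped(self) -> "ReactionSignature":
        return ReactionSignature(key=self.key, left=self.right, right=self.left)


@dataclass(frozen=True)
class OverlapResult:
    percent: Fraction
    matches: int
    size1: int
    size2: int
    orientation: str  # "parallel" | "antiparallel"


@dataclass
class OverlapMatrix:
    """Symmetric all-pairs overlap store keyed by unordered reaction pairs."""

    results: dict[frozenset, OverlapResult] = field(default_factory=dict)
    keys: list[Key] = field(default_factory=list)

    def get(self, k1: Key, k2: Key) -> OverlapResult:
        if k1 == k2:
            return OverlapResult(Fraction(100), 0, 0, 0, "parallel")
        return self.results[frozenset((k1, k2))]

    def percent(self, k1: Key, k2: Key) -> Fraction:
        return self.get(k1, k2).percent

    def to_frame(self):
        import pandas as pd

        rows = []
        for pair in self.results:
            k1, k2 = sorted(pair)
            r = self.results[pair]
            rows.append(
                {
                    "db1": k1[0], "reaction1": k1[1],
                    "db2": k2[0], "reaction2": k2[1],
                    "percent_display": display_percent(r.percent),
                    "matches": r.matches, "size1": r.size1, "size2": r.size2,
                    "orientation": r.orientation,
                }
            )
        rows.sort(key=lambda r: (r["db1"], r["reaction1"], r["db2"], r["reaction2"]))
        return pd.DataFrame(
            rows,
            columns=[
                "db1", "reaction1", "db2", "reaction2",
                "percent_display", "matches", "size1", "size2", "orientation",
            ],
        )


# ---------------------------------------------------------------------------
# Exclusion list


def currency_classes(
    corpus: Corpus,
    met_classes: Optional[EquivalenceClasses] = None,
    extra_names: Iterable[str] = (),
    extra_class_ids: Iterable[str] = (),
) -> frozenset[str]:
    """Metabolite class ids to exclude from reaction matching.

    Seeded from names/ids for electrons, protons and water; extensible with
    further names or explicit class ids."""
    met_classes = met_classes or identity.metabolite_classes(corpus)
    wanted = CURRENCY_NAMES | {normalize_name(n) for n in extra_names}
    excluded = set(extra_class_ids)
    for m in corpus.iter_metabolites():
        hit = (
            any(normalize_name(n) in wanted for n in m.all_names())
            or m.external_ids.get("kegg_compound") in CURRENCY_KEGG_IDS
        )
        if hit:
            excluded.add(met_classes.class_of[m.key])
    return frozenset(excluded)


def default_exclusion(corpus: Corpus) -> frozenset[str]:
    cached = corpus.cache_get("exclusion")
    if cached is None:
        cached = currency_classes(corpus)
        corpus.cache_set("exclusion", cached)
    return cached


# ---------------------------------------------------------------------------
# Signatures and overlap


def make_signature(
    reaction: ReactionRecord,
    met_classes: EquivalenceClasses,
    exclusion: frozenset[str] = frozenset(),
) -> ReactionSignature:
    """Per-side class sets with currency classes removed.

    Duplicate participants collapse (set semantics); a side left empty by
    the exclusion is permitted."""
    sides = {"left": set(), "right": set()}
    for p in reaction.participants:
        key = (reaction.source_db, p.metabolite_ref)
        if key not in met_classes.class_of:
            raise ValidationError(
                f"participant {key} of reaction {reaction.key} has no identity class"
            )
        cid = met_classes.class_of[key]
        if cid not in exclusion:
            sides[p.side].add(cid)
    return ReactionSignature(
        key=reaction.key, left=frozenset(sides["left"]), right=frozenset(sides["right"])
    )


def signature_index(corpus: Corpus, exclusion: Optional[frozenset[str]] = None):
    """Signatures for every reaction in the corpus (cached for the default
    exclusion list)."""
    use_default = exclusion is None
    if use_default:
        exclusion = default_exclusion(corpus)
        cached = corpus.cache_get("signatures")
        if cached is not None:
            return cached
    met_classes = identity.metabolite_classes(corpus)
    sigs = {
        r.key: make_signature(r, met_classes, exclusion) for r in corpus.iter_reactions()
    }
    if use_default:
        corpus.cache_set("signatures", sigs)
    return sigs


def overlap(s1: ReactionSignature, s2: ReactionSignature) -> OverlapResult:
    """Percentage of overlap between two signatures (best orientation)."""
    parallel = len(s1.left & s2.left) + len(s1.right & s2.right)
    antiparallel = len(s1.left & s2.right) + len(s1.right & s2.left)
    if antiparallel > parallel:
        matches, orientation = antiparallel, "antiparallel"
    else:
        matches, orientation = parallel, "parallel"
    denom = max(s1.size, s2.size)
    percent = Fraction(0) if denom == 0 else Fraction(matches * 100, denom)
    return OverlapResult(
        percent=percent, matches=matches, size1=s1.size, size2=s2.size,
        orientation=orientation,
    )


def display_percent(percent) -> int:
    """Integer rendering of an overlap percentage: floor (2/3 -> 66)."""
    return math.floor(percent)


def mismatch_count(s1: ReactionSignature, s2: ReactionSignature) -> int:
    """Metabolite classes of the larger reaction left unmatched under the
    best orientation; 0 iff the overlap is 100%."""
    r = overlap(s1, s2)
    return max(r.size1, r.size2) - r.matches


# ---------------------------------------------------------------------------
# Queries

_ARROW_RE = re.compile(r"<==>|<=>|\|==\||-->|->|→|=(?!=)")
_COMPARTMENT_RE = re.compile(r"\[[^\]]*\]\s*$")


def parse_equation(text: str) -> tuple[list[str], list[str], str]:
    """Split ``"A + B -> C + D"`` into (left terms, right terms, direction).

    Recognized arrows: ``->``/``-->``/``→`` (forward), ``<==>``/``<=>``/``=``
    (reversible), ``|==|`` (unknown).  Compartment suffixes like ``[c]``
    are stripped from terms."""
    m = _ARROW_RE.search(text)
    if not m:
        raise ParseError(f"no reaction arrow found in {text!r}")
    arrow = m.group(0)
    direction = {
        "->": "forward", "-->": "forward", "→": "forward",
        "<==>": "reversible", "<=>": "reversible", "=": "reversible",
        "|==|": "unknown",
    }[arrow]

    def split_side(side: str) -> list[str]:
        terms = []
        for raw in side.split(" + "):
            t = _COMPARTMENT_RE.sub("", raw.strip()).strip()
            if t:
                terms.append(t)
        return terms

    left = split_side(text[: m.start()])
    right = split_side(text[m.end() :])
    if not left or not right:
        raise ParseError(f"both sides of the equation must be non-empty: {text!r}")
    return left, right, direction


def resolve_metabolite_terms(
    corpus: Corpus, terms: Sequence[str]
) -> tuple[dict[str, set[str]], list[str]]:
    """Resolve query terms to metabolite class ids.

    A term matches a metabolite by normalized name/synonym, by any external
    identifier value, or by explicit ``db:local_id`` key.  Returns
    (term -> class-id set, unresolved terms)."""
    met_classes = identity.metabolite_classes(corpus)
    resolved: dict[str, set[str]] = {}
    unresolved: list[str] = []
    for term in terms:
        norm = normalize_name(term)
        hits: set[str] = set()
        for m in corpus.iter_metabolites():
            if (
                norm
                and norm in {normalize_name(n) for n in m.all_names()}
                or term in m.external_ids.values()
                or term == f"{m.source_db}:{m.local_id}"
            ):
                hits.add(met_classes.class_of[m.key])
        if hits:
            resolved[term] = hits
        else:
            unresolved.append(term)
    return resolved, unresolved


def _query_signature(
    corpus: Corpus,
    left_terms: Sequence[str],
    right_terms: Sequence[str],
    exclusion: frozenset[str],
) -> tuple[ReactionSignature, list[str]]:
    resolved, unresolved = resolve_metabolite_terms(
        corpus, list(left_terms) + list(right_terms)
    )

    def side_classes(terms: Sequence[str]) -> frozenset[str]:
        out = set()
        for t in terms:
            for cid in resolved.get(t, ()):
                if cid not in exclusion:
                    out.add(cid)
        return frozenset(out)

    sig = ReactionSignature(
        key=("query", "query"),
        left=side_classes(left_terms),
        right=side_classes(right_terms),
    )
    return sig, unresolved


def query_reactions(
    corpus: Corpus,
    query,
    allowed_mismatches: int = 0,
    pathway_filter: Optional[str] = None,
    exclusion: Optional[frozenset[str]] = None,
):
    """Find reactions similar to a queried conversion.

    ``query`` is an equation string (``"l-arginine + H2O -> ornithine +
    urea"``), a ``(left_terms, right_terms)`` pair, or a plain term list
    (side-free mode: terms are matched against the union of both sides).
    Reactions whose mismatch count does not exceed ``allowed_mismatches``
    are returned sorted by descending overlap, then reaction key.

    Returns a list of ``(reaction_key, OverlapResult)`` plus the list of
    query terms that resolved to nothing; if no term resolves the result
    is empty.
    """
    custom_exclusion = exclusion is not None
    if exclusion is None:
        exclusion = default_exclusion(corpus)
    side_free = False
    if isinstance(query, str):
        left_terms, right_terms, _ = parse_equation(query)
    elif (
        isinstance(query, (tuple, list))
        and len(query) == 2
        and all(isinstance(s, (tuple, list)) for s in query)
    ):
        left_terms, right_terms = query
    else:
        left_terms, right_terms = list(query), []
        side_free = True
    qsig, unresolved = _query_signature(corpus, left_terms, right_terms, exclusion)
    if qsig.size == 0:
        return [], unresolved

    sigs = signature_index(corpus, exclusion if custom_exclusion else None)
    hits = []
    for r in corpus.iter_reactions():
        if pathway_filter is not None and pathway_filter not in r.pathways:
            continue
        sig = sigs[r.key]
        if side_free:
            pool = sig.left | sig.right
            matches = len(qsig.left & pool)
            denom = max(len(qsig.left), sig.size)
            percent = Fraction(0) if denom == 0 else Fraction(matches * 100, denom)
            result = OverlapResult(percent, matches, len(qsig.left), sig.size, "parallel")
            mismatches = max(len(qsig.left), sig.size) - matches
        else:
            result = overlap(qsig, sig)
            mismatches = mismatch_count(qsig, sig)
        if mismatches <= allowed_mismatches:
            hits.append((r.key, result))
    hits.sort(key=lambda h: (-h[1].percent, h[0]))
    return hits, unresolved


# ---------------------------------------------------------------------------
# All-pairs matrix and exact-match closure


def all_pairwise(corpus: Corpus, sparse: bool = False) -> OverlapMatrix:
    """Overlap between every unordered pair of reactions in the corpus.

    ``sparse`` stores only pairs with non-zero overlap."""
    cache_key = f"overlap_matrix_sparse={sparse}"
    cached = corpus.cache_get(cache_key)
    if cached is not None:
        return cached
    sigs = signature_index(corpus)
    keys = sorted(sigs)
    matrix = OverlapMatrix(keys=keys)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            result = overlap(sigs[k1], sigs[k2])
            if sparse and result.percent == 0:
                continue
            matrix.results[frozenset((k1, k2))] = result
    corpus.cache_set(cache_key, matrix)
    return matrix


def exact_reaction_classes(corpus: Corpus) -> EquivalenceClasses:
    """Transitive closure over reaction pairs at exactly 100% overlap.

    Partial overlaps are reported on cards but never merged into a class.
    Degenerate reactions (empty signature after exclusion) stay singletons.
    """
    cached = corpus.cache_get("reaction_classes")
    if cached is not None:
        return cached
    import networkx as nx

    sigs = signature_index(corpus)
    graph = nx.Graph()
    graph.add_nodes_from(sigs)
    matrix = all_pairwise(corpus)
    for pair, result in matrix.results.items():
        if result.percent == 100:
            k1, k2 = pair
            graph.add_edge(k1, k2)
    eq = EquivalenceClasses(kind="reaction")
    for component in nx.connected_components(graph):
        cid = class_id_for(component)
        eq.members[cid] = frozenset(component)
        for key in component:
            eq.class_of[key] = cid
    corpus.cache_set("reaction_classes", eq)
    return eq
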