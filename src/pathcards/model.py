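"""Core data model for a multi-database metabolic-network corpus.

A *corpus* bundles several independently curated descriptions of one
organism's metabolic network (e.g. the five human databases EHMN,
Recon 1, HumanCyc, KEGG, Reactome).  Each source database contributes
metabolites, genes, reactions with gene associations and EC links, and
pathway assignments.  All cross-database reasoning (identity classes,
reaction overlap, cards) is layered on top of these records.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "PathcardsError",
    "LoadError",
    "ValidationError",
    "ParseError",
    "ConfigError",
    "NotFoundError",
    "AmbiguousQueryError",
    "ECNumber",
    "GeneAssociation",
    "Participant",
    "MetaboliteRecord",
    "GeneRecord",
    "ReactionRecord",
    "PathwayRecord",
    "SourceDatabase",
    "Corpus",
    "IdUpdateTable",
    "METABOLITE_NAMESPACES",
    "GENE_NAMESPACES",
    "DIRECTION_ARROWS",
]

# Identifier namespaces a database may attach to a metabolite.  Order is the
# canonical column order of the interchange format.
METABOLITE_NAMESPACES = (
    "kegg_compound",
    "kegg_glycan",
    "chebi",
    "pubchem_compound",
    "pubchem_substance",
    "cas",
)

GENE_NAMESPACES = ("entrez", "ensembl", "uniprot")

DIRECTION_ARROWS = {"forward": "→", "reversible": "<==>", "unknown": "|==|"}

OBSOLETE = "OBSOLETE"


class PathcardsError(Exception):
    """Base class for all package errors."""


class LoadError(PathcardsError):
    """A mandatory interchange table is missing or unreadable."""


class ValidationError(PathcardsError):
    """Referential-integrity or schema violations; carries offender list."""

    def __init__(self, message: str, offenders: Optional[list[str]] = None):
        super().__init__(message)
        self.offenders = offenders or []


class ParseError(PathcardsError):
    """Malformed EC number, gene association, formula, or equation text."""


class ConfigError(PathcardsError):
    """Invalid configuration value (unknown update kind, bad rate...)."""


class NotFoundError(PathcardsError):
    """A query resolved to no entity in the corpus."""


class AmbiguousQueryError(PathcardsError):
    """A query resolved to several entities; lists the candidates."""

    def __init__(self, message: str, candidates: Optional[list[str]] = None):
        super().__init__(message)
        self.candidates = candidates or []


# ---------------------------------------------------------------------------
# EC numbers


@dataclass(frozen=True)
class ECNumber:
    """Four-component Enzyme Commission code.

    Unassigned components are stored as ``None`` and rendered as ``"-"``.
    Equality is literal: ``2.4.2.-`` never matches ``2.4.2.1`` — the dash is
    deliberately not a wildcard, to avoid spurious cross-database matches.
    """

    c1: Optional[int]
    c2: Optional[int]
    c3: Optional[int]
    c4: Optional[int]

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if len(parts) != 4:
            raise ParseError(f"EC number must have 4 components: {text!r}")
        comps = []
        for p in parts:
            p = p.strip()
            if p == "-":
                comps.append(None)
            else:
                try:
                    v = int(p)
                except ValueError:
                    raise ParseError(f"bad EC component {p!r} in {text!r}") from None
                if v <= 0:
                    raise ParseError(f"EC components must be positive: {text!r}")
                comps.append(v)
        return cls(*comps)

    def __str__(self) -> str:
        return ".".join("-" if c is None else str(c) for c in (self.c1, self.c2, self.c3, self.c4))

    @property
    def is_complete(self) -> bool:
        return None not in (self.c1, self.c2, self.c3, self.c4)

    def _sort_key(self):
        # stable ordering with unassigned ("-") components sorting last
        return tuple(
            (c is None, c if c is not None else 0) for c in (self.c1, self.c2, self.c3, self.c4)
        )

    def __lt__(self, other: "ECNumber"):
        return self._sort_key() < other._sort_key()


# ---------------------------------------------------------------------------
# Gene associations (GPR expressions)


@dataclass(frozen=True)
class GeneAssociation:
    """Boolean gene-product expression attached to a reaction.

    ``op`` is one of:

    - ``"leaf"`` — a single gene (``gene`` holds its local id),
    - ``"and"``  — subunits of a complex (all required),
    - ``"or"``   — isozymes (any suffices),
    - ``"list"`` — genes listed without stated semantics (databases such as
      EHMN and KEGG have no syntax for complexes vs isozymes; rendered
      comma-separated).
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GeneAssociation", ...] = ()

    def __post_init__(self):
        if self.op not in ("leaf", "and", "or", "list"):
            raise ParseError(f"unknown association operator {self.op!r}")
        if self.op == "leaf" and not self.gene:
            raise ParseError("leaf association requires a gene id")

    @classmethod
    def leaf(cls, gene: str) -> "GeneAssociation":
        return cls("leaf", gene=gene)

    @classmethod
    def or_(cls, *children: "GeneAssociation") -> "GeneAssociation":
        return cls("or", children=tuple(children))

    @classmethod
    def and_(cls, *children: "GeneAssociation") -> "GeneAssociation":
        return cls("and", children=tuple(children))

    @classmethod
    def list_(cls, *genes: str) -> "GeneAssociation":
        return cls("list", children=tuple(cls.leaf(g) for g in genes))

    def genes(self) -> list[str]:
        """All gene local ids, in tree order (duplicates preserved)."""
        if self.op == "leaf":
            return [self.gene]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.genes())
        return out

    @property
    def dialect(self) -> str:
        return "list" if self.op == "list" else "boolean"

    def render(self, symbol_of=None) -> str:
        """Human-readable rendering; ``symbol_of`` maps a gene local id to
        its display symbol (defaults to the id itself)."""
        sym = symbol_of or (lambda g: g)
        if self.op == "leaf":
            return sym(self.gene)
        if self.op == "list":
            return ", ".join(c.render(sym) for c in self.children)
        if self.op == "or":
            parts = []
            for c in self.children:
                r = c.render(sym)
                parts.append(r)
            return " or ".join(parts)
        # and: complexes are parenthesized; or-children need their own
        # parentheses to keep the rendering re-parseable
        def wrap(c: "GeneAssociation") -> str:
            r = c.render(sym)
            return f"({r})" if c.op == "or" else r

        inner = " and ".join(wrap(c) for c in self.children)
        return f"({inner})"

    def to_text(self) -> str:
        """Canonical storage text (local ids, re-parseable)."""
        return self.render()


# ---------------------------------------------------------------------------
# Records


@dataclass
class Participant:
    """One metabolite occurrence on one side of a reaction.

    Compartment and stoichiometry are display-only: reaction matching works
    on per-side metabolite sets and ignores both.
    """

    metabolite_ref: str
    side: str  # "left" | "right"
    compartment: Optional[str] = None
    stoichiometry: Optional[float] = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"participant side must be left/right, got {self.side!r}")


@dataclass
class MetaboliteRecord:
    source_db: str
    local_id: str
    primary_name: str
    synonyms: set[str] = field(default_factory=set)
    chemical_formula: Optional[str] = None
    external_ids: dict[str, str] = field(default_factory=dict)
    inchi: Optional[str] = None
    smiles: Optional[str] = None
    # namespace -> "current" | "transferred" | "obsolete"; absent = current
    id_status: dict[str, str] = field(default_factory=dict)
    # namespace -> previous value (for transferred ids)
    id_previous: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_db, self.local_id)

    def all_names(self) -> set[str]:
        return {self.primary_name} | set(self.synonyms)

    def usable_id(self, namespace: str) -> Optional[str]:
        """Identifier value for matching: obsolete-flagged ids are excluded."""
        if self.id_status.get(namespace) == "obsolete":
            return None
        return self.external_ids.get(namespace) or None


@dataclass
class GeneRecord:
    source_db: str
    local_id: str
    entrez: Optional[str] = None
    ensembl: Optional[str] = None
    uniprot: Optional[str] = None
    hgnc_symbols: set[str] = field(default_factory=set)
    id_status: dict[str, str] = field(default_factory=dict)
    id_previous: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_db, self.local_id)

    def usable_id(self, namespace: str) -> Optional[str]:
        if self.id_status.get(namespace) == "obsolete":
            return None
        return getattr(self, namespace) or None

    def display_symbol(self) -> str:
        """Display rule: HGNC symbols joined by double underscore; fall back
        to Entrez, then Ensembl, then the database-internal id."""
        if self.hgnc_symbols:
            return "__".join(sorted(self.hgnc_symbols))
        return self.entrez or self.ensembl or self.local_id


@dataclass
class ReactionRecord:
    source_db: str
    local_id: str
    participants: list[Participant] = field(default_factory=list)
    direction: str = "unknown"  # forward | reversible | unknown
    ec_numbers: set[ECNumber] = field(default_factory=set)
    gene_association: Optional[GeneAssociation] = None
    pathways: set[str] = field(default_factory=set)
    # EC -> status flag, EC -> previous text (update-table bookkeeping)
    ec_status: dict[ECNumber, str] = field(default_factory=dict)
    ec_previous: dict[ECNumber, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.direction not in DIRECTION_ARROWS:
            raise ValidationError(
                f"direction must be forward/reversible/unknown, got {self.direction!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_db, self.local_id)

    def side(self, which: str) -> list[Participant]:
        return [p for p in self.participants if p.side == which]

    @property
    def arrow(self) -> str:
        return DIRECTION_ARROWS[self.direction]


@dataclass
class PathwayRecord:
    source_db: str
    pathway_id: str
    name: str


@dataclass
class SourceDatabase:
    """All records one pathway database contributes to a corpus."""

    name: str
    version: str = ""
    metabolites: dict[str, MetaboliteRecord] = field(default_factory=dict)
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)
    pathways: dict[str, PathwayRecord] = field(default_factory=dict)

    def add(self, record) -> None:
        if isinstance(record, MetaboliteRecord):
            table, rid = self.metabolites, record.local_id
        elif isinstance(record, GeneRecord):
            table, rid = self.genes, record.local_id
        elif isinstance(record, ReactionRecord):
            table, rid = self.reactions, record.local_id
        elif isinstance(record, PathwayRecord):
            table, rid = self.pathways, record.pathway_id
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot add {type(record).__name__}")
        if rid in table:
            raise ValidationError(f"{self.name}: duplicate id {rid!r}")
        if record.source_db != self.name:
            raise ValidationError(
                f"record {rid!r} labelled {record.source_db!r}, expected {self.name!r}"
            )
        table[rid] = record

    def validate(self) -> list[str]:
        """Referential-integrity check; returns offender descriptions."""
        offenders = []
        for rxn in self.reactions.values():
            left = right = 0
            for p in rxn.participants:
                if p.metabolite_ref not in self.metabolites:
                    offenders.append(
                        f"{self.name}/reactions/{rxn.local_id}: unknown metabolite "
                        f"{p.metabolite_ref!r}"
                    )
                if p.side == "left":
                    left += 1
                else:
                    right += 1
            if left == 0 or right == 0:
                offenders.append(
                    f"{self.name}/reactions/{rxn.local_id}: needs >=1 participant per side"
                )
            if rxn.gene_association is not None:
                for g in rxn.gene_association.genes():
                    if g not in self.genes:
                        offenders.append(
                            f"{self.name}/reactions/{rxn.local_id}: unknown gene {g!r}"
                        )
            for pw in rxn.pathways:
                if pw not in self.pathways:
                    offenders.append(
                        f"{self.name}/reactions/{rxn.local_id}: unknown pathway {pw!r}"
                    )
        return offenders


@dataclass
class Corpus:
    """A set of source databases plus lazily built derived caches."""

    databases: dict[str, SourceDatabase] = field(default_factory=dict)
    _caches: dict = field(default_factory=dict, repr=False, compare=False)

    def add_database(self, db: SourceDatabase) -> None:
        if db.name in self.databases:
            raise ValidationError(f"duplicate database name {db.name!r}")
        self.databases[db.name] = db
        self.invalidate_caches()

    def db_names(self) -> list[str]:
        return sorted(self.databases)

    def iter_metabolites(self) -> Iterator[MetaboliteRecord]:
        for name in self.db_names():
            yield from self.databases[name].metabolites.values()

    def iter_genes(self) -> Iterator[GeneRecord]:
        for name in self.db_names():
            yield from self.databases[name].genes.values()

    def iter_reactions(self) -> Iterator[ReactionRecord]:
        for name in self.db_names():
            yield from self.databases[name].reactions.values()

    def metabolite(self, key: tuple[str, str]) -> MetaboliteRecord:
        return self.databases[key[0]].metabolites[key[1]]

    def gene(self, key: tuple[str, str]) -> GeneRecord:
        return self.databases[key[0]].genes[key[1]]

    def reaction(self, key: tuple[str, str]) -> ReactionRecord:
        return self.databases[key[0]].reactions[key[1]]

    def validate(self) -> None:
        offenders = []
        for db in self.databases.values():
            offenders.extend(db.validate())
        if offenders:
            raise ValidationError(
                f"{len(offenders)} referential-integrity violation(s)", offenders
            )

    # -- caches (equivalence classes, overlap matrix) -----------------------

    def invalidate_caches(self) -> None:
        self._caches.clear()

    def cache_get(self, key: str):
        return self._caches.get(key)

    def cache_set(self, key: str, value) -> None:
        self._caches[key] = value

    def copy(self) -> "Corpus":
        dup = Corpus(databases=copy.deepcopy(self.databases))
        return dup


@dataclass
class IdUpdateTable:
    """Pre-flattened identifier update mapping (old -> new, or OBSOLETE).

    ``kind`` selects what the table updates: ``gene_id`` (Entrez/Ensembl
    values), ``metabolite_id`` (any metabolite namespace value), or
    ``ec_number``.
    """

    kind: str
    entries: dict[str, str] = field(default_factory=dict)

    VALID_KINDS = ("gene_id", "metabolite_id", "ec_number")

    def __post_init__(self):
        if self.kind not in self.VALID_KINDS:
            raise ConfigError(f"unknown update-table kind {self.kind!r}")
        # reject chains: a value that is also a key must be forbidden
        for old, new in self.entries.items():
            if new != OBSOLETE and new in self.entries:
                raise ConfigError(
                    f"update chain {old!r} -> {new!r} -> ...: tables must be pre-flattened"
                )
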