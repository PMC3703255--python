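"""Corpus-level utilities: metabolite fate, dead-ends, membership tables,
content statistics, and cross-database presence overviews.

A *dead-end* metabolite is, within one database, a metabolite that its
reactions only ever produce or only ever consume; such species are prime
candidates for gap-filling against the other databases.  Dead-end status
is computed per database over metabolite identity classes (so synonyms
cannot split production from consumption) and, by default, with the
currency-species exclusion applied — water or protons are not meaningful
dead-ends.  Reactions of unknown direction are treated like reversible
ones: absence of direction evidence should not manufacture dead-ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pandas as pd

from . import identity, reactions as rx
from .model import Corpus, NotFoundError

__all__ = [
    "DeadEndReport",
    "metabolite_fate",
    "dead_end_metabolites",
    "pathway_membership_tables",
    "corpus_stats",
    "presence_overview",
]

Key = tuple[str, str]


@dataclass
class DeadEndReport:
    source_db: str
    metabolite_class: str
    status: str  # "produced_only" | "consumed_only"
    witness_reactions: list[str] = field(default_factory=list)


def _class_roles(corpus: Corpus, db_name: str, exclusion: frozenset[str]):
    """Per metabolite class in one database: sets of reactions producing
    and consuming it.  Reversible/unknown reactions count as both."""
    met_classes = identity.metabolite_classes(corpus)
    produced: dict[str, set[str]] = {}
    consumed: dict[str, set[str]] = {}
    db = corpus.databases[db_name]
    for r in db.reactions.values():
        for p in r.participants:
            cid = met_classes.class_of[(db_name, p.metabolite_ref)]
            if cid in exclusion:
                continue
            consuming = p.side == "left" or r.direction != "forward"
            producing = p.side == "right" or r.direction != "forward"
            if producing:
                produced.setdefault(cid, set()).add(r.local_id)
            if consuming:
                consumed.setdefault(cid, set()).add(r.local_id)
    return produced, consumed


def dead_end_metabolites(
    corpus: Corpus, db: str, apply_exclusion: bool = True
) -> list[DeadEndReport]:
    """Metabolite classes one database only produces or only consumes."""
    exclusion = rx.default_exclusion(corpus) if apply_exclusion else frozenset()
    produced, consumed = _class_roles(corpus, db, exclusion)
    reports = []
    for cid in sorted(set(produced) | set(consumed)):
        prod = produced.get(cid, set())
        cons = consumed.get(cid, set())
        if prod and not cons:
            reports.append(DeadEndReport(db, cid, "produced_only", sorted(prod)))
        elif cons and not prod:
            reports.append(DeadEndReport(db, cid, "consumed_only", sorted(cons)))
    return reports


def metabolite_fate(
    corpus: Corpus, metabolite_query: str, apply_exclusion: bool = True
) -> dict[str, dict]:
    """Per-database list of reactions a metabolite participates in.

    The query resolves to a metabolite identity class; for each database
    the reactions containing any class member are listed, and databases
    where the metabolite is a dead-end are flagged with its status."""
    resolved, unresolved = rx.resolve_metabolite_terms(corpus, [metabolite_query])
    if metabolite_query not in resolved:
        raise NotFoundError(f"metabolite query {metabolite_query!r} matched nothing")
    class_ids = resolved[metabolite_query]
    met_classes = identity.metabolite_classes(corpus)

    out: dict[str, dict] = {}
    for db_name in corpus.db_names():
        db = corpus.databases[db_name]
        hits = []
        for r in db.reactions.values():
            for p in r.participants:
                if met_classes.class_of[(db_name, p.metabolite_ref)] in class_ids:
                    hits.append(r.local_id)
                    break
        dead = {
            rep.metabolite_class: rep.status
            for rep in dead_end_metabolites(corpus, db_name, apply_exclusion)
            if rep.metabolite_class in class_ids
        }
        out[db_name] = {
            "reactions": sorted(hits),
            "dead_end": next(iter(dead.values()), None),
        }
    return out


def pathway_membership_tables(corpus: Corpus) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-pathway and metabolite-pathway tables.

    One row per (database, entity, pathway) pair, derived by joining each
    reaction's genes/metabolites with its pathway assignments; entities in
    no pathway contribute no row.  These tables feed per-database pathway
    enrichment analyses."""
    gene_rows = set()
    met_rows = set()
    for r in corpus.iter_reactions():
        db = corpus.databases[r.source_db]
        pathway_names = [
            db.pathways[pw].name if pw in db.pathways else pw for pw in r.pathways
        ]
        genes = r.gene_association.genes() if r.gene_association else []
        for pw in pathway_names:
            for g in set(genes):
                gene_rows.add((r.source_db, g, pw))
            for m in {p.metabolite_ref for p in r.participants}:
                met_rows.add((r.source_db, m, pw))
    cols_g = ["source_db", "gene_id", "pathway"]
    cols_m = ["source_db", "metabolite_id", "pathway"]
    genes_df = pd.DataFrame(sorted(gene_rows), columns=cols_g)
    mets_df = pd.DataFrame(sorted(met_rows), columns=cols_m)
    return genes_df, mets_df


def corpus_stats(corpus: Corpus) -> pd.DataFrame:
    """Per-database content statistics: distinct genes, EC numbers,
    reactions and pathways (the shape of a database-comparison summary
    table)."""
    rows = []
    for db_name in corpus.db_names():
        db = corpus.databases[db_name]
        ecs = {e for r in db.reactions.values() for e in r.ec_numbers}
        rows.append(
            {
                "database": db_name,
                "genes": len(db.genes),
                "ec_numbers": len(ecs),
                "reactions": len(db.reactions),
                "pathways": len(db.pathways),
            }
        )
    return pd.DataFrame(rows, columns=["database", "genes", "ec_numbers", "reactions", "pathways"])


def presence_overview(corpus: Corpus) -> dict[str, pd.DataFrame]:
    """Which genes, EC numbers and reactions occur in which database.

    Returns one boolean matrix per entity kind, indexed by identity-class
    id (genes, reactions) or literal EC text, with one column per source
    database.  Reaction presence uses exact-match (100% overlap) classes,
    so two near-identical variants occupy separate rows."""
    db_names = corpus.db_names()

    def matrix(rows: dict[str, set[str]]) -> pd.DataFrame:
        df = pd.DataFrame(
            [[db in dbs for db in db_names] for _, dbs in sorted(rows.items())],
            index=sorted(rows),
            columns=db_names,
            dtype=bool,
        )
        df.index.name = "class_id"
        return df

    gene_eq = identity.gene_classes(corpus)
    gene_rows: dict[str, set[str]] = {}
    for (db, _), cid in gene_eq.class_of.items():
        gene_rows.setdefault(cid, set()).add(db)

    ec_rows: dict[str, set[str]] = {}
    for r in corpus.iter_reactions():
        for e in r.ec_numbers:
            ec_rows.setdefault(str(e), set()).add(r.source_db)

    rxn_eq = rx.exact_reaction_classes(corpus)
    rxn_rows: dict[str, set[str]] = {}
    for (db, _), cid in rxn_eq.class_of.items():
        rxn_rows.setdefault(cid, set()).add(db)

    return {"gene": matrix(gene_rows), "ec": matrix(ec_rows), "reaction": matrix(rxn_rows)}
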