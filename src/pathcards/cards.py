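"""Consensus-and-conflict cards: per-entity cross-database overviews.

A card is centered at a focal entity — a gene, an EC number, or a reaction
— and lists, for every source database containing that entity, the
reaction(s) linked to it together with the EC number(s), gene(s) and
pathway each database attaches.  A reaction assigned to several pathways
contributes one row per pathway.  Missing elements render as an em dash.

Each card also carries reaction-similarity annotations: the gene and EC
perspectives attach an all-pairs overlap table, the reaction perspective
annotates every row with its overlap against the focal reaction.  The
three perspectives are complementary: differences in metabolite
granularity or protonation break reaction-level matches but usually leave
the linked gene and EC number untouched, so the gene/EC perspectives
co-locate such variants while the reaction perspective pinpoints them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from . import identity, reactions as rx
from .model import (
    AmbiguousQueryError,
    Corpus,
    ECNumber,
    NotFoundError,
    ParseError,
    ReactionRecord,
)

__all__ = [
    "CardRow",
    "Card",
    "gene_card",
    "ec_card",
    "reaction_card",
    "render_card",
    "parse_card_json",
    "export_all",
    "DEFAULT_BANDS",
]

Key = tuple[str, str]

MISSING = "—"

# Similarity banding for presentation layers (display percent lower bounds).
DEFAULT_BANDS = (100, 50, 1, 0)

TSV_COLUMNS = ["Database", "Reaction", "Overlap(%)", "EC number", "Gene(s)", "Pathway"]


@dataclass
class CardRow:
    source_db: str
    reaction_key: Key
    reaction_text: str
    overlap_display: Optional[int]
    ec_text: str
    genes_text: str
    pathway_name: str
    source_link: str


@dataclass
class Card:
    focus_kind: str  # "gene" | "ec" | "reaction"
    focus_label: str
    rows: list[CardRow] = field(default_factory=list)
    # gene/EC perspective: display percent for every unordered row-reaction pair
    similarity_pairs: dict[tuple[Key, Key], int] = field(default_factory=dict)
    id_panels: dict = field(default_factory=dict)
    ec_panels: dict = field(default_factory=dict)
    extensions: dict = field(default_factory=dict)  # reserved for annotations

    def databases(self) -> list[str]:
        return sorted({r.source_db for r in self.rows})

    def reaction_keys(self) -> list[Key]:
        seen: list[Key] = []
        for r in self.rows:
            if r.reaction_key not in seen:
                seen.append(r.reaction_key)
        return seen


# ---------------------------------------------------------------------------
# Rendering helpers


def render_reaction_text(reaction: ReactionRecord, corpus: Corpus) -> str:
    """``name[compartment] + ... ARROW name[compartment] + ...`` with the
    database's primary metabolite names."""

    def term(p) -> str:
        name = corpus.databases[reaction.source_db].metabolites[p.metabolite_ref].primary_name
        return f"{name}[{p.compartment}]" if p.compartment else name

    left = " + ".join(term(p) for p in reaction.side("left"))
    right = " + ".join(term(p) for p in reaction.side("right"))
    return f"{left} {reaction.arrow} {right}"


def _ec_text(reaction: ReactionRecord) -> str:
    if not reaction.ec_numbers:
        return MISSING
    return ", ".join(str(e) for e in sorted(reaction.ec_numbers))


def _genes_text(reaction: ReactionRecord, corpus: Corpus) -> str:
    assoc = reaction.gene_association
    if assoc is None:
        return MISSING
    db = corpus.databases[reaction.source_db]
    return assoc.render(lambda g: db.genes[g].display_symbol())


def _source_link(reaction: ReactionRecord, url_templates: Optional[dict] = None) -> str:
    template = (url_templates or {}).get(reaction.source_db)
    if template:
        return template.format(id=reaction.local_id)
    return f"{reaction.source_db}:{reaction.local_id}"


def _rows_for_reaction(
    corpus: Corpus,
    reaction: ReactionRecord,
    overlap_display: Optional[int],
    url_templates: Optional[dict] = None,
) -> list[CardRow]:
    db = corpus.databases[reaction.source_db]
    base = dict(
        source_db=reaction.source_db,
        reaction_key=reaction.key,
        reaction_text=render_reaction_text(reaction, corpus),
        overlap_display=overlap_display,
        ec_text=_ec_text(reaction),
        genes_text=_genes_text(reaction, corpus),
        source_link=_source_link(reaction, url_templates),
    )
    if not reaction.pathways:
        return [CardRow(pathway_name=MISSING, **base)]
    names = sorted(
        db.pathways[pw].name if pw in db.pathways else pw for pw in reaction.pathways
    )
    return [CardRow(pathway_name=n, **base) for n in names]


def _finish_rows(rows: list[CardRow]) -> list[CardRow]:
    rows.sort(key=lambda r: (r.source_db, r.reaction_key[1], r.pathway_name))
    return rows


def _id_panels(corpus: Corpus, reaction_keys: Iterable[Key]) -> dict:
    """Identifier details for every gene and metabolite on the card,
    including transferred/obsolete flags."""
    genes: dict[str, dict] = {}
    mets: dict[str, dict] = {}
    for key in reaction_keys:
        reaction = corpus.reaction(key)
        db = corpus.databases[reaction.source_db]
        if reaction.gene_association is not None:
            for gid in reaction.gene_association.genes():
                g = db.genes[gid]
                genes[f"{g.source_db}:{g.local_id}"] = {
                    "display": g.display_symbol(),
                    "entrez": g.entrez,
                    "ensembl": g.ensembl,
                    "uniprot": g.uniprot,
                    "hgnc": sorted(g.hgnc_symbols),
                    "id_status": dict(g.id_status),
                }
        for p in reaction.participants:
            m = db.metabolites[p.metabolite_ref]
            mets[f"{m.source_db}:{m.local_id}"] = {
                "name": m.primary_name,
                "synonyms": sorted(m.synonyms),
                "formula": m.chemical_formula,
                "external_ids": dict(m.external_ids),
                "inchi": m.inchi,
                "smiles": m.smiles,
                "id_status": dict(m.id_status),
            }
    return {"genes": genes, "metabolites": mets}


def _all_pairs_similarity(corpus: Corpus, keys: list[Key]) -> dict[tuple[Key, Key], int]:
    sigs = rx.signature_index(corpus)
    out: dict[tuple[Key, Key], int] = {}
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            a, b = sorted((k1, k2))
            out[(a, b)] = rx.display_percent(rx.overlap(sigs[k1], sigs[k2]).percent)
    return out


def _ec_panels(ecs: Iterable[ECNumber], ec_reference: Optional[dict]) -> dict:
    if not ec_reference:
        return {}
    panels = {}
    for ec in ecs:
        ref = ec_reference.get(str(ec))
        if ref:
            panels[str(ec)] = ref
    return panels


# ---------------------------------------------------------------------------
# Perspectives


def _resolve_gene_classes(corpus: Corpus, query: str) -> list[str]:
    eq = identity.gene_classes(corpus)
    hits = set()
    for g in corpus.iter_genes():
        if (
            query == g.display_symbol()
            or query in g.hgnc_symbols
            or query == g.entrez
            or query == g.ensembl
            or query == f"{g.source_db}:{g.local_id}"
        ):
            hits.add(eq.class_of[g.key])
    return sorted(hits)


def gene_card(
    corpus: Corpus,
    gene_query: str,
    url_templates: Optional[dict] = None,
    ec_reference: Optional[dict] = None,
) -> Card:
    """Card centered at a gene: which metabolic functions does its product
    have according to each database?

    The query (HGNC symbol, display symbol, Entrez/Ensembl id, or explicit
    ``db:local_id``) must resolve to exactly one cross-database gene class;
    an ambiguous symbol raises with the candidate classes listed.  Rows are
    every reaction, in any database, whose gene association references a
    class member."""
    classes = _resolve_gene_classes(corpus, gene_query)
    if not classes:
        raise NotFoundError(f"gene query {gene_query!r} matched nothing")
    if len(classes) > 1:
        raise AmbiguousQueryError(
            f"gene query {gene_query!r} is ambiguous", candidates=classes
        )
    eq = identity.gene_classes(corpus)
    members = eq.members[classes[0]]
    member_set = set(members)

    rows: list[CardRow] = []
    keys: list[Key] = []
    for r in corpus.iter_reactions():
        if r.gene_association is None:
            continue
        refs = {(r.source_db, g) for g in r.gene_association.genes()}
        if refs & member_set:
            rows.extend(_rows_for_reaction(corpus, r, None, url_templates))
            keys.append(r.key)
    card = Card(focus_kind="gene", focus_label=gene_query, rows=_finish_rows(rows))
    card.similarity_pairs = _all_pairs_similarity(corpus, keys)
    card.id_panels = _id_panels(corpus, keys)
    all_ecs = {e for k in keys for e in corpus.reaction(k).ec_numbers}
    card.ec_panels = _ec_panels(all_ecs, ec_reference)
    return card


def ec_card(
    corpus: Corpus,
    ec,
    fourth_wildcard: bool = False,
    url_templates: Optional[dict] = None,
    ec_reference: Optional[dict] = None,
) -> Card:
    """Card centered at an EC number: on which elements linked to this
    enzymatic activity do the databases (dis)agree?

    By default ECs compare literally; ``fourth_wildcard`` relaxes the
    fourth component (substrate-specificity digit), pulling in sibling
    activities."""
    focus = ec if isinstance(ec, ECNumber) else ECNumber.parse(str(ec))
    rule = identity.ec_family_equal if fourth_wildcard else identity.ec_equal
    rows: list[CardRow] = []
    keys: list[Key] = []
    for r in corpus.iter_reactions():
        if any(rule(focus, e) for e in r.ec_numbers):
            rows.extend(_rows_for_reaction(corpus, r, None, url_templates))
            keys.append(r.key)
    card = Card(focus_kind="ec", focus_label=str(focus), rows=_finish_rows(rows))
    card.similarity_pairs = _all_pairs_similarity(corpus, keys)
    card.id_panels = _id_panels(corpus, keys)
    all_ecs = {e for k in keys for e in corpus.reaction(k).ec_numbers} | {focus}
    card.ec_panels = _ec_panels(all_ecs, ec_reference)
    return card


def _resolve_reaction(corpus: Corpus, ref) -> ReactionRecord:
    if isinstance(ref, ReactionRecord):
        return ref
    if isinstance(ref, tuple) and len(ref) == 2:
        db, rid = ref
    elif isinstance(ref, str) and ":" in ref and not rx._ARROW_RE.search(ref):
        db, _, rid = ref.partition(":")
    else:
        raise NotFoundError(f"cannot resolve reaction reference {ref!r}")
    try:
        return corpus.databases[db].reactions[rid]
    except KeyError:
        raise NotFoundError(f"reaction {db}:{rid} not in corpus") from None


def reaction_card(
    corpus: Corpus,
    reaction_ref,
    mismatch_budget: int = 0,
    url_templates: Optional[dict] = None,
    ec_reference: Optional[dict] = None,
) -> Card:
    """Card centered at a reaction: which gene(s) and EC number(s) does
    each database link to this conversion?

    ``reaction_ref`` is either an existing reaction (record, key tuple or
    ``"db:local_id"``) or an equation query string such as
    ``"l-arginine + H2O -> ornithine + urea"``.  Rows cover the focal
    reaction's exact-match class and, with a positive ``mismatch_budget``,
    near matches; every row is annotated with its overlap against the
    focus."""
    if isinstance(reaction_ref, str) and rx._ARROW_RE.search(reaction_ref):
        hits, unresolved = rx.query_reactions(
            corpus, reaction_ref, allowed_mismatches=mismatch_budget
        )
        if not hits:
            raise NotFoundError(
                f"query {reaction_ref!r} matched no reaction"
                + (f" (unresolved terms: {unresolved})" if unresolved else "")
            )
        focus_label = reaction_ref
        annotated = hits
    else:
        focus = _resolve_reaction(corpus, reaction_ref)
        sigs = rx.signature_index(corpus)
        fsig = sigs[focus.key]
        annotated = []
        for r in corpus.iter_reactions():
            result = rx.overlap(fsig, sigs[r.key])
            if rx.mismatch_count(fsig, sigs[r.key]) <= mismatch_budget:
                annotated.append((r.key, result))
        annotated.sort(key=lambda h: (-h[1].percent, h[0]))
        focus_label = f"{focus.source_db}:{focus.local_id}"

    rows: list[CardRow] = []
    keys: list[Key] = []
    for key, result in annotated:
        r = corpus.reaction(key)
        rows.extend(
            _rows_for_reaction(corpus, r, rx.display_percent(result.percent), url_templates)
        )
        keys.append(key)
    card = Card(focus_kind="reaction", focus_label=focus_label, rows=_finish_rows(rows))
    card.id_panels = _id_panels(corpus, keys)
    all_ecs = {e for k in keys for e in corpus.reaction(k).ec_numbers}
    card.ec_panels = _ec_panels(all_ecs, ec_reference)
    return card


# ---------------------------------------------------------------------------
# Serialization


def _key_str(k: Key) -> str:
    return f"{k[0]}:{k[1]}"


def render_card(card: Card, format: str = "tsv") -> str:
    """Serialize a card deterministically.

    ``tsv``: the main table (Database, Reaction, Overlap(%), EC number,
    Gene(s), Pathway) followed, for gene/EC perspectives, by a
    ``# similarity`` section with one row per reaction pair.  ``json``:
    the full card model including identifier panels."""
    if format == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        for r in card.rows:
            overlap_cell = "" if r.overlap_display is None else str(r.overlap_display)
            lines.append(
                "\t".join(
                    [r.source_db, r.reaction_text, overlap_cell, r.ec_text,
                     r.genes_text, r.pathway_name]
                )
            )
        if card.similarity_pairs:
            lines.append("")
            lines.append("# similarity")
            lines.append("\t".join(["Reaction1", "Reaction2", "Overlap(%)"]))
            for (k1, k2) in sorted(card.similarity_pairs):
                lines.append(
                    "\t".join(
                        [_key_str(k1), _key_str(k2), str(card.similarity_pairs[(k1, k2)])]
                    )
                )
        return "\n".join(lines) + "\n"
    if format == "json":
        payload = {
            "schema_version": 1,
            "focus": {"kind": card.focus_kind, "label": card.focus_label},
            "rows": [
                {
                    "database": r.source_db,
                    "reaction_key": _key_str(r.reaction_key),
                    "reaction": r.reaction_text,
                    "overlap_display": r.overlap_display,
                    "ec": r.ec_text,
                    "genes": r.genes_text,
                    "pathway": r.pathway_name,
                    "source_link": r.source_link,
                }
                for r in card.rows
            ],
            "similarity": {
                f"{_key_str(k1)}|{_key_str(k2)}": v
                for (k1, k2), v in sorted(card.similarity_pairs.items())
            },
            "id_panels": card.id_panels,
            "ec_panels": card.ec_panels,
            "extensions": card.extensions,
        }
        return json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    raise ParseError(f"unknown card format {format!r}")


def _parse_key(s: str) -> Key:
    db, _, rid = s.partition(":")
    return (db, rid)


def parse_card_json(text: str) -> Card:
    """Inverse of ``render_card(..., "json")``; round-trip stable."""
    payload = json.loads(text)
    card = Card(
        focus_kind=payload["focus"]["kind"], focus_label=payload["focus"]["label"]
    )
    for r in payload["rows"]:
        card.rows.append(
            CardRow(
                source_db=r["database"],
                reaction_key=_parse_key(r["reaction_key"]),
                reaction_text=r["reaction"],
                overlap_display=r["overlap_display"],
                ec_text=r["ec"],
                genes_text=r["genes"],
                pathway_name=r["pathway"],
                source_link=r["source_link"],
            )
        )
    for pair, v in payload.get("similarity", {}).items():
        a, b = pair.split("|")
        card.similarity_pairs[(_parse_key(a), _parse_key(b))] = v
    card.id_panels = payload.get("id_panels", {})
    card.ec_panels = payload.get("ec_panels", {})
    card.extensions = payload.get("extensions", {})
    return card


# ---------------------------------------------------------------------------
# Bulk export


_SAFE_RE = re.compile(r"[^0-9A-Za-z._-]+")


def _safe_name(s: str) -> str:
    return _SAFE_RE.sub("_", s) or "_"


def export_all(
    corpus: Corpus, out_dir, format: str = "tsv", url_templates: Optional[dict] = None
) -> dict[tuple[str, str], int]:
    """Write one card per (database, perspective, entity).

    Produces ``out_dir/<db>/<perspective>/`` directories with one file per
    entity and an ``index.tsv`` (entity, file) each; returns a map from
    (database, perspective) to the number of cards written."""
    out = Path(out_dir)
    counts: dict[tuple[str, str], int] = {}
    ext = "tsv" if format == "tsv" else "json"
    for db_name in corpus.db_names():
        db = corpus.databases[db_name]

        entries: dict[str, list[tuple[str, Card]]] = {"gene": [], "ec": [], "reaction": []}
        for gid in sorted(db.genes):
            entries["gene"].append(
                (gid, gene_card(corpus, f"{db_name}:{gid}", url_templates))
            )
        ecs = sorted({e for r in db.reactions.values() for e in r.ec_numbers})
        for ec in ecs:
            entries["ec"].append((str(ec), ec_card(corpus, ec, url_templates=url_templates)))
        for rid in sorted(db.reactions):
            entries["reaction"].append(
                (rid, reaction_card(corpus, (db_name, rid), url_templates=url_templates))
            )

        for perspective, items in entries.items():
            d = out / db_name / perspective
            d.mkdir(parents=True, exist_ok=True)
            index_lines = ["entity\tfile"]
            for entity, card in items:
                fname = f"{_safe_name(entity)}.{ext}"
                (d / fname).write_text(render_card(card, format), encoding="utf-8")
                index_lines.append(f"{entity}\t{fname}")
            (d / "index.tsv").write_text("\n".join(index_lines) + "\n", encoding="utf-8")
            counts[(db_name, perspective)] = len(items)
    return counts
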