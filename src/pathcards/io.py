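"""Read/write the TSV interchange format and apply identifier updates.

One corpus lives in a directory with one subdirectory per source database.
Each subdirectory holds eight mandatory TSV tables (UTF-8, header row,
empty string = absent):

- ``metabolites.tsv``: local_id, primary_name, synonyms (``|``-separated),
  formula, one column per identifier namespace, inchi, smiles, id_status
- ``genes.tsv``: local_id, entrez, ensembl, uniprot, hgnc (``|``-separated),
  id_status
- ``reactions.tsv``: local_id, direction (forward/reversible/unknown)
- ``participants.tsv``: reaction_id, metabolite_id, side, compartment,
  stoichiometry
- ``reaction_genes.tsv``: reaction_id, association_text, dialect
- ``reaction_ec.tsv``: reaction_id, ec, status
- ``reaction_pathways.tsv``: reaction_id, pathway_id
- ``pathways.tsv``: pathway_id, name

plus an optional ``database.tsv`` (name, version).  Exports are byte-stable:
records are written sorted by (source_db, local_id).

Identifier-update tables (``id_updates.tsv``: kind, old, new_or_OBSOLETE;
``cid_sid.tsv``: substance_id, compound_id) support transferring out-of-date
gene/metabolite identifiers and EC numbers to their current values, or
flagging them obsolete when no replacement exists.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import (
    ConfigError,
    GENE_NAMESPACES,
    METABOLITE_NAMESPACES,
    OBSOLETE,
    Corpus,
    ECNumber,
    GeneAssociation,
    GeneRecord,
    IdUpdateTable,
    LoadError,
    MetaboliteRecord,
    ParseError,
    Participant,
    PathwayRecord,
    ReactionRecord,
    SourceDatabase,
    ValidationError,
)

__all__ = [
    "read_corpus",
    "write_corpus",
    "apply_id_updates",
    "convert_substance_ids",
    "parse_gene_association",
    "read_id_updates",
    "read_cid_sid",
]

MANDATORY_TABLES = (
    "metabolites.tsv",
    "genes.tsv",
    "reactions.tsv",
    "participants.tsv",
    "reaction_genes.tsv",
    "reaction_ec.tsv",
    "reaction_pathways.tsv",
    "pathways.tsv",
)

_MET_COLUMNS = (
    ["local_id", "primary_name", "synonyms", "formula"]
    + list(METABOLITE_NAMESPACES)
    + ["inchi", "smiles", "id_status"]
)
_GENE_COLUMNS = ["local_id", "entrez", "ensembl", "uniprot", "hgnc", "id_status"]


# ---------------------------------------------------------------------------
# Gene association grammar


_TOKEN_RE = re.compile(r"\(|\)|,|[^\s(),]+")


def parse_gene_association(text: str, dialect: str = "boolean") -> GeneAssociation:
    """Parse a gene-association expression.

    ``boolean`` dialect: gene ids combined with ``or`` (isozymes) and
    parenthesized ``and`` groups (complexes), e.g. ``"(A and B) or C"``.
    ``list`` dialect: comma-separated gene ids with unknown semantics,
    e.g. ``"A, B"`` — kept distinct because some databases (EHMN, KEGG)
    have no syntax to distinguish complexes from isozymes.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty gene association")
    if dialect == "list":
        genes = [g.strip() for g in text.split(",")]
        if any(not g for g in genes):
            raise ParseError(f"empty gene id in list association {text!r}")
        if len(genes) == 1:
            return GeneAssociation.leaf(genes[0])
        return GeneAssociation.list_(*genes)
    if dialect != "boolean":
        raise ParseError(f"unknown association dialect {dialect!r}")

    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GeneAssociation:
        items = [parse_and()]
        while peek() == "or":
            take()
            items.append(parse_and())
        return items[0] if len(items) == 1 else GeneAssociation.or_(*items)

    def parse_and() -> GeneAssociation:
        items = [parse_atom()]
        while peek() == "and":
            take()
            items.append(parse_atom())
        return items[0] if len(items) == 1 else GeneAssociation.and_(*items)

    def parse_atom() -> GeneAssociation:
        tok = peek()
        if tok is None:
            raise ParseError(f"unexpected end of association {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ParseError(f"unbalanced parentheses in {text!r}")
            take()
            return inner
        if tok in (")", ",", "and", "or"):
            raise ParseError(f"unexpected token {tok!r} in {text!r}")
        return GeneAssociation.leaf(take())

    tree = parse_or()
    if pos != len(tokens):
        raise ParseError(f"trailing tokens in association {text!r}")
    return tree


# ---------------------------------------------------------------------------
# Status-flag serialization (id_status column)


def _format_status(status: dict[str, str], previous: dict[str, str]) -> str:
    parts = []
    for ns in sorted(status):
        flag = status[ns]
        if ns in previous:
            parts.append(f"{ns}={flag}:{previous[ns]}")
        else:
            parts.append(f"{ns}={flag}")
    return ";".join(parts)


def _parse_status(cell: str) -> tuple[dict[str, str], dict[str, str]]:
    status: dict[str, str] = {}
    previous: dict[str, str] = {}
    if not cell:
        return status, previous
    for part in cell.split(";"):
        ns, _, rest = part.partition("=")
        flag, _, prev = rest.partition(":")
        status[ns] = flag
        if prev:
            previous[ns] = prev
    return status, previous


# ---------------------------------------------------------------------------
# Reading


def _read_table(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.is_file():
        raise LoadError(f"missing mandatory table {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    return df


def _read_database(dirpath: Path) -> SourceDatabase:
    name = dirpath.name
    version = ""
    meta_path = dirpath / "database.tsv"
    if meta_path.is_file():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
        if len(meta):
            name = meta.iloc[0].get("name", name) or name
            version = meta.iloc[0].get("version", "") or ""
    db = SourceDatabase(name=name, version=version)

    mets = _read_table(dirpath / "metabolites.tsv", ["local_id", "primary_name"])
    for i, row in mets.iterrows():
        line = i + 2
        if not row["local_id"]:
            raise ValidationError(f"{dirpath / 'metabolites.tsv'}:{line}: empty local_id")
        status, previous = _parse_status(row.get("id_status", ""))
        ext = {
            ns: row[ns]
            for ns in METABOLITE_NAMESPACES
            if ns in mets.columns and row[ns]
        }
        rec = MetaboliteRecord(
            source_db=name,
            local_id=row["local_id"],
            primary_name=row["primary_name"],
            synonyms={s for s in row.get("synonyms", "").split("|") if s},
            chemical_formula=row.get("formula", "") or None,
            external_ids=ext,
            inchi=row.get("inchi", "") or None,
            smiles=row.get("smiles", "") or None,
            id_status=status,
            id_previous=previous,
        )
        db.add(rec)

    genes = _read_table(dirpath / "genes.tsv", ["local_id"])
    for i, row in genes.iterrows():
        status, previous = _parse_status(row.get("id_status", ""))
        rec = GeneRecord(
            source_db=name,
            local_id=row["local_id"],
            entrez=row.get("entrez", "") or None,
            ensembl=row.get("ensembl", "") or None,
            uniprot=row.get("uniprot", "") or None,
            hgnc_symbols={s for s in row.get("hgnc", "").split("|") if s},
            id_status=status,
            id_previous=previous,
        )
        db.add(rec)

    rxns = _read_table(dirpath / "reactions.tsv", ["local_id", "direction"])
    for i, row in rxns.iterrows():
        line = i + 2
        direction = row["direction"] or "unknown"
        try:
            rec = ReactionRecord(source_db=name, local_id=row["local_id"], direction=direction)
        except ValidationError as exc:
            raise ValidationError(f"{dirpath / 'reactions.tsv'}:{line}: {exc}") from None
        db.add(rec)

    parts = _read_table(
        dirpath / "participants.tsv", ["reaction_id", "metabolite_id", "side"]
    )
    for i, row in parts.iterrows():
        line = i + 2
        rxn = db.reactions.get(row["reaction_id"])
        if rxn is None:
            raise ValidationError(
                f"{dirpath / 'participants.tsv'}:{line}: unknown reaction "
                f"{row['reaction_id']!r}"
            )
        stoich = row.get("stoichiometry", "")
        try:
            p = Participant(
                metabolite_ref=row["metabolite_id"],
                side=row["side"],
                compartment=row.get("compartment", "") or None,
                stoichiometry=float(stoich) if stoich else None,
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{dirpath / 'participants.tsv'}:{line}: {exc}") from None
        rxn.participants.append(p)

    rgenes = _read_table(dirpath / "reaction_genes.tsv", ["reaction_id", "association_text"])
    for i, row in rgenes.iterrows():
        line = i + 2
        rxn = db.reactions.get(row["reaction_id"])
        if rxn is None:
            raise ValidationError(
                f"{dirpath / 'reaction_genes.tsv'}:{line}: unknown reaction "
                f"{row['reaction_id']!r}"
            )
        try:
            rxn.gene_association = parse_gene_association(
                row["association_text"], row.get("dialect", "") or "boolean"
            )
        except ParseError as exc:
            raise ValidationError(f"{dirpath / 'reaction_genes.tsv'}:{line}: {exc}") from None

    recs = _read_table(dirpath / "reaction_ec.tsv", ["reaction_id", "ec"])
    for i, row in recs.iterrows():
        line = i + 2
        rxn = db.reactions.get(row["reaction_id"])
        if rxn is None:
            raise ValidationError(
                f"{dirpath / 'reaction_ec.tsv'}:{line}: unknown reaction "
                f"{row['reaction_id']!r}"
            )
        try:
            ec = ECNumber.parse(row["ec"])
        except ParseError as exc:
            raise ValidationError(f"{dirpath / 'reaction_ec.tsv'}:{line}: {exc}") from None
        rxn.ec_numbers.add(ec)
        status_cell = row.get("status", "")
        if status_cell:
            flag, _, prev = status_cell.partition(":")
            rxn.ec_status[ec] = flag
            if prev:
                rxn.ec_previous[ec] = prev

    rpaths = _read_table(dirpath / "reaction_pathways.tsv", ["reaction_id", "pathway_id"])
    for i, row in rpaths.iterrows():
        line = i + 2
        rxn = db.reactions.get(row["reaction_id"])
        if rxn is None:
            raise ValidationError(
                f"{dirpath / 'reaction_pathways.tsv'}:{line}: unknown reaction "
                f"{row['reaction_id']!r}"
            )
        rxn.pathways.add(row["pathway_id"])

    paths = _read_table(dirpath / "pathways.tsv", ["pathway_id", "name"])
    for i, row in paths.iterrows():
        db.add(PathwayRecord(source_db=name, pathway_id=row["pathway_id"], name=row["name"]))

    return db


def read_corpus(root_directory) -> Corpus:
    """Load and validate a corpus from an interchange directory."""
    root = Path(root_directory)
    if not root.is_dir():
        raise LoadError(f"corpus directory not found: {root}")
    corpus = Corpus()
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        corpus.add_database(_read_database(sub))
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# Writing


def _fmt_stoich(v: Optional[float]) -> str:
    if v is None:
        return ""
    return f"{v:g}"


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_corpus(corpus: Corpus, root_directory) -> None:
    """Write a corpus; ``read_corpus(write_corpus(c))`` is record-identical
    and exports are byte-stable under the canonical sort order."""
    root = Path(root_directory)
    root.mkdir(parents=True, exist_ok=True)
    for db_name in corpus.db_names():
        db = corpus.databases[db_name]
        d = root / db_name
        d.mkdir(parents=True, exist_ok=True)

        _write_df(
            pd.DataFrame([{"name": db.name, "version": db.version}]),
            d / "database.tsv",
        )

        met_rows = []
        for m in sorted(db.metabolites.values(), key=lambda r: r.local_id):
            row = {
                "local_id": m.local_id,
                "primary_name": m.primary_name,
                "synonyms": "|".join(sorted(m.synonyms)),
                "formula": m.chemical_formula or "",
            }
            for ns in METABOLITE_NAMESPACES:
                row[ns] = m.external_ids.get(ns, "")
            row["inchi"] = m.inchi or ""
            row["smiles"] = m.smiles or ""
            row["id_status"] = _format_status(m.id_status, m.id_previous)
            met_rows.append(row)
        _write_df(pd.DataFrame(met_rows, columns=_MET_COLUMNS), d / "metabolites.tsv")

        gene_rows = []
        for g in sorted(db.genes.values(), key=lambda r: r.local_id):
            gene_rows.append(
                {
                    "local_id": g.local_id,
                    "entrez": g.entrez or "",
                    "ensembl": g.ensembl or "",
                    "uniprot": g.uniprot or "",
                    "hgnc": "|".join(sorted(g.hgnc_symbols)),
                    "id_status": _format_status(g.id_status, g.id_previous),
                }
            )
        _write_df(pd.DataFrame(gene_rows, columns=_GENE_COLUMNS), d / "genes.tsv")

        rxns = sorted(db.reactions.values(), key=lambda r: r.local_id)
        _write_df(
            pd.DataFrame(
                [{"local_id": r.local_id, "direction": r.direction} for r in rxns],
                columns=["local_id", "direction"],
            ),
            d / "reactions.tsv",
        )

        part_rows = []
        for r in rxns:
            for p in r.participants:
                part_rows.append(
                    {
                        "reaction_id": r.local_id,
                        "metabolite_id": p.metabolite_ref,
                        "side": p.side,
                        "compartment": p.compartment or "",
                        "stoichiometry": _fmt_stoich(p.stoichiometry),
                    }
                )
        _write_df(
            pd.DataFrame(
                part_rows,
                columns=["reaction_id", "metabolite_id", "side", "compartment", "stoichiometry"],
            ),
            d / "participants.tsv",
        )

        assoc_rows = []
        for r in rxns:
            if r.gene_association is not None:
                assoc_rows.append(
                    {
                        "reaction_id": r.local_id,
                        "association_text": r.gene_association.to_text(),
                        "dialect": r.gene_association.dialect,
                    }
                )
        _write_df(
            pd.DataFrame(assoc_rows, columns=["reaction_id", "association_text", "dialect"]),
            d / "reaction_genes.tsv",
        )

        ec_rows = []
        for r in rxns:
            for ec in sorted(r.ec_numbers):
                flag = r.ec_status.get(ec, "")
                prev = r.ec_previous.get(ec, "")
                ec_rows.append(
                    {
                        "reaction_id": r.local_id,
                        "ec": str(ec),
                        "status": f"{flag}:{prev}" if prev else flag,
                    }
                )
        _write_df(
            pd.DataFrame(ec_rows, columns=["reaction_id", "ec", "status"]),
            d / "reaction_ec.tsv",
        )

        pw_rows = []
        for r in rxns:
            for pw in sorted(r.pathways):
                pw_rows.append({"reaction_id": r.local_id, "pathway_id": pw})
        _write_df(
            pd.DataFrame(pw_rows, columns=["reaction_id", "pathway_id"]),
            d / "reaction_pathways.tsv",
        )

        _write_df(
            pd.DataFrame(
                [
                    {"pathway_id": p.pathway_id, "name": p.name}
                    for p in sorted(db.pathways.values(), key=lambda r: r.pathway_id)
                ],
                columns=["pathway_id", "name"],
            ),
            d / "pathways.tsv",
        )


# ---------------------------------------------------------------------------
# Identifier updates


def read_id_updates(path) -> list[IdUpdateTable]:
    """Read ``id_updates.tsv`` (kind, old, new_or_OBSOLETE) into one table
    per kind."""
    df = _read_table(Path(path), ["kind", "old", "new_or_OBSOLETE"])
    tables: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        tables.setdefault(row["kind"], {})[row["old"]] = row["new_or_OBSOLETE"]
    return [IdUpdateTable(kind=k, entries=v) for k, v in sorted(tables.items())]


def read_cid_sid(path) -> dict[str, str]:
    """Read the substance-id -> compound-id mapping (``cid_sid.tsv``)."""
    df = _read_table(Path(path), ["substance_id", "compound_id"])
    return dict(zip(df["substance_id"], df["compound_id"]))


def _update_value(entries: dict[str, str], value: str):
    """Return (new_value, flag, previous) or None when no entry applies."""
    if value not in entries:
        return None
    new = entries[value]
    if new == OBSOLETE:
        return (value, "obsolete", None)
    return (new, "transferred", value)


def apply_id_updates(corpus: Corpus, tables: Iterable[IdUpdateTable]) -> Corpus:
    """Transfer out-of-date identifiers/ECs to their current values.

    Entries mapping to ``OBSOLETE`` keep the stale value but flag it, which
    excludes it from all matching.  Idempotent: applying the same tables
    twice equals applying them once.
    """
    out = corpus.copy()
    for table in tables:
        if table.kind == "gene_id":
            for g in out.iter_genes():
                for ns in GENE_NAMESPACES:
                    value = getattr(g, ns)
                    if not value:
                        continue
                    hit = _update_value(table.entries, value)
                    if hit is None:
                        continue
                    new, flag, prev = hit
                    setattr(g, ns, new)
                    g.id_status[ns] = flag
                    if prev is not None:
                        g.id_previous[ns] = prev
        elif table.kind == "metabolite_id":
            for m in out.iter_metabolites():
                for ns in METABOLITE_NAMESPACES:
                    value = m.external_ids.get(ns)
                    if not value:
                        continue
                    hit = _update_value(table.entries, value)
                    if hit is None:
                        continue
                    new, flag, prev = hit
                    m.external_ids[ns] = new
                    m.id_status[ns] = flag
                    if prev is not None:
                        m.id_previous[ns] = prev
        elif table.kind == "ec_number":
            for r in out.iter_reactions():
                for ec in sorted(r.ec_numbers):
                    hit = _update_value(table.entries, str(ec))
                    if hit is None:
                        continue
                    new_text, flag, prev = hit
                    if flag == "obsolete":
                        r.ec_status[ec] = "obsolete"
                    else:
                        new_ec = ECNumber.parse(new_text)
                        r.ec_numbers.discard(ec)
                        r.ec_numbers.add(new_ec)
                        r.ec_status.pop(ec, None)
                        r.ec_status[new_ec] = "transferred"
                        r.ec_previous[new_ec] = prev
        else:  # pragma: no cover - IdUpdateTable already validates
            raise ConfigError(f"unknown update-table kind {table.kind!r}")
    out.invalidate_caches()
    return out


def convert_substance_ids(corpus: Corpus, cid_sid_map: dict[str, str]) -> Corpus:
    """Add PubChem Compound ids derived from PubChem Substance ids.

    Substance ids are depositor-specific and never used for matching; a
    mapped substance id contributes the depositor-independent compound id
    instead.  Unmapped substance ids pass through untouched."""
    out = corpus.copy()
    for m in out.iter_metabolites():
        sid = m.external_ids.get("pubchem_substance")
        if sid and sid in cid_sid_map and "pubchem_compound" not in m.external_ids:
            out_cid = cid_sid_map[sid]
            m.external_ids["pubchem_compound"] = out_cid
    out.invalidate_caches()
    return out
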