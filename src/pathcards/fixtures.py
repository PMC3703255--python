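"""Synthetic multi-database corpora with ground truth, and hand-coded
mini-corpora reproducing well-known cross-database conflict patterns.

``generate_corpus`` replicates one base metabolic network across several
synthetic source databases and perturbs each copy according to
configurable conflict rates, emulating the discrepancy classes observed
between real curated databases:

- *granularity splits* — one database describes a conversion in two steps
  via an intermediate where others use one;
- *protonation variants* — a metabolite written in a different charge
  state, with disjoint identifiers and an H-shifted formula;
- *alternative substrates* — an extra reaction variant with a different
  co-substrate in a subset of databases;
- *missing genes* — a database links no gene to a reaction;
- *isozyme/complex divergence* — databases disagree on the Boolean
  structure of the gene association;
- *identifier sparsity* and *synonym-only identity* — records that must be
  matched by name+formula rather than by shared identifiers.

The returned :class:`GroundTruth` records the intended identity classes
and per-reaction conflict labels, enabling parameter-recovery checks.

``paper_fixtures`` returns six small hand-built corpora (arginase,
ctps, cmpk1_ec, aconitase_steps, succinate_coa_ligase, deoxyuridine)
covering the canonical conflict case studies: ornithine granularity,
ammonia/ammonium protonation, IDP/ITP alternative substrates, EC
disagreement on one reaction, and multi-step lumping.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    ConfigError,
    Corpus,
    ECNumber,
    GeneAssociation,
    GeneRecord,
    MetaboliteRecord,
    Participant,
    PathwayRecord,
    ReactionRecord,
    SourceDatabase,
)

__all__ = ["FixtureConfig", "GroundTruth", "generate_corpus", "paper_fixtures", "partition"]

Key = tuple[str, str]

DB_LABELS = ("EHMN", "HumanCyc", "KEGG", "Reactome", "Recon1")


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic corpus.

    Rates are probabilities in [0, 1] applied per base reaction (conflict
    classes) or per record (identifier sparsity / synonym swaps).  The
    same seed and config always produce a byte-identical corpus.
    """

    n_databases: int = 5
    n_reactions: int = 12
    granularity_split: float = 0.0
    protonation_variant: float = 0.0
    alternative_substrate: float = 0.0
    missing_gene: float = 0.0
    isozyme_complex: float = 0.0
    id_sparsity: float = 0.0
    synonym_only: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_databases <= len(DB_LABELS)):
            raise ConfigError(f"n_databases must be 1..{len(DB_LABELS)}")
        if self.n_reactions < 1:
            raise ConfigError("n_reactions must be >= 1")
        for name in (
            "granularity_split", "protonation_variant", "alternative_substrate",
            "missing_gene", "isozyme_complex", "id_sparsity", "synonym_only",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"rate {name} must be in [0,1], got {v}")


@dataclass
class GroundTruth:
    """Intended identity structure of a generated corpus.

    ``*_class_of`` map record keys to base-entity labels; two records are
    truly identical iff they share a label.  ``conflict_labels`` lists the
    perturbations applied, each with its class, base reaction and target
    database(s)."""

    met_class_of: dict[Key, str] = field(default_factory=dict)
    gene_class_of: dict[Key, str] = field(default_factory=dict)
    reaction_class_of: dict[Key, str] = field(default_factory=dict)
    conflict_labels: list[dict] = field(default_factory=list)


def partition(class_of: dict) -> set[frozenset]:
    """Partition induced by a key->label map (for comparing classifications
    without caring about label spelling)."""
    groups: dict = {}
    for key, label in class_of.items():
        groups.setdefault(label, set()).add(key)
    return {frozenset(v) for v in groups.values()}


# ---------------------------------------------------------------------------
# Generator


def _base_formula(i: int) -> str:
    return f"C{i + 2}H{2 * (i + 2)}O{1 + i % 3}"


def generate_corpus(config: FixtureConfig) -> tuple[Corpus, GroundTruth]:
    """Build a synthetic corpus by replicating a base network across
    databases and perturbing the copies per the conflict rates."""
    config.validate()
    rng = random.Random(config.seed)
    db_names = list(DB_LABELS[: config.n_databases])

    n_met = config.n_reactions + 1
    # Base network: linear chain with occasional branches back to an
    # earlier metabolite, plus water on some reactions (exclusion fodder).
    base_edges = []  # (reaction index, substrate met, product met, has water)
    for i in range(config.n_reactions):
        src = i if i < 2 or rng.random() >= 0.3 else rng.randrange(i)
        base_edges.append((i, src, i + 1, rng.random() < 0.3))
    directions = [
        "forward" if rng.random() < 0.7 else "reversible"
        for _ in range(config.n_reactions)
    ]
    base_ecs = [
        ECNumber(1 + i % 6, 1 + (i // 2) % 9, 1 + i % 9, 1 + i)
        for i in range(config.n_reactions)
    ]

    # Per-reaction conflict draws (one draw per class, shared across dbs).
    def draw(rate: float) -> list[bool]:
        return [rng.random() < rate for _ in range(config.n_reactions)]

    do_split = draw(config.granularity_split)
    do_proton = draw(config.protonation_variant)
    do_alt = draw(config.alternative_substrate)
    do_nogene = draw(config.missing_gene)
    do_iso = draw(config.isozyme_complex)
    target_db = [rng.choice(db_names) for _ in range(config.n_reactions)]
    proton_side = [rng.choice(["substrate", "product"]) for _ in range(config.n_reactions)]

    truth = GroundTruth()
    corpus = Corpus()

    for db_name in db_names:
        db = SourceDatabase(name=db_name, version="synthetic")
        pathway = PathwayRecord(db_name, "PW1", f"{db_name} core pathway")
        db.add(pathway)

        def add_met(base_id: str, name: str, formula: str, kegg: str | None,
                    chebi: str | None = None, synonyms: tuple = ()) -> str:
            lid = f"M_{base_id}"
            drop_kegg = kegg is not None and rng.random() < config.id_sparsity
            use_alt_name = rng.random() < config.synonym_only
            primary = f"{name} ({db_name} name)" if use_alt_name else name
            syns = set(synonyms) | ({name} if use_alt_name else set())
            rec = MetaboliteRecord(
                source_db=db_name,
                local_id=lid,
                primary_name=primary,
                synonyms=syns,
                chemical_formula=formula,
                external_ids={
                    k: v
                    for k, v in (
                        ("kegg_compound", None if drop_kegg else kegg),
                        ("chebi", chebi),
                    )
                    if v
                },
            )
            db.add(rec)
            truth.met_class_of[rec.key] = base_id
            return lid

        water = add_met("h2o", "H2O", "H2O", "C00001")
        met_lid = {
            i: add_met(f"b{i:03d}", f"metabolite b{i}", _base_formula(i),
                       f"C9{i:04d}", chebi=f"CH{i:04d}")
            for i in range(n_met)
        }

        def add_gene(base_id: str, index: int, symbol: str) -> str:
            lid = f"G_{base_id}"
            if lid not in db.genes:
                rec = GeneRecord(
                    source_db=db_name,
                    local_id=lid,
                    entrez=str(100000 + index),
                    hgnc_symbols={symbol},
                )
                db.add(rec)
                truth.gene_class_of[rec.key] = base_id
            return lid

        for i, src, dst, has_water in base_edges:
            gene_lid = add_gene(f"g{i:03d}", i, f"GENE{i}")
            assoc: GeneAssociation | None = GeneAssociation.leaf(gene_lid)
            extra_lid = None
            if do_iso[i]:
                extra_lid = add_gene(f"g{i:03d}x", 1000 + i, f"GENE{i}X")
                if db_name == target_db[i]:
                    assoc = GeneAssociation.and_(
                        GeneAssociation.leaf(gene_lid), GeneAssociation.leaf(extra_lid)
                    )
                else:
                    assoc = GeneAssociation.or_(
                        GeneAssociation.leaf(gene_lid), GeneAssociation.leaf(extra_lid)
                    )
            if do_nogene[i] and db_name == target_db[i]:
                assoc = None

            sub_lid, prod_lid = met_lid[src], met_lid[dst]
            perturbed = False

            if do_proton[i] and db_name == target_db[i]:
                # replace one participant with a protonation variant:
                # disjoint ids, different name, formula shifted by one H
                which = proton_side[i]
                base_idx = src if which == "substrate" else dst
                formula = _base_formula(base_idx)
                c_part, rest = formula.split("H", 1)
                h_count = int(rest.split("O")[0])
                variant = MetaboliteRecord(
                    source_db=db_name,
                    local_id=f"M_b{base_idx:03d}_ion_r{i:03d}",
                    primary_name=f"metabolite b{base_idx} anion",
                    chemical_formula=f"{c_part}H{h_count - 1}{'O' + rest.split('O')[1]}",
                    external_ids={"chebi": f"CHX{i:04d}"},
                )
                db.add(variant)
                truth.met_class_of[variant.key] = f"b{base_idx:03d}__ion{i}"
                if which == "substrate":
                    sub_lid = variant.local_id
                else:
                    prod_lid = variant.local_id
                perturbed = True
                truth.conflict_labels.append(
                    {"class": "protonation_variant", "reaction": f"r{i:03d}",
                     "db": db_name}
                )

            def participants(sub: str, prod: str, with_water: bool) -> list[Participant]:
                parts = [
                    Participant(sub, "left"),
                    Participant(prod, "right"),
                ]
                if with_water:
                    parts.insert(1, Participant(water, "left"))
                return parts

            if do_split[i] and db_name == target_db[i]:
                # two-step description via a db-private intermediate
                inter = MetaboliteRecord(
                    source_db=db_name,
                    local_id=f"M_i{i:03d}",
                    primary_name=f"intermediate i{i} ({db_name})",
                    chemical_formula=_base_formula(src),
                    external_ids={"chebi": f"CHI{i:04d}"},
                )
                db.add(inter)
                truth.met_class_of[inter.key] = f"i{i:03d}__{db_name}"
                for step, (s, p) in enumerate(
                    ((sub_lid, inter.local_id), (inter.local_id, prod_lid))
                ):
                    r = ReactionRecord(
                        source_db=db_name,
                        local_id=f"R_r{i:03d}_s{step}",
                        participants=participants(s, p, has_water and step == 0),
                        direction=directions[i],
                        ec_numbers={base_ecs[i]},
                        gene_association=assoc,
                        pathways={"PW1"},
                    )
                    db.add(r)
                    truth.reaction_class_of[r.key] = f"r{i:03d}__split{db_name}s{step}"
                truth.conflict_labels.append(
                    {"class": "granularity_split", "reaction": f"r{i:03d}", "db": db_name}
                )
            else:
                r = ReactionRecord(
                    source_db=db_name,
                    local_id=f"R_r{i:03d}",
                    participants=participants(sub_lid, prod_lid, has_water),
                    direction=directions[i],
                    ec_numbers={base_ecs[i]},
                    gene_association=assoc,
                    pathways={"PW1"},
                )
                db.add(r)
                truth.reaction_class_of[r.key] = (
                    f"r{i:03d}__proton{db_name}" if perturbed else f"r{i:03d}"
                )

            if do_alt[i] and db_name in (db_names[0], target_db[i]):
                # alternative co-substrate variant, present in <=2 databases
                alt_sub = add_met(f"alt{i:03d}a", f"alt substrate a{i}",
                                  f"C{20 + i}H{40}O2", f"C8{i:04d}a")
                alt_prod = add_met(f"alt{i:03d}b", f"alt product b{i}",
                                   f"C{20 + i}H{40}O3", f"C8{i:04d}b")
                r = ReactionRecord(
                    source_db=db_name,
                    local_id=f"R_r{i:03d}_alt",
                    participants=[
                        Participant(sub_lid, "left"),
                        Participant(alt_sub, "left"),
                        Participant(prod_lid, "right"),
                        Participant(alt_prod, "right"),
                    ],
                    direction=directions[i],
                    ec_numbers={base_ecs[i]},
                    gene_association=assoc,
                    pathways={"PW1"},
                )
                db.add(r)
                truth.reaction_class_of[r.key] = f"r{i:03d}__alt"
                if db_name == db_names[0]:
                    truth.conflict_labels.append(
                        {"class": "alternative_substrate", "reaction": f"r{i:03d}",
                         "db": db_name}
                    )
            if do_nogene[i] and db_name == target_db[i]:
                truth.conflict_labels.append(
                    {"class": "missing_gene", "reaction": f"r{i:03d}", "db": db_name}
                )
            if do_iso[i] and db_name == target_db[i]:
                truth.conflict_labels.append(
                    {"class": "isozyme_complex", "reaction": f"r{i:03d}", "db": db_name}
                )

        corpus.add_database(db)

    corpus.validate()
    return corpus, truth


# ---------------------------------------------------------------------------
# Hand-coded mini-corpora


def _met(db, lid, name, formula=None, kegg=None, chebi=None, synonyms=(), cas=None):
    db.add(
        MetaboliteRecord(
            source_db=db.name, local_id=lid, primary_name=name,
            synonyms=set(synonyms), chemical_formula=formula,
            external_ids={
                k: v
                for k, v in (("kegg_compound", kegg), ("chebi", chebi), ("cas", cas))
                if v
            },
        )
    )
    return lid


def _gene(db, lid, symbol, entrez=None, ensembl=None):
    db.add(
        GeneRecord(
            source_db=db.name, local_id=lid, entrez=entrez, ensembl=ensembl,
            hgnc_symbols={symbol},
        )
    )
    return lid


def _rxn(db, lid, left, right, direction="forward", ecs=(), assoc=None,
         pathways=(), compartment=None):
    parts = [Participant(m, "left", compartment=compartment) for m in left] + [
        Participant(m, "right", compartment=compartment) for m in right
    ]
    db.add(
        ReactionRecord(
            source_db=db.name, local_id=lid, participants=parts,
            direction=direction, ec_numbers={ECNumber.parse(e) for e in ecs},
            gene_association=assoc, pathways=set(pathways),
        )
    )


def _arginase() -> Corpus:
    """Two databases describing arginine hydrolysis; one writes the product
    as the generic 'ornithine', the other as 'l-ornithine' with a different
    compound id — a granularity conflict yielding a 66% overlap."""
    corpus = Corpus()

    recon = SourceDatabase("Recon1", version="1")
    recon.add(PathwayRecord("Recon1", "PW_urea", "Urea cycle / amino group metabolism"))
    arg = _met(recon, "arg_L", "l-arginine", "C6H14N4O2", kegg="C00062")
    h2o = _met(recon, "h2o", "H2O", "H2O", kegg="C00001")
    orn = _met(recon, "orn", "ornithine", "C5H12N2O2", kegg="C90001")
    urea = _met(recon, "urea", "urea", "CH4N2O", kegg="C00086")
    arg1 = _gene(recon, "ARG1", "ARG1", entrez="383")
    arg2 = _gene(recon, "ARG2", "ARG2", entrez="384")
    _rxn(recon, "ARGN_c", [arg, h2o], [orn, urea], ecs=["3.5.3.1"],
         assoc=GeneAssociation.leaf(arg1), pathways=["PW_urea"], compartment="c")
    _rxn(recon, "ARGN_m", [arg, h2o], [orn, urea], ecs=["3.5.3.1"],
         assoc=GeneAssociation.leaf(arg2), pathways=["PW_urea"], compartment="m")
    corpus.add_database(recon)

    reactome = SourceDatabase("Reactome", version="36")
    reactome.add(PathwayRecord("Reactome", "PW_urea", "Urea Cycle"))
    arg = _met(reactome, "arg_L", "l-arginine", "C6H14N4O2", kegg="C00062")
    h2o = _met(reactome, "h2o", "water", "H2O", kegg="C00001")
    lorn = _met(reactome, "orn_L", "l-ornithine", "C5H12N2O2", kegg="C00077")
    urea = _met(reactome, "urea", "urea", "CH4N2O", kegg="C00086")
    arg1 = _gene(reactome, "ARG1", "ARG1", entrez="383")
    arg2 = _gene(reactome, "ARG2", "ARG2", entrez="384")
    _rxn(reactome, "ARGSUCC_c", [arg, h2o], [lorn, urea], ecs=["3.5.3.1"],
         assoc=GeneAssociation.leaf(arg1), pathways=["PW_urea"], compartment="c")
    _rxn(reactome, "ARGSUCC_m", [arg, h2o], [lorn, urea], ecs=["3.5.3.1"],
         assoc=GeneAssociation.leaf(arg2), pathways=["PW_urea"], compartment="m")
    corpus.add_database(reactome)

    corpus.validate()
    return corpus


def _ctps() -> Corpus:
    """CTP synthase across five databases: EHMN and KEGG carry both the
    glutamine- and the ammonia-dependent reaction, Reactome and HumanCyc
    only the glutamine one, Recon1 only the ammonium one (ammonia vs
    ammonium is a protonation conflict with disjoint identifiers)."""
    corpus = Corpus()

    shared = dict(
        gln=("gln", "l-glutamine", "C5H10N2O3", "C00064"),
        glu=("glu", "l-glutamate", "C5H9NO4", "C00025"),
        atp=("atp", "ATP", "C10H16N5O13P3", "C00002"),
        utp=("utp", "UTP", "C9H15N2O15P3", "C00075"),
        adp=("adp", "ADP", "C10H15N5O10P2", "C00008"),
        ctp=("ctp", "CTP", "C9H16N3O14P3", "C00063"),
        pi=("pi", "orthophosphate", "H3PO4", "C00009"),
        h2o=("h2o", "H2O", "H2O", "C00001"),
        h=("h", "H+", "H", "C00080"),
    )

    def build(db_name, gene_ids, glutamine, aminated, amine_met, pathway_name,
              glutamine_gene="CTPS"):
        db = SourceDatabase(db_name)
        db.add(PathwayRecord(db_name, "PW1", pathway_name))
        lids = {
            k: _met(db, lid, name, formula, kegg=kegg)
            for k, (lid, name, formula, kegg) in shared.items()
        }
        if amine_met == "ammonia":
            lids["amine"] = _met(db, "nh3", "ammonia", "NH3", kegg="C00014",
                                 chebi="16134")
        else:
            lids["amine"] = _met(db, "nh4", "ammonium", "NH4", chebi="28938")
        entrez, ensembl = gene_ids
        ctps = _gene(db, "CTPS", "CTPS", entrez=entrez, ensembl=ensembl)
        if glutamine:
            gene = ctps
            if glutamine_gene != "CTPS":
                gene = _gene(db, glutamine_gene, glutamine_gene, entrez="56474")
            _rxn(db, "R_gln",
                 [lids["gln"], lids["atp"], lids["utp"], lids["h2o"]],
                 [lids["glu"], lids["adp"], lids["ctp"], lids["pi"]],
                 ecs=["6.3.4.2"], assoc=GeneAssociation.leaf(gene), pathways=["PW1"])
        if aminated:
            _rxn(db, "R_amine",
                 [lids["amine"], lids["atp"], lids["utp"]],
                 [lids["adp"], lids["ctp"], lids["pi"], lids["h"]],
                 ecs=["6.3.4.2"], assoc=GeneAssociation.leaf(ctps), pathways=["PW1"])
        corpus.add_database(db)

    build("EHMN", ("1503", None), True, True, "ammonia", "Pyrimidine metabolism")
    build("KEGG", ("1503", "ENSG00000171793"), True, True, "ammonia",
          "Pyrimidine metabolism")
    build("Reactome", (None, "ENSG00000171793"), True, False, "ammonia",
          "Pyrimidine biosynthesis")
    build("HumanCyc", ("1503", None), True, False, "ammonia",
          "UTP and CTP de novo biosynthesis")
    # Recon1's glutamine reaction is linked to the paralog CTPS2 only
    build("Recon1", ("1503", None), True, True, "ammonium", "Nucleotides",
          glutamine_gene="CTPS2")
    corpus.validate()
    return corpus


def _cmpk1_ec() -> Corpus:
    """One and the same phosphotransfer reaction linked to three different
    EC numbers (same gene) by three databases."""
    corpus = Corpus()
    ecs = {"EHMN": "2.7.4.14", "KEGG": "2.7.4.22", "Reactome": "2.7.4.4"}
    for db_name, ec in ecs.items():
        db = SourceDatabase(db_name)
        db.add(PathwayRecord(db_name, "PW1", "Pyrimidine metabolism"))
        atp = _met(db, "atp", "ATP", "C10H16N5O13P3", kegg="C00002")
        ump = _met(db, "ump", "UMP", "C9H13N2O9P", kegg="C00105")
        adp = _met(db, "adp", "ADP", "C10H15N5O10P2", kegg="C00008")
        udp = _met(db, "udp", "UDP", "C9H14N2O12P2", kegg="C00015")
        cmpk1 = _gene(db, "CMPK1", "CMPK1", entrez="51727")
        _rxn(db, "R_ump", [atp, ump], [adp, udp], direction="reversible",
             ecs=[ec], assoc=GeneAssociation.leaf(cmpk1), pathways=["PW1"])
        corpus.add_database(db)
    corpus.validate()
    return corpus


def _aconitase_steps() -> Corpus:
    """Citrate-to-isocitrate in one step (Recon1) versus two steps via
    cis-aconitate (KEGG); same gene and EC number throughout."""
    corpus = Corpus()

    def mets(db):
        return {
            "cit": _met(db, "cit", "citrate", "C6H8O7", kegg="C00158"),
            "icit": _met(db, "icit", "isocitrate", "C6H8O7", kegg="C00311"),
            "acon": _met(db, "acon", "cis-aconitate", "C6H6O6", kegg="C00417"),
            "h2o": _met(db, "h2o", "H2O", "H2O", kegg="C00001"),
        }

    recon = SourceDatabase("Recon1")
    recon.add(PathwayRecord("Recon1", "PW1", "Citric acid cycle"))
    m = mets(recon)
    aco = _gene(recon, "ACO2", "ACO2", entrez="50")
    _rxn(recon, "R_acont", [m["cit"]], [m["icit"]], direction="reversible",
         ecs=["4.2.1.3"], assoc=GeneAssociation.leaf(aco), pathways=["PW1"])
    corpus.add_database(recon)

    kegg = SourceDatabase("KEGG")
    kegg.add(PathwayRecord("KEGG", "PW1", "Citrate cycle (TCA cycle)"))
    m = mets(kegg)
    aco = _gene(kegg, "ACO2", "ACO2", entrez="50")
    _rxn(kegg, "R_step1", [m["cit"]], [m["acon"], m["h2o"]], direction="reversible",
         ecs=["4.2.1.3"], assoc=GeneAssociation.leaf(aco), pathways=["PW1"])
    _rxn(kegg, "R_step2", [m["acon"], m["h2o"]], [m["icit"]], direction="reversible",
         ecs=["4.2.1.3"], assoc=GeneAssociation.leaf(aco), pathways=["PW1"])
    corpus.add_database(kegg)

    corpus.validate()
    return corpus


def _succinate_coa_ligase() -> Corpus:
    """EC 6.2.1.4 across five databases: all share the GDP-forming
    reaction; EHMN and KEGG additionally carry an IDP/ITP variant
    (alternative co-substrates).  Gene products form a complex."""
    corpus = Corpus()

    def build(db_name, with_itp, pathway, boolean_dialect, direction):
        db = SourceDatabase(db_name)
        if pathway:
            db.add(PathwayRecord(db_name, "PW1", pathway))
        gtp = _met(db, "gtp", "GTP", "C10H16N5O14P3", kegg="C00044")
        gdp = _met(db, "gdp", "GDP", "C10H15N5O11P2", kegg="C00035")
        succ = _met(db, "succ", "succinate", "C4H6O4", kegg="C00042")
        coa = _met(db, "coa", "CoA", "C21H36N7O16P3S", kegg="C00010")
        scoa = _met(db, "succoa", "succinyl-CoA", "C25H40N7O19P3S", kegg="C00091")
        pi = _met(db, "pi", "orthophosphate", "H3PO4", kegg="C00009")
        g1 = _gene(db, "SUCLG1", "SUCLG1", entrez="8802")
        g2 = _gene(db, "SUCLG2", "SUCLG2", entrez="8801")
        if boolean_dialect:
            assoc = GeneAssociation.and_(
                GeneAssociation.leaf(g1), GeneAssociation.leaf(g2)
            )
        else:
            assoc = GeneAssociation.list_(g1, g2)
        _rxn(db, "R_gdp", [gtp, succ, coa], [gdp, scoa, pi], direction=direction,
             ecs=["6.2.1.4"], assoc=assoc, pathways=["PW1"] if pathway else [])
        if with_itp:
            itp = _met(db, "itp", "ITP", "C10H15N4O14P3", kegg="C00081")
            idp = _met(db, "idp", "IDP", "C10H14N4O11P2", kegg="C00104")
            _rxn(db, "R_idp", [itp, succ, coa], [idp, scoa, pi], direction=direction,
                 ecs=["6.2.1.4"], assoc=assoc, pathways=["PW1"] if pathway else [])
        corpus.add_database(db)

    build("EHMN", True, "Citric acid cycle", False, "reversible")
    build("KEGG", True, "Citrate cycle (TCA cycle)", False, "reversible")
    build("Reactome", False, "Citric acid cycle (TCA cycle)", True, "reversible")
    build("Recon1", False, "Citric acid cycle", True, "reversible")
    build("HumanCyc", False, None, True, "unknown")
    corpus.validate()
    return corpus


def _deoxyuridine() -> Corpus:
    """Deoxyuridine phosphorolysis in all five databases with the classic
    disagreement pattern: four different EC numbers (one incomplete), no
    gene at all in HumanCyc, and isozyme lists that only partly agree."""
    corpus = Corpus()

    def mets(db):
        return (
            _met(db, "duri", "deoxyuridine", "C9H12N2O5", kegg="C00526"),
            _met(db, "pi", "phosphate", "H3PO4", kegg="C00009"),
            _met(db, "drib1p", "2-deoxy-d-ribose 1-phosphate", "C5H11O7P",
                 kegg="C00672"),
            _met(db, "ura", "uracil", "C4H4N2O2", kegg="C00106"),
        )

    ehmn = SourceDatabase("EHMN")
    ehmn.add(PathwayRecord("EHMN", "PW1", "Pyrimidine metabolism"))
    duri, pi, drib, ura = mets(ehmn)
    pnp = _gene(ehmn, "PNP", "PNP", entrez="4860")
    tymp = _gene(ehmn, "TYMP", "TYMP", entrez="1890")
    upp1 = _gene(ehmn, "UPP1", "UPP1", entrez="7378")
    _rxn(ehmn, "R1", [duri, pi], [drib, ura], direction="reversible",
         ecs=["2.4.2.1", "2.4.2.4"], assoc=GeneAssociation.list_(pnp, tymp, upp1),
         pathways=["PW1"])
    corpus.add_database(ehmn)

    recon = SourceDatabase("Recon1")
    recon.add(PathwayRecord("Recon1", "PW1", "Nucleotides"))
    duri, pi, drib, ura = mets(recon)
    pnp = _gene(recon, "PNP", "PNP", entrez="4860")
    upp2 = _gene(recon, "UPP2", "UPP2", entrez="151531")
    _rxn(recon, "R1", [duri, pi], [drib, ura], direction="reversible",
         ecs=[], assoc=GeneAssociation.or_(
             GeneAssociation.leaf(pnp), GeneAssociation.leaf(upp2)),
         pathways=["PW1"])
    corpus.add_database(recon)

    humancyc = SourceDatabase("HumanCyc")
    humancyc.add(
        PathwayRecord("HumanCyc", "PW1",
                      "salvage pathways of pyrimidine deoxyribonucleotides")
    )
    duri, pi, drib, ura = mets(humancyc)
    _rxn(humancyc, "R1", [duri, pi], [drib, ura], direction="reversible",
         ecs=["2.4.2.23"], assoc=None, pathways=["PW1"])
    corpus.add_database(humancyc)

    kegg = SourceDatabase("KEGG")
    kegg.add(PathwayRecord("KEGG", "PW1", "Pyrimidine metabolism"))
    duri, pi, drib, ura = mets(kegg)
    pnp = _gene(kegg, "PNP", "PNP", entrez="4860")
    tymp = _gene(kegg, "TYMP", "TYMP", entrez="1890")
    _rxn(kegg, "R1", [duri, pi], [drib, ura], direction="reversible",
         ecs=["2.4.2.1"], assoc=GeneAssociation.leaf(pnp), pathways=["PW1"])
    _rxn(kegg, "R2", [duri, pi], [drib, ura], direction="reversible",
         ecs=["2.4.2.4"], assoc=GeneAssociation.leaf(tymp), pathways=["PW1"])
    corpus.add_database(kegg)

    reactome = SourceDatabase("Reactome")
    reactome.add(PathwayRecord("Reactome", "PW1", "Pyrimidine catabolism"))
    reactome.add(PathwayRecord("Reactome", "PW2", "Pyrimidine salvage reactions"))
    duri, pi, drib, ura = mets(reactome)
    upp1 = _gene(reactome, "UPP1", "UPP1", entrez="7378")
    upp2 = _gene(reactome, "UPP2", "UPP2", entrez="151531")
    tymp = _gene(reactome, "TYMP", "TYMP", entrez="1890")
    _rxn(reactome, "R1", [duri, pi], [drib, ura], direction="reversible",
         ecs=["2.4.2.3"], assoc=GeneAssociation.or_(
             GeneAssociation.leaf(upp1), GeneAssociation.leaf(upp2)),
         pathways=["PW1", "PW2"])
    _rxn(reactome, "R2", [duri, pi], [drib, ura], direction="reversible",
         ecs=["2.4.2.-"], assoc=GeneAssociation.leaf(tymp), pathways=["PW1", "PW2"])
    corpus.add_database(reactome)

    corpus.validate()
    return corpus


def paper_fixtures() -> dict[str, Corpus]:
    """Six named mini-corpora encoding the canonical conflict case studies."""
    return {
        "arginase": _arginase(),
        "ctps": _ctps(),
        "cmpk1_ec": _cmpk1_ec(),
        "aconitase_steps": _aconitase_steps(),
        "succinate_coa_ligase": _succinate_coa_ligase(),
        "deoxyuridine": _deoxyuridine(),
    }
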