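"""Metabolite fate, dead-end detection, membership tables, statistics."""

import random

import pytest

from pathcards import identity, reactions as rx
from pathcards.fixtures import FixtureConfig, generate_corpus
from pathcards.model import (
    Corpus,
    GeneAssociation,
    MetaboliteRecord,
    NotFoundError,
    Participant,
    PathwayRecord,
    ReactionRecord,
    SourceDatabase,
)
from pathcards.network import (
    corpus_stats,
    dead_end_metabolites,
    metabolite_fate,
    pathway_membership_tables,
    presence_overview,
)


def chain_corpus(direction="forward"):
    """A -> B -> C in a single database."""
    corpus = Corpus()
    db = SourceDatabase("db1")
    for lid, name in [("A", "met A"), ("B", "met B"), ("C", "met C")]:
        db.add(MetaboliteRecord("db1", lid, name, chemical_formula="CH4",
                                external_ids={"kegg_compound": f"C_{lid}"}))
    db.add(ReactionRecord("db1", "r1",
                          [Participant("A", "left"), Participant("B", "right")],
                          direction=direction))
    db.add(ReactionRecord("db1", "r2",
                          [Participant("B", "left"), Participant("C", "right")],
                          direction=direction))
    corpus.add_database(db)
    corpus.validate()
    return corpus


def brute_force_dead_ends(corpus, db_name, exclusion):
    """Independent recount: walk every reaction of the database and track
    producing/consuming roles per metabolite class."""
    met_classes = identity.metabolite_classes(corpus)
    roles = {}
    for r in corpus.databases[db_name].reactions.values():
        for p in r.participants:
            cid = met_classes.class_of[(db_name, p.metabolite_ref)]
            if cid in exclusion:
                continue
            produced, consumed = roles.setdefault(cid, [False, False])
            if r.direction in ("reversible", "unknown"):
                roles[cid] = [True, True]
            elif p.side == "right":
                roles[cid][0] = True
            else:
                roles[cid][1] = True
    out = {}
    for cid, (produced, consumed) in roles.items():
        if produced and not consumed:
            out[cid] = "produced_only"
        elif consumed and not produced:
            out[cid] = "consumed_only"
    return out


class TestDeadEnds:
    def test_linear_forward_chain(self):
        corpus = chain_corpus("forward")
        reports = {r.metabolite_class: r.status for r in dead_end_metabolites(corpus, "db1")}
        met_classes = identity.metabolite_classes(corpus)
        a = met_classes.class_of[("db1", "A")]
        c = met_classes.class_of[("db1", "C")]
        b = met_classes.class_of[("db1", "B")]
        assert reports[a] == "consumed_only"
        assert reports[c] == "produced_only"
        assert b not in reports

    def test_reversible_reaction_creates_no_dead_ends(self):
        corpus = chain_corpus("reversible")
        assert dead_end_metabolites(corpus, "db1") == []

    def test_unknown_direction_counts_as_reversible(self):
        corpus = chain_corpus("unknown")
        assert dead_end_metabolites(corpus, "db1") == []

    def test_currency_species_not_reported_by_default(self, arginase):
        reports = dead_end_metabolites(arginase, "Recon1")
        met_classes = identity.metabolite_classes(arginase)
        water = met_classes.class_of[("Recon1", "h2o")]
        assert water not in {r.metabolite_class for r in reports}
        with_currency = dead_end_metabolites(arginase, "Recon1", apply_exclusion=False)
        assert water in {r.metabolite_class for r in with_currency}

    @pytest.mark.parametrize("seed", range(8))
    def test_random_corpora_equal_bruteforce_recount(self, seed):
        rng = random.Random(seed)
        corpus, _ = generate_corpus(
            FixtureConfig(
                seed=seed,
                n_databases=rng.randint(1, 4),
                n_reactions=rng.randint(3, 15),
                granularity_split=rng.random() * 0.5,
                protonation_variant=rng.random() * 0.5,
                missing_gene=rng.random() * 0.5,
            )
        )
        exclusion = rx.default_exclusion(corpus)
        for db_name in corpus.db_names():
            got = {
                r.metabolite_class: r.status
                for r in dead_end_metabolites(corpus, db_name)
            }
            assert got == brute_force_dead_ends(corpus, db_name, exclusion)

    def test_witnesses_consistent_with_status(self):
        corpus = chain_corpus("forward")
        for rep in dead_end_metabolites(corpus, "db1"):
            assert rep.witness_reactions
            assert rep.status in ("produced_only", "consumed_only")

    def test_stable_under_reaction_reordering(self):
        corpus = chain_corpus("forward")
        db = corpus.databases["db1"]
        db.reactions = dict(reversed(list(db.reactions.items())))
        corpus.invalidate_caches()
        reordered = {(r.metabolite_class, r.status) for r in dead_end_metabolites(corpus, "db1")}
        assert reordered == {
            (r.metabolite_class, r.status)
            for r in dead_end_metabolites(chain_corpus("forward"), "db1")
        }


class TestMetaboliteFate:
    def test_per_database_reaction_lists(self, ctps):
        fate = metabolite_fate(ctps, "l-glutamine")
        assert {db for db, info in fate.items() if info["reactions"]} == {
            "EHMN", "HumanCyc", "KEGG", "Reactome", "Recon1"
        }

    def test_dead_end_flag_matches_reports(self, arginase):
        fate = metabolite_fate(arginase, "urea")
        for db_name, info in fate.items():
            reports = {
                r.metabolite_class: r.status
                for r in dead_end_metabolites(arginase, db_name)
            }
            met_classes = identity.metabolite_classes(arginase)
            cid = met_classes.class_of[(db_name, "urea")]
            assert info["dead_end"] == reports.get(cid)

    def test_unresolved_query_raises(self, arginase):
        with pytest.raises(NotFoundError):
            metabolite_fate(arginase, "unobtainium")

    def test_listed_reactions_resolve_to_cards(self, arginase):
        from pathcards.cards import reaction_card

        fate = metabolite_fate(arginase, "l-arginine")
        for db_name, info in fate.items():
            for rid in info["reactions"]:
                assert reaction_card(arginase, (db_name, rid)).rows


class TestPathwayMembership:
    def test_row_counts_for_simple_reaction(self):
        corpus = Corpus()
        db = SourceDatabase("d")
        for lid in ("m1", "m2", "m3"):
            db.add(MetaboliteRecord("d", lid, f"met {lid}"))
        for g in ("g1", "g2"):
            db.add(__import__("pathcards.model", fromlist=["GeneRecord"]).GeneRecord("d", g))
        db.add(PathwayRecord("d", "pw", "some pathway"))
        db.add(
            ReactionRecord(
                "d", "r",
                [Participant("m1", "left"), Participant("m2", "left"),
                 Participant("m3", "right")],
                gene_association=GeneAssociation.or_(
                    GeneAssociation.leaf("g1"), GeneAssociation.leaf("g2")
                ),
                pathways={"pw"},
            )
        )
        corpus.add_database(db)
        genes_df, mets_df = pathway_membership_tables(corpus)
        assert len(genes_df) == 2
        assert len(mets_df) == 3

    def test_entity_in_no_pathway_contributes_no_row(self, corpora):
        succ = corpora["succinate_coa_ligase"]
        genes_df, mets_df = pathway_membership_tables(succ)
        assert "HumanCyc" not in set(genes_df["source_db"])
        assert "HumanCyc" not in set(mets_df["source_db"])

    def test_totals_equal_bruteforce_join(self, deoxyuridine):
        genes_df, mets_df = pathway_membership_tables(deoxyuridine)
        expected_genes = set()
        expected_mets = set()
        for r in deoxyuridine.iter_reactions():
            db = deoxyuridine.databases[r.source_db]
            for pw in r.pathways:
                pname = db.pathways[pw].name
                if r.gene_association:
                    for g in r.gene_association.genes():
                        expected_genes.add((r.source_db, g, pname))
                for p in r.participants:
                    expected_mets.add((r.source_db, p.metabolite_ref, pname))
        assert set(map(tuple, genes_df.itertuples(index=False))) == expected_genes
        assert set(map(tuple, mets_df.itertuples(index=False))) == expected_mets


class TestCorpusStats:
    def test_schema_and_counts(self, deoxyuridine):
        df = corpus_stats(deoxyuridine)
        assert list(df.columns) == ["database", "genes", "ec_numbers", "reactions", "pathways"]
        row = df.set_index("database").loc["Reactome"]
        assert row["reactions"] == 2
        assert row["ec_numbers"] == 2
        assert row["pathways"] == 2

    def test_duplicate_ec_links_counted_once(self, deoxyuridine):
        df = corpus_stats(deoxyuridine).set_index("database")
        assert df.loc["EHMN", "ec_numbers"] == 2  # two ECs on one reaction

    def test_empty_database_all_zero(self):
        corpus = Corpus()
        corpus.add_database(SourceDatabase("empty"))
        df = corpus_stats(corpus)
        assert df.iloc[0][["genes", "ec_numbers", "reactions", "pathways"]].sum() == 0

    def test_invariant_to_record_order(self, deoxyuridine):
        reordered = deoxyuridine.copy()
        db = reordered.databases["KEGG"]
        db.reactions = dict(reversed(list(db.reactions.items())))
        assert corpus_stats(reordered).equals(corpus_stats(deoxyuridine))


class TestPresenceOverview:
    def test_consensus_entities_span_all_databases(self, deoxyuridine):
        matrices = presence_overview(deoxyuridine)
        rxn = matrices["reaction"]
        assert len(rxn) == 1  # one exact-match class
        assert rxn.iloc[0].all()

    def test_near_variants_occupy_separate_rows(self, arginase):
        rxn = presence_overview(arginase)["reaction"]
        assert len(rxn) == 2
        assert list(rxn.sum(axis=1)) == [1, 1]

    def test_every_row_has_a_true_cell_and_row_sums_recount(self, succinate):
        matrices = presence_overview(succinate)
        for kind, df in matrices.items():
            assert (df.sum(axis=1) >= 1).all()
        ec_df = matrices["ec"]
        assert ec_df.loc["6.2.1.4"].sum() == 5
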