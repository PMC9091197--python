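"""Knowledge-graph assembly, evidence, rankings, similarity, repurposing."""

import itertools
import logging

import numpy as np
import pytest

from herbkg.graph import (
    EvidenceRecord,
    KGEntity,
    KGRelation,
    KnowledgeGraph,
    assemble_graph,
    degree_rankings,
    disease_profile,
    evidence_query,
    gene_profile,
    herb_similarity,
    rank_similar_herbs,
    repurposing_candidates,
    to_networkx,
    write_csv_tables,
    write_graphml,
)
from herbkg.ontology import RELATION_SIGNATURES, EntityType, RelationType
from herbkg.pubtator import AnnotatedDocument, EntityMention, RelationAnnotation


def make_kg(triples) -> KnowledgeGraph:
    """Build a graph directly from (rtype, head_id, tail_id) triples; entity
    types are inferred from the signature, ids prefixed by type letter."""
    kg = KnowledgeGraph()
    for rtype, head, tail in triples:
        rtype = RelationType(rtype)
        head_t, tail_t = RELATION_SIGNATURES[rtype]
        for eid, etype in ((head, head_t), (tail, tail_t)):
            kg.entities.setdefault(eid, KGEntity(eid, etype, {eid}))
        kg.relations[(rtype, head, tail)] = KGRelation(
            rtype, head, tail, [EvidenceRecord("1", f"{head} and {tail}.")]
        )
    return kg


def _case_study_doc() -> AnnotatedDocument:
    """A miniature of the oxymatrine abstract: herb, chemical, genes, disease."""
    pmid = "27882228"
    title = "Oxymatrine and microglial inflammation."
    abstract = (
        "Oxymatrine (OMT) is an alkaloid extracted from Sophora flavescens and "
        "has anti-inflammatory properties. Western blot analysis and ELISA showed "
        "that OMT decreased the expression and release of HSP60 by LPS-activated "
        "BV2 cells. OMT may therefore offer substantial therapeutic potential for "
        "treating neurodegenerative diseases in multiple models."
    )
    text = f"{title} {abstract}"

    def mention(surface, etype, eid, occurrence=0):
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(surface, start + 1)
        return EntityMention(pmid, start, start + len(surface), surface, etype, eid)

    return AnnotatedDocument(
        pmid, title, abstract,
        mentions=(
            mention("Oxymatrine", "Chemical", "C023412"),
            mention("Sophora flavescens", "Herb", "32476"),
            mention("OMT", "Chemical", "C023412", occurrence=1),
            mention("HSP60", "Gene", "G3329"),
            mention("neurodegenerative diseases", "Disease", "D019636"),
        ),
        relations=(
            RelationAnnotation(pmid, "HHC", "32476", "C023412"),
            RelationAnnotation(pmid, "CAG", "C023412", "G3329"),
            RelationAnnotation(pmid, "CAD", "C023412", "D019636"),
        ),
    )


class TestAssembly:
    def test_case_study_edges_and_evidence_sentences(self):
        kg = assemble_graph([_case_study_doc()])
        assert (RelationType.HHC, "32476", "C023412") in kg.relations
        hhc = evidence_query(kg, "32476", "C023412", "HHC")
        assert "alkaloid extracted from Sophora flavescens" in hhc[0].sentence
        cag = evidence_query(kg, "C023412", "G3329", "CAG")
        assert "OMT decreased the expression and release of HSP60" in cag[0].sentence

    def test_duplicate_triplet_across_documents_reinforces_support(self):
        doc = _case_study_doc()
        import dataclasses
        doc2 = dataclasses.replace(
            doc, pmid="99999999",
            mentions=tuple(dataclasses.replace(m, pmid="99999999") for m in doc.mentions),
            relations=tuple(dataclasses.replace(r, pmid="99999999") for r in doc.relations),
        )
        kg = assemble_graph([doc, doc2])
        rel = kg.relations[(RelationType.HHC, "32476", "C023412")]
        assert rel.support == 2 and len(rel.evidence) == 2

    def test_planted_graph_recovered_exactly(self, corpus):
        docs, truth = corpus
        kg = assemble_graph(docs)
        assert set(kg.relations) == truth.relations
        for eid, ent in kg.entities.items():
            assert ent.etype is truth.entity_types[eid]

    def test_signature_violations_rejected_and_logged(self, caplog):
        pmid = "3"
        doc = AnnotatedDocument(
            pmid, "T", "Genovar and Genovar interact.",
            mentions=(
                EntityMention(pmid, 2, 9, "Genovar", "Gene", "G1"),
                EntityMention(pmid, 14, 21, "Genovar", "Gene", "G2"),
            ),
            relations=(RelationAnnotation(pmid, "HHC", "G1", "G2"),),
        )
        with caplog.at_level(logging.WARNING):
            kg = assemble_graph([doc])
        assert kg.relations == {}
        assert "violates signature" in caplog.text

    def test_all_stored_relations_satisfy_signatures(self, corpus):
        docs, _ = corpus
        kg = assemble_graph(docs)
        for (rtype, head, tail) in kg.relations:
            head_t, tail_t = RELATION_SIGNATURES[rtype]
            assert kg.entities[head].etype is head_t
            assert kg.entities[tail].etype is tail_t

    def test_whole_abstract_fallback_is_flagged(self):
        pmid = "4"
        title = "Split evidence."
        abstract = "Herbaxa was studied. Separately, Chemarin was isolated."
        text = f"{title} {abstract}"
        doc = AnnotatedDocument(
            pmid, title, abstract,
            mentions=(
                EntityMention(pmid, text.index("Herbaxa"), text.index("Herbaxa") + 7,
                              "Herbaxa", "Herb", "H1"),
                EntityMention(pmid, text.index("Chemarin"), text.index("Chemarin") + 8,
                              "Chemarin", "Chemical", "C1"),
            ),
            relations=(RelationAnnotation(pmid, "HHC", "H1", "C1"),),
        )
        kg = assemble_graph([doc])
        (record,) = evidence_query(kg, "H1", "C1", "HHC")
        assert record.whole_abstract


class TestRankings:
    def test_herb_gene_counts_traverse_chemicals(self):
        kg = make_kg([
            ("HHC", "H1", "C1"), ("HHC", "H1", "C2"),
            ("CAG", "C1", "G1"), ("CAG", "C1", "G2"), ("CAG", "C2", "G3"),
            ("HHC", "H2", "C3"), ("CAG", "C3", "G1"),
        ])
        assert degree_rankings(kg, "herb_by_genes") == [("H1", 3), ("H2", 1)]

    def test_gene_by_herbs_is_the_reverse_view(self):
        kg = make_kg([
            ("HHC", "H1", "C1"), ("HHC", "H2", "C1"), ("CAG", "C1", "G1"),
        ])
        assert degree_rankings(kg, "gene_by_herbs") == [("G1", 2)]

    def test_disease_rankings_use_direct_treatment_edges(self):
        kg = make_kg([
            ("HTD", "H1", "D1"), ("HTD", "H1", "D2"), ("HTD", "H2", "D1"),
        ])
        assert degree_rankings(kg, "herb_by_diseases") == [("H1", 2), ("H2", 1)]
        assert degree_rankings(kg, "disease_by_herbs") == [("D1", 2), ("D2", 1)]

    def test_k_clamps_to_available_entities(self):
        kg = make_kg([("HTD", "H1", "D1")])
        assert degree_rankings(kg, "herb_by_diseases", k=10) == [("H1", 1)]

    def test_empty_graph_ranks_nothing(self):
        assert degree_rankings(KnowledgeGraph(), "herb_by_genes") == []

    def test_unknown_query_rejected(self):
        with pytest.raises(ValueError):
            degree_rankings(KnowledgeGraph(), "herb_by_planets")


class TestEvidenceQuery:
    def test_absent_relation_returns_empty(self):
        kg = make_kg([("HHC", "H1", "C1")])
        assert evidence_query(kg, "H1", "C9", "HHC") == []

    def test_evidence_count_equals_support_for_distinct_pmids(self, corpus):
        docs, _ = corpus
        kg = assemble_graph(docs)
        for rel in kg.relations.values():
            pmids = [e.pmid for e in rel.evidence]
            if len(set(pmids)) == len(pmids):
                assert rel.support == len(rel.evidence)


class TestSimilarity:
    def _kg_with_profiles(self, sg_i, sg_j, sd_i, sd_j):
        triples = []
        for herb, genes, diseases in (("Hi", sg_i, sd_i), ("Hj", sg_j, sd_j)):
            chem = f"C_{herb}"
            for g in genes:
                triples += [("HHC", herb, chem), ("CAG", chem, g)]
            for d in diseases:
                triples.append(("HTD", herb, d))
            if not genes and not diseases:
                triples.append(("HHC", herb, chem))
        return make_kg(triples)

    def test_half_sum_of_jaccard_terms(self):
        kg = self._kg_with_profiles({"g1", "g2", "g3"}, {"g2", "g3"}, {"d1"}, {"d1"})
        assert herb_similarity(kg, "Hi", "Hj") == pytest.approx(0.5 * (2 / 3 + 1))

    def test_identical_nonempty_profiles_score_one(self):
        kg = self._kg_with_profiles({"g1"}, {"g1"}, {"d1"}, {"d1"})
        assert herb_similarity(kg, "Hi", "Hj") == 1.0

    def test_disjoint_profiles_score_zero(self):
        kg = self._kg_with_profiles({"g1"}, {"g2"}, {"d1"}, {"d2"})
        assert herb_similarity(kg, "Hi", "Hj") == 0.0

    def test_empty_union_term_contributes_zero(self):
        kg = self._kg_with_profiles({"g1"}, {"g1"}, set(), set())
        assert herb_similarity(kg, "Hi", "Hj") == pytest.approx(0.5)

    def test_absent_herb_is_an_error(self):
        with pytest.raises(ValueError, match="not in graph"):
            herb_similarity(make_kg([("HHC", "H1", "C1")]), "H1", "H9")

    def test_similarity_symmetric_and_bounded(self, corpus):
        docs, _ = corpus
        kg = assemble_graph(docs)
        herbs = kg.herbs()
        for a, b in itertools.combinations(herbs, 2):
            s = herb_similarity(kg, a, b)
            assert s == herb_similarity(kg, b, a)
            assert 0.0 <= s <= 1.0

    def test_ranking_matches_brute_force_pairwise_scores(self, corpus):
        docs, _ = corpus
        kg = assemble_graph(docs)
        herbs = kg.herbs()
        target = herbs[0]
        ranked = rank_similar_herbs(kg, target, k=5)
        brute = sorted(
            ((h, herb_similarity(kg, target, h)) for h in herbs if h != target),
            key=lambda t: (-t[1], t[0]),
        )[:5]
        assert ranked == brute

    def test_single_herb_graph_has_empty_ranking(self):
        kg = make_kg([("HHC", "H1", "C1")])
        assert rank_similar_herbs(kg, "H1") == []


class TestRepurposing:
    def test_gene_mediated_candidate_found(self):
        kg = make_kg([("GID", "G1", "D1"), ("CAG", "C1", "G1")])
        assert repurposing_candidates(kg, "D1") == ["C1"]

    def test_disease_without_gene_links_has_no_candidates(self):
        kg = make_kg([("CAD", "C1", "D1")])
        assert repurposing_candidates(kg, "D1") == []

    def test_directly_linked_chemicals_are_excluded(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            triples = {("GID", "G1", "D1")}
            chems = [f"C{i}" for i in range(6)]
            linked = set()
            for c in chems:
                if rng.random() < 0.7:
                    triples.add(("CAG", c, "G1"))
                if rng.random() < 0.5:
                    triples.add(("CAD", c, "D1"))
                    linked.add(c)
            kg = make_kg(sorted(triples))
            for c in repurposing_candidates(kg, "D1"):
                assert c not in linked

    def test_candidates_ranked_by_shared_gene_count(self):
        kg = make_kg([
            ("GID", "G1", "D1"), ("GID", "G2", "D1"),
            ("CAG", "C1", "G1"), ("CAG", "C1", "G2"), ("CAG", "C2", "G1"),
        ])
        assert repurposing_candidates(kg, "D1") == ["C1", "C2"]

    def test_absent_disease_is_an_error(self):
        with pytest.raises(ValueError, match="not in graph"):
            repurposing_candidates(KnowledgeGraph(), "D404")


class TestExport:
    def test_graphml_and_csv_outputs(self, corpus, tmp_path):
        docs, _ = corpus
        kg = assemble_graph(docs)
        g = to_networkx(kg)
        assert g.number_of_nodes() == len(kg.entities)
        assert g.number_of_edges() == len(kg.relations)
        write_graphml(kg, tmp_path / "kg.graphml")
        write_csv_tables(kg, tmp_path / "nodes.csv", tmp_path / "edges.csv")
        edges = (tmp_path / "edges.csv").read_text().strip().split("\n")
        assert len(edges) == len(kg.relations) + 1
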