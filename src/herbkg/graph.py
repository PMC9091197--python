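"""Evidence-backed knowledge-graph assembly and analytics.

Extracted relation triplets are deduplicated into a typed graph whose edges
carry evidence: for every occurrence, the sentence of the source abstract in
which both endpoints appear (falling back, flagged, to the whole abstract
when the endpoints never share a sentence).  A relation's *support* is the
number of distinct articles contributing evidence — a relation confirmed by
several studies is reinforced.

Analytics mirror the downstream uses of such a graph:

* degree rankings — herbs reaching the most genes (via their chemicals),
  genes reached by the most herbs, herbs treating the most diseases, and
  diseases treated by the most herbs;
* evidence queries returning the supporting sentences of a relation;
* herb functional similarity
  ``sim(i,j) = 1/2 (|SG_i ∩ SG_j|/|SG_i ∪ SG_j| + |SD_i ∩ SD_j|/|SD_i ∪ SD_j|)``
  where ``SG`` is the gene set reachable through the herb's chemicals and
  ``SD`` the disease set the herb treats;
* gene-mediated drug repurposing: chemicals acting on a disease's genes but
  not yet linked to the disease itself.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from ._util import split_sentences
from .ontology import (
    RELATION_SIGNATURES,
    EntityType,
    RelationType,
    coerce_entity_type,
    coerce_relation,
)
from .pubtator import AnnotatedDocument

logger = logging.getLogger(__name__)

__all__ = [
    "KGEntity",
    "EvidenceRecord",
    "KGRelation",
    "KnowledgeGraph",
    "assemble_graph",
    "degree_rankings",
    "evidence_query",
    "herb_similarity",
    "rank_similar_herbs",
    "repurposing_candidates",
    "to_networkx",
    "write_graphml",
    "write_csv_tables",
]

RelationKey = tuple[RelationType, str, str]


@dataclass
class KGEntity:
    """One graph node: a concept id with a fixed type and its surface forms."""

    entity_id: str
    etype: EntityType
    names: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class EvidenceRecord:
    """A supporting sentence from one article.

    ``whole_abstract`` flags the fallback case where the endpoints never
    co-occur in a single sentence and the whole abstract is the evidence.
    """

    pmid: str
    sentence: str
    whole_abstract: bool = False

    def __post_init__(self) -> None:
        if not self.sentence:
            raise ValueError("evidence sentence must be non-empty")


@dataclass
class KGRelation:
    """A deduplicated typed edge with its evidence list."""

    rtype: RelationType
    head_id: str
    tail_id: str
    evidence: list[EvidenceRecord] = field(default_factory=list)

    @property
    def support(self) -> int:
        """Number of distinct articles backing the relation."""
        return len({e.pmid for e in self.evidence})


@dataclass
class KnowledgeGraph:
    """Typed entities plus relations keyed by (rtype, head id, tail id)."""

    entities: dict[str, KGEntity] = field(default_factory=dict)
    relations: dict[RelationKey, KGRelation] = field(default_factory=dict)

    def herbs(self) -> list[str]:
        return sorted(
            eid for eid, e in self.entities.items() if e.etype is EntityType.HERB
        )

    def neighbors(
        self, entity_id: str, rtype: RelationType, forward: bool = True
    ) -> set[str]:
        """Partner ids over edges of one type, from head (forward) or tail."""
        out = set()
        for (rt, head, tail) in self.relations:
            if rt is not rtype:
                continue
            if forward and head == entity_id:
                out.add(tail)
            elif not forward and tail == entity_id:
                out.add(head)
        return out


def _evidence_for(doc: AnnotatedDocument, head, tail) -> EvidenceRecord:
    text = doc.text
    for sent in split_sentences(text):
        if head.text in sent and tail.text in sent:
            return EvidenceRecord(doc.pmid, sent)
    return EvidenceRecord(doc.pmid, text, whole_abstract=True)


def assemble_graph(docs: Iterable[AnnotatedDocument]) -> KnowledgeGraph:
    """Merge extracted relations from many documents into one graph.

    Each occurrence of a triplet contributes one evidence record; triplets
    whose endpoint types violate the ontology signature are rejected and
    logged, never stored.
    """
    kg = KnowledgeGraph()
    for doc in docs:
        for rel in doc.relations:
            rtype = coerce_relation(rel.rtype)
            if rtype is RelationType.NEG:
                continue
            head = doc.mention_by_id(rel.head_id)
            tail = doc.mention_by_id(rel.tail_id)
            if head is None or tail is None:
                logger.warning(
                    "doc %s: %s(%s, %s) endpoint unresolved; rejected",
                    doc.pmid, rtype, rel.head_id, rel.tail_id,
                )
                continue
            try:
                sig = (coerce_entity_type(head.etype), coerce_entity_type(tail.etype))
            except ValueError:
                sig = None
            if sig != RELATION_SIGNATURES[rtype]:
                logger.warning(
                    "doc %s: %s(%s, %s) violates signature; rejected",
                    doc.pmid, rtype, rel.head_id, rel.tail_id,
                )
                continue
            for m in (head, tail):
                ent = kg.entities.setdefault(
                    m.entity_id, KGEntity(m.entity_id, coerce_entity_type(m.etype))
                )
                ent.names.add(m.text)
            key: RelationKey = (rtype, rel.head_id, rel.tail_id)
            edge = kg.relations.setdefault(key, KGRelation(rtype, rel.head_id, rel.tail_id))
            edge.evidence.append(_evidence_for(doc, head, tail))
    return kg


# ---------------------------------------------------------------------------
# analytics

def _genes_via_chemicals(kg: KnowledgeGraph, herb_id: str) -> set[str]:
    genes: set[str] = set()
    for chem in kg.neighbors(herb_id, RelationType.HHC):
        genes |= kg.neighbors(chem, RelationType.CAG)
    return genes


def degree_rankings(
    kg: KnowledgeGraph, query: str, k: Union[int, None] = None
) -> list[tuple[str, int]]:
    """Descending partner-count rankings, ties alphabetical by entity id.

    Herb-gene counts traverse herb -> chemical -> gene paths (a herb reaches
    a gene through a contained chemical that associates with it); herb-
    disease counts use direct treats-disease edges.
    """
    if query == "herb_by_genes":
        items = [(h, len(_genes_via_chemicals(kg, h))) for h in kg.herbs()]
    elif query == "gene_by_herbs":
        gene_to_herbs: dict[str, set[str]] = {
            eid: set() for eid, e in kg.entities.items() if e.etype is EntityType.GENE
        }
        for h in kg.herbs():
            for g in _genes_via_chemicals(kg, h):
                gene_to_herbs.setdefault(g, set()).add(h)
        items = [(g, len(hs)) for g, hs in gene_to_herbs.items()]
    elif query == "herb_by_diseases":
        items = [(h, len(kg.neighbors(h, RelationType.HTD))) for h in kg.herbs()]
    elif query == "disease_by_herbs":
        disease_to_herbs: dict[str, set[str]] = {
            eid: set() for eid, e in kg.entities.items() if e.etype is EntityType.DISEASE
        }
        for (rt, head, tail) in kg.relations:
            if rt is RelationType.HTD:
                disease_to_herbs.setdefault(tail, set()).add(head)
        items = [(d, len(hs)) for d, hs in disease_to_herbs.items()]
    else:
        raise ValueError(f"unknown ranking query: {query!r}")
    items = [it for it in items if it[1] > 0]
    items.sort(key=lambda t: (-t[1], t[0]))
    return items if k is None else items[:k]


def evidence_query(
    kg: KnowledgeGraph,
    head_id: str,
    tail_id: str,
    rtype: Union[str, RelationType],
) -> list[EvidenceRecord]:
    """All evidence for a relation, ordered by pmid; empty when absent."""
    rel = kg.relations.get((coerce_relation(rtype), head_id, tail_id))
    if rel is None:
        return []
    return sorted(rel.evidence, key=lambda e: e.pmid)


def gene_profile(kg: KnowledgeGraph, herb_id: str) -> set[str]:
    """SG: genes reachable through the herb's contained chemicals."""
    return _genes_via_chemicals(kg, herb_id)


def disease_profile(kg: KnowledgeGraph, herb_id: str) -> set[str]:
    """SD: diseases the herb treats directly."""
    return kg.neighbors(herb_id, RelationType.HTD)


def _require_herb(kg: KnowledgeGraph, herb_id: str) -> None:
    ent = kg.entities.get(herb_id)
    if ent is None or ent.etype is not EntityType.HERB:
        raise ValueError(f"herb {herb_id!r} not in graph")


def herb_similarity(kg: KnowledgeGraph, herb_i: str, herb_j: str) -> float:
    """Functional similarity: half-sum of the gene-set and disease-set
    Jaccard indices of the two herbs.  A term whose union is empty
    contributes 0 and is flagged in the log."""
    _require_herb(kg, herb_i)
    _require_herb(kg, herb_j)
    score = 0.0
    for name, profile in (("gene", gene_profile), ("disease", disease_profile)):
        a, b = profile(kg, herb_i), profile(kg, herb_j)
        union = a | b
        if not union:
            logger.info(
                "empty %s-profile union for (%s, %s); term contributes 0",
                name, herb_i, herb_j,
            )
            continue
        score += 0.5 * len(a & b) / len(union)
    return score


def rank_similar_herbs(
    kg: KnowledgeGraph, herb_id: str, k: Union[int, None] = None
) -> list[tuple[str, float]]:
    """All other herbs scored against ``herb_id``, descending, ties
    alphabetical."""
    _require_herb(kg, herb_id)
    scored = [
        (other, herb_similarity(kg, herb_id, other))
        for other in kg.herbs()
        if other != herb_id
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored if k is None else scored[:k]


def repurposing_candidates(kg: KnowledgeGraph, disease_id: str) -> list[str]:
    """Chemicals linked to the disease's genes but not to the disease.

    Step 1: locate the disease.  Step 2: collect its genes over
    gene-influences-disease edges.  Step 3: collect chemicals associated
    with those genes that have *no* direct chemical-acts-on-disease edge to
    the disease.  Ranked by number of shared genes descending, ties
    alphabetical.
    """
    ent = kg.entities.get(disease_id)
    if ent is None or ent.etype is not EntityType.DISEASE:
        raise ValueError(f"disease {disease_id!r} not in graph")
    genes = kg.neighbors(disease_id, RelationType.GID, forward=False)
    direct = {
        head
        for (rt, head, tail) in kg.relations
        if rt is RelationType.CAD and tail == disease_id
    }
    shared: dict[str, int] = {}
    for g in genes:
        for chem in kg.neighbors(g, RelationType.CAG, forward=False):
            if chem in direct:
                continue
            shared[chem] = shared.get(chem, 0) + 1
    ranked = sorted(shared.items(), key=lambda t: (-t[1], t[0]))
    return [chem for chem, _ in ranked]


# ---------------------------------------------------------------------------
# export

def to_networkx(kg: KnowledgeGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for eid, ent in kg.entities.items():
        g.add_node(eid, etype=ent.etype.value, names="|".join(sorted(ent.names)))
    for (rtype, head, tail), rel in kg.relations.items():
        g.add_edge(
            head, tail, key=rtype.value, rtype=rtype.value,
            support=rel.support,
            pmids="|".join(sorted({e.pmid for e in rel.evidence})),
        )
    return g


def write_graphml(kg: KnowledgeGraph, path: Union[str, Path]) -> None:
    nx.write_graphml(to_networkx(kg), str(path))


def write_csv_tables(
    kg: KnowledgeGraph, nodes_path: Union[str, Path], edges_path: Union[str, Path]
) -> None:
    """Node/edge tables suitable for bulk import into graph databases."""
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["entity_id", "etype", "names"])
        for eid in sorted(kg.entities):
            ent = kg.entities[eid]
            w.writerow([eid, ent.etype.value, "|".join(sorted(ent.names))])
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["rtype", "head_id", "tail_id", "support", "evidence_pmids"])
        for key in sorted(kg.relations, key=lambda k: (k[0].value, k[1], k[2])):
            rel = kg.relations[key]
            w.writerow([
                rel.rtype.value, rel.head_id, rel.tail_id, rel.support,
                "|".join(sorted({e.pmid for e in rel.evidence})),
            ])
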