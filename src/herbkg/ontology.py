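"""The herb ontology: entity types, typed relation labels, and corpus screening.

The ontology covers four bio-entity types — herbs, the chemicals extracted
from them, the genes those chemicals act on, and the diseases herbs treat —
and five directed relation labels with fixed type signatures:

====== ========================== ====================
label  meaning                    signature
====== ========================== ====================
HHC    herb has compound chemical (Herb, Chemical)
HTD    herb treats disease        (Herb, Disease)
CAD    chemical acts on disease   (Chemical, Disease)
CAG    chemical associates gene   (Chemical, Gene)
GID    gene influences disease    (Gene, Disease)
====== ========================== ====================

A sixth label, ``Neg``, marks non-relations in the classification task and
carries no signature.  Only signature-valid triplets may enter the knowledge
graph.

Upstream named-entity recognition tags six types (Gene, Disease, Chemical,
Mutation, Species, Cellline); :func:`adapt_ner_annotations` maps that tag set
onto the ontology by dropping mutations/cell lines and re-labelling species
as herbs when they match a curated domain vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "EntityType",
    "RelationType",
    "POSITIVE_RELATIONS",
    "RELATION_SIGNATURES",
    "DomainVocabulary",
    "relation_signature",
    "is_valid_triplet",
    "adapt_ner_annotations",
    "screen_abstract",
]


class EntityType(str, Enum):
    """Closed four-member enumeration of ontology entity types."""

    HERB = "Herb"
    CHEMICAL = "Chemical"
    DISEASE = "Disease"
    GENE = "Gene"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationType(str, Enum):
    """The five positive relation labels plus the negative class."""

    HHC = "HHC"
    HTD = "HTD"
    CAD = "CAD"
    CAG = "CAG"
    GID = "GID"
    NEG = "Neg"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


POSITIVE_RELATIONS: tuple[RelationType, ...] = (
    RelationType.HHC,
    RelationType.HTD,
    RelationType.CAD,
    RelationType.CAG,
    RelationType.GID,
)

#: Fixed (head type, tail type) signature of each positive relation label.
RELATION_SIGNATURES: dict[RelationType, tuple[EntityType, EntityType]] = {
    RelationType.HHC: (EntityType.HERB, EntityType.CHEMICAL),
    RelationType.HTD: (EntityType.HERB, EntityType.DISEASE),
    RelationType.CAD: (EntityType.CHEMICAL, EntityType.DISEASE),
    RelationType.CAG: (EntityType.CHEMICAL, EntityType.GENE),
    RelationType.GID: (EntityType.GENE, EntityType.DISEASE),
}

#: Raw NER tags that the ontology does not model and that adaptation removes.
_DISABLED_RAW_TAGS = frozenset({"mutation", "cellline", "cell line"})


def coerce_relation(rtype: Union[str, RelationType]) -> RelationType:
    """Return ``rtype`` as a :class:`RelationType`, accepting label strings."""
    if isinstance(rtype, RelationType):
        return rtype
    try:
        return RelationType(rtype)
    except ValueError:
        # tolerate the trailing-dot spelling of the negative label
        if str(rtype).rstrip(".").lower() == "neg":
            return RelationType.NEG
        raise ValueError(f"unknown relation label: {rtype!r}") from None


def coerce_entity_type(etype: Union[str, EntityType]) -> EntityType:
    if isinstance(etype, EntityType):
        return etype
    try:
        return EntityType(etype)
    except ValueError:
        raise ValueError(f"unknown entity type: {etype!r}") from None


def relation_signature(
    rtype: Union[str, RelationType],
) -> Union[tuple[EntityType, EntityType], str]:
    """Return the (head, tail) type signature of a relation label.

    The negative label carries no signature and yields the sentinel
    string ``"any"``.
    """
    rtype = coerce_relation(rtype)
    if rtype is RelationType.NEG:
        return "any"
    return RELATION_SIGNATURES[rtype]


def is_valid_triplet(head, tail, rtype: Union[str, RelationType]) -> bool:
    """True iff the mention pair's entity types satisfy ``rtype``'s signature.

    ``head`` and ``tail`` are entity mentions (anything exposing ``etype``)
    carrying post-adaptation types.  ``Neg`` validates any pair.
    """
    sig = relation_signature(rtype)
    if sig == "any":
        return True
    try:
        head_t = coerce_entity_type(head.etype)
        tail_t = coerce_entity_type(tail.etype)
    except ValueError:
        return False
    return (head_t, tail_t) == sig


def normalize_term(term: str) -> str:
    """Vocabulary normalization: lowercase with collapsed whitespace."""
    return " ".join(term.lower().split())


@dataclass
class DomainVocabulary:
    """A curated list of herb and chemical terms used for corpus screening.

    Terms are stored normalized (lowercase, collapsed whitespace).  A term may
    optionally be typed as ``herb`` or ``chemical``; untyped terms match
    either role.  Matching is whole-word: "rice" does not match inside
    "price".
    """

    terms: set[str] = field(default_factory=set)
    #: normalized term -> roles ({"herb"}, {"chemical"} or both)
    roles: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {normalize_term(t) for t in self.terms}
        if any(not t for t in self.terms):
            raise ValueError("vocabulary contains an empty term")
        self.roles = {normalize_term(k): set(v) for k, v in self.roles.items()}

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "DomainVocabulary":
        return cls(terms=set(terms))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "DomainVocabulary":
        """Load a one-term-per-line list; an optional second tab-separated
        column types the term as ``herb`` or ``chemical``."""
        terms: set[str] = set()
        roles: dict[str, set[str]] = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            term = normalize_term(parts[0])
            if not term:
                continue
            terms.add(term)
            if len(parts) > 1 and parts[1].strip():
                roles.setdefault(term, set()).add(parts[1].strip().lower())
        return cls(terms=terms, roles=roles)

    def _pattern(self, term: str) -> re.Pattern:
        # whole-word phrase match on the normalized text
        return re.compile(r"(?<!\w)" + re.escape(term) + r"(?!\w)")

    def contains_match(self, text: str) -> bool:
        """Whole-word occurrence of any vocabulary term in ``text``."""
        hay = normalize_term(text)
        return any(self._pattern(t).search(hay) for t in self.terms)

    def has_term(self, text: str) -> bool:
        """Exact (normalized) membership test for a candidate mention text."""
        return normalize_term(text) in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def adapt_ner_annotations(doc, vocab: DomainVocabulary):
    """Map raw NER output onto the ontology's four entity types.

    Mutation and cell-line mentions are discarded.  A species mention is kept
    and re-typed as ``Herb`` when its (normalized) surface text is in the
    domain vocabulary, and discarded otherwise; its concept identifier is
    preserved.  Gene, chemical and disease mentions pass through unchanged.
    The operation is idempotent: a document already using ontology types is
    returned with the same mention list.
    """
    kept = []
    for m in doc.mentions:
        tag = str(m.etype).strip()
        low = tag.lower()
        if low in _DISABLED_RAW_TAGS:
            continue
        if low == "species":
            if vocab.has_term(m.text):
                kept.append(replace(m, etype=EntityType.HERB.value))
            continue
        try:
            kept.append(replace(m, etype=coerce_entity_type(tag).value))
        except ValueError:
            continue  # any other raw tag is outside the ontology
    return replace(doc, mentions=kept)


def screen_abstract(doc, vocab: DomainVocabulary) -> bool:
    """Corpus screening: does the abstract mention a vocabulary term?

    True iff any vocabulary phrase occurs (normalized, whole-word) in the
    concatenated title + abstract text.  An empty vocabulary matches nothing.
    """
    if not vocab.terms:
        return False
    return vocab.contains_match(doc.text)
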