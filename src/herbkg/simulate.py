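"""Seeded synthetic-corpus generation for end-to-end testing.

Real inputs to the pipeline are annotated PubMed abstracts; this module
fabricates structurally faithful stand-ins: documents with exact gold
offsets, typed entity mentions, planted relations, and a known ground-truth
graph.  Each planted relation appears as a template sentence
``<head> <cue word> <tail> ...`` whose cue word is a deterministic function
of the relation type, so the relation task over generated corpora is
linearly separable by design — model-capacity and token-attribution claims
become decidable tests.  Filler sentences place type-compatible but
unrelated entity pairs, giving negative sampling something to find.

The generator makes no attempt at linguistic realism; entity names are
synthetic coinages chosen so that no name is a substring of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import REExample
from .ontology import (
    POSITIVE_RELATIONS,
    RELATION_SIGNATURES,
    EntityType,
    RelationType,
)
from .pubtator import AnnotatedDocument, EntityMention, RelationAnnotation

__all__ = [
    "DEFAULT_CUE_WORDS",
    "GeneratorSpec",
    "GroundTruth",
    "generate_corpus",
    "make_separable_re_set",
]

#: Deterministic trigger word for each relation label (the negative class
#: gets a non-relational verb).
DEFAULT_CUE_WORDS: dict[RelationType, str] = {
    RelationType.HHC: "contained",
    RelationType.HTD: "alleviated",
    RelationType.CAD: "suppressed",
    RelationType.CAG: "modulated",
    RelationType.GID: "aggravated",
    RelationType.NEG: "accompanied",
}

_NAME_PREFIXES = {
    EntityType.HERB: ("Herbaxa", "H"),
    EntityType.CHEMICAL: ("Chemarin", "C"),
    EntityType.DISEASE: ("Malvexia", "D"),
    EntityType.GENE: ("Genovar", "G"),
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic corpus.

    ``vocab_sizes`` caps each entity type's name pool (max 676); cue words
    must be unique per relation type; ``negative_density`` is the fraction
    of abstract sentences that pair unrelated compatible entities.
    """

    seed: int = 0
    n_docs: int = 30
    sentences_per_doc: int = 3
    vocab_sizes: dict[EntityType, int] = field(
        default_factory=lambda: {
            EntityType.HERB: 12,
            EntityType.CHEMICAL: 12,
            EntityType.DISEASE: 8,
            EntityType.GENE: 8,
        }
    )
    relation_mix: dict[RelationType, float] = field(
        default_factory=lambda: {r: 1.0 for r in POSITIVE_RELATIONS}
    )
    cue_words: dict[RelationType, str] = field(
        default_factory=lambda: dict(DEFAULT_CUE_WORDS)
    )
    negative_density: float = 0.3

    def __post_init__(self) -> None:
        if self.n_docs < 0 or self.sentences_per_doc < 0:
            raise ValueError("counts must be >= 0")
        if any(v < 0 for v in self.vocab_sizes.values()):
            raise ValueError("vocabulary sizes must be >= 0")
        cues = list(self.cue_words.values())
        if len(set(cues)) != len(cues):
            raise ValueError("cue words must be unique per relation type")
        if not 0.0 <= self.negative_density <= 1.0:
            raise ValueError("negative_density must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure: the relation set and every entity's type."""

    relations: set[tuple[RelationType, str, str]] = field(default_factory=set)
    entity_types: dict[str, EntityType] = field(default_factory=dict)
    entity_names: dict[str, str] = field(default_factory=dict)


def _letters(i: int) -> str:
    # aa, ab, ... : fixed width so no name is a prefix of another
    return chr(ord("a") + i // 26) + chr(ord("a") + i % 26)


def _pools(spec: GeneratorSpec):
    pools: dict[EntityType, list[tuple[str, str]]] = {}
    for etype, size in spec.vocab_sizes.items():
        if size > 676:
            raise ValueError("vocabulary size capped at 676 per type")
        prefix, id_prefix = _NAME_PREFIXES[etype]
        pools[etype] = [
            (f"{prefix}{_letters(i)}", f"{id_prefix}{i:03d}") for i in range(size)
        ]
    return pools


class _DocBuilder:
    """Accumulates text while recording exact mention offsets."""

    def __init__(self, pmid: str):
        self.pmid = pmid
        self.parts: list[str] = []
        self.length = 0
        self.mentions: list[EntityMention] = []

    def add_text(self, text: str) -> None:
        self.parts.append(text)
        self.length += len(text)

    def add_entity(self, name: str, etype: EntityType, eid: str) -> None:
        self.mentions.append(
            EntityMention(self.pmid, self.length, self.length + len(name),
                          name, etype.value, eid)
        )
        self.add_text(name)

    @property
    def text(self) -> str:
        return "".join(self.parts)


def generate_corpus(spec: GeneratorSpec) -> tuple[list[AnnotatedDocument], GroundTruth]:
    """Generate annotated documents plus their planted ground truth.

    Every document validates cleanly (mention slices match their offsets,
    relation endpoints resolve); the ground-truth graph is the union of
    planted relations across documents.  Byte-identical output for the same
    spec.
    """
    rng = np.random.default_rng(spec.seed)
    pools = _pools(spec)
    truth = GroundTruth()
    rtypes = [r for r, wgt in spec.relation_mix.items() if wgt > 0]
    weights = np.array([spec.relation_mix[r] for r in rtypes], dtype=float)
    weights /= weights.sum() if len(weights) else 1.0
    compatible_sigs = list(RELATION_SIGNATURES.values())
    docs: list[AnnotatedDocument] = []

    for d in range(spec.n_docs):
        pmid = f"{900000 + d}"
        b = _DocBuilder(pmid)
        herb_name, herb_id = pools[EntityType.HERB][
            int(rng.integers(len(pools[EntityType.HERB])))
        ]
        b.add_text("Molecular survey of ")
        b.add_entity(herb_name, EntityType.HERB, herb_id)
        title_end = b.length
        b.add_text(" bioactivity.")
        title = b.text
        b.add_text(" ")  # title/abstract separator of the offset frame

        planted: set[tuple[RelationType, str, str]] = set()
        for s in range(spec.sentences_per_doc):
            make_filler = rng.random() < spec.negative_density
            if make_filler:
                head_t, tail_t = compatible_sigs[
                    int(rng.integers(len(compatible_sigs)))
                ]
                head = pools[head_t][int(rng.integers(len(pools[head_t])))]
                tail = pools[tail_t][int(rng.integers(len(pools[tail_t])))]
                if head == tail:
                    continue
                b.add_entity(head[0], head_t, head[1])
                b.add_text(f" {spec.cue_words[RelationType.NEG]} ")
                b.add_entity(tail[0], tail_t, tail[1])
                b.add_text(" in replicate assays. ")
                for eid, name, et in ((head[1], head[0], head_t), (tail[1], tail[0], tail_t)):
                    truth.entity_types[eid] = et
                    truth.entity_names[eid] = name
            else:
                rtype = rtypes[int(rng.choice(len(rtypes), p=weights))]
                head_t, tail_t = RELATION_SIGNATURES[rtype]
                head = pools[head_t][int(rng.integers(len(pools[head_t])))]
                tail = pools[tail_t][int(rng.integers(len(pools[tail_t])))]
                b.add_entity(head[0], head_t, head[1])
                b.add_text(f" {spec.cue_words[rtype]} ")
                b.add_entity(tail[0], tail_t, tail[1])
                b.add_text(" in controlled experiments. ")
                planted.add((rtype, head[1], tail[1]))
                for eid, name, et in ((head[1], head[0], head_t), (tail[1], tail[0], tail_t)):
                    truth.entity_types[eid] = et
                    truth.entity_names[eid] = name
        truth.entity_types[herb_id] = EntityType.HERB
        truth.entity_names[herb_id] = herb_name

        abstract = b.text[title_end + len(" bioactivity.") + 1 :].rstrip()
        # rebuild mention list against the final trimmed text frame
        doc = AnnotatedDocument(
            pmid=pmid,
            title=b.text[: title_end + len(" bioactivity.")],
            abstract=abstract,
            mentions=tuple(b.mentions),
            relations=tuple(
                RelationAnnotation(pmid, rt.value, hid, tid)
                for rt, hid, tid in sorted(planted, key=lambda t: (t[0].value, t[1], t[2]))
            ),
        )
        truth.relations |= planted
        docs.append(doc)
    return docs, truth


def make_separable_re_set(
    spec: Optional[GeneratorSpec] = None,
    n_per_label: int = 10,
    seed: Optional[int] = None,
) -> list[REExample]:
    """Labelled sentence-pair examples separable by their cue word.

    Each example's sentence A is a single template sentence containing
    exactly one cue word, which deterministically encodes the label; a
    decision rule "predict by cue word" is perfect on the set.  Negative
    examples reuse positive-signature type pairs with the non-relational
    cue.  Class counts match ``n_per_label`` exactly.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pools = _pools(spec)
    out: list[REExample] = []
    labels = list(POSITIVE_RELATIONS) + [RelationType.NEG]
    sigs = list(RELATION_SIGNATURES.values())
    for label in labels:
        cue = spec.cue_words[label]
        for _ in range(n_per_label):
            if label is RelationType.NEG:
                head_t, tail_t = sigs[int(rng.integers(len(sigs)))]
            else:
                head_t, tail_t = RELATION_SIGNATURES[label]
            head_name, head_id = pools[head_t][int(rng.integers(len(pools[head_t])))]
            tail_name, tail_id = pools[tail_t][int(rng.integers(len(pools[tail_t])))]
            sentence = f"{head_name} {cue} {tail_name} in controlled experiments."
            out.append(
                REExample(
                    sentence_a=sentence,
                    head_text=head_name,
                    tail_text=tail_name,
                    label=label,
                    pmid="synthetic",
                    head_id=head_id,
                    tail_id=tail_id,
                    origin="sampled_negative" if label is RelationType.NEG else "annotated",
                )
            )
    return out
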