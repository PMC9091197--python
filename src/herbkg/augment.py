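"""Substitution-based generative augmentation of the relation dataset.

The pipeline has four steps, one relation type at a time:

1. *Template-corpus extraction* — from annotated abstracts, keep each
   sentence that contains both endpoints of a gold relation of the target
   type.
2. *Substitution I* — replace every entity mention in the kept sentence with
   its type placeholder (``[Herb]``, ``[Chemical]``, ``[Disease]``,
   ``[Gene]``), so a generator can learn the relational pattern rather than
   particular entities.
3. *Template generation* — produce new placeholder sentences in the shape of
   the corpus.  The generator is pluggable: the default desk-scale generator
   recombines clause fragments of corpus templates around the placeholders;
   a fine-tuned generative language model can be plugged into the same
   contract (n templates, exactly one head-type and one tail-type
   placeholder each).
4. *Substitution II* — fill the placeholders with an entity pair whose
   relation of the target type is already known (from an entity database),
   yielding a correctly labelled synthetic training example.

Label soundness is the module's core guarantee: every augmented example's
label matches a known relation of its entity pair, and augmented examples
are only ever appended to training data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from ._util import sentence_spans
from .dataset import REExample
from .ontology import (
    POSITIVE_RELATIONS,
    RELATION_SIGNATURES,
    EntityType,
    RelationType,
    coerce_entity_type,
    coerce_relation,
)
from .pubtator import AnnotatedDocument

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSentence",
    "EntityDB",
    "extract_template_corpus",
    "generate_templates",
    "substitution_two",
    "augment_training_set",
    "entity_db_from_docs",
]

_PLACEHOLDER_RE = re.compile(r"\[(Herb|Chemical|Disease|Gene)\]")


def placeholder(etype: Union[str, EntityType]) -> str:
    return f"[{coerce_entity_type(etype).value}]"


@dataclass(frozen=True)
class TemplateSentence:
    """A sentence with type placeholders, tied to one positive relation type.

    ``source`` is the pmid the sentence came from, or ``"generated"``.
    Corpus templates contain at least one placeholder of the head and of the
    tail type; generated templates contain exactly one of each.
    """

    text: str
    rtype: RelationType
    source: str = "generated"

    def placeholder_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in _PLACEHOLDER_RE.finditer(self.text):
            counts[m.group(0)] = counts.get(m.group(0), 0) + 1
        return counts


@dataclass
class EntityDB:
    """Known entities and related pairs backing Substitution II.

    ``entities`` maps each type to its surface forms; ``pairs`` maps each
    positive relation type to (head text, tail text) pairs with that known
    relation.  Pair types must match the relation's signature by
    construction.
    """

    entities: dict[EntityType, list[str]] = field(default_factory=dict)
    pairs: dict[RelationType, list[tuple[str, str]]] = field(default_factory=dict)

    def add_pair(self, rtype: Union[str, RelationType], head: str, tail: str) -> None:
        rtype = coerce_relation(rtype)
        if rtype not in RELATION_SIGNATURES:
            raise ValueError(f"negative label cannot carry known pairs: {rtype}")
        head_t, tail_t = RELATION_SIGNATURES[rtype]
        self.entities.setdefault(head_t, [])
        self.entities.setdefault(tail_t, [])
        if head not in self.entities[head_t]:
            self.entities[head_t].append(head)
        if tail not in self.entities[tail_t]:
            self.entities[tail_t].append(tail)
        self.pairs.setdefault(rtype, [])
        if (head, tail) not in self.pairs[rtype]:
            self.pairs[rtype].append((head, tail))

    @classmethod
    def from_tsv(
        cls, entities_path: Union[str, Path], pairs_path: Union[str, Path]
    ) -> "EntityDB":
        """Load ``type<TAB>surface`` entities and ``rtype<TAB>head<TAB>tail``
        pairs."""
        db = cls()
        for line in Path(entities_path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            etype, surface = line.split("\t")
            db.entities.setdefault(coerce_entity_type(etype), []).append(surface)
        for line in Path(pairs_path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            rtype, head, tail = line.split("\t")
            db.add_pair(rtype, head, tail)
        return db


def entity_db_from_docs(docs: Iterable[AnnotatedDocument]) -> EntityDB:
    """Collect every annotated relation's endpoint surfaces into a database."""
    db = EntityDB()
    for doc in docs:
        for rel in doc.relations:
            rtype = coerce_relation(rel.rtype)
            if rtype is RelationType.NEG:
                continue
            head = doc.mention_by_id(rel.head_id)
            tail = doc.mention_by_id(rel.tail_id)
            if head is None or tail is None:
                continue
            db.add_pair(rtype, head.text, tail.text)
    return db


def _substitute_types(sentence: str, offset: int, mentions) -> str:
    """Substitution I on one sentence: replace each contained mention with
    its type placeholder, working right-to-left to keep offsets valid."""
    out = sentence
    for m in sorted(mentions, key=lambda m: -m.start):
        lo, hi = m.start - offset, m.end - offset
        out = out[:lo] + placeholder(m.etype) + out[hi:]
    return out


def extract_template_corpus(
    docs: Iterable[AnnotatedDocument],
    rtype: Union[str, RelationType],
) -> list[TemplateSentence]:
    """Build the template corpus for one relation type.

    For every sentence of every document that contains mentions of both
    endpoints of an annotated relation of ``rtype``, emit the sentence with
    all entity mentions replaced by type placeholders.  Duplicates are kept
    once; an empty corpus is a legitimate result.
    """
    rtype = coerce_relation(rtype)
    templates: list[TemplateSentence] = []
    seen: set[str] = set()
    for doc in docs:
        text = doc.text
        rels = [r for r in doc.relations if coerce_relation(r.rtype) is rtype]
        if not rels:
            continue
        for start, end in sentence_spans(text):
            in_sent = [m for m in doc.mentions if start <= m.start and m.end <= end]
            ids_here = {m.entity_id for m in in_sent}
            if not any(
                r.head_id in ids_here and r.tail_id in ids_here for r in rels
            ):
                continue
            templ = _substitute_types(text[start:end], start, in_sent)
            if templ not in seen:
                seen.add(templ)
                templates.append(TemplateSentence(templ, rtype, source=doc.pmid))
    return templates


def _fragments(template: TemplateSentence, head_ph: str, tail_ph: str):
    """Split a template into (prefix, middle, suffix) around the first
    head-type and first tail-type placeholder, in order of appearance."""
    text = template.text
    hi = text.find(head_ph)
    ti = text.find(tail_ph)
    if hi < 0 or ti < 0 or hi == ti:
        return None
    first, second = (hi, ti) if hi < ti else (ti, hi)
    first_ph = head_ph if hi < ti else tail_ph
    second_ph = tail_ph if hi < ti else head_ph
    prefix = text[:first]
    middle = text[first + len(first_ph) : second]
    suffix = text[second + len(second_ph) :]
    # fragments must not smuggle extra placeholders into generated output
    if any(_PLACEHOLDER_RE.search(s) for s in (prefix, middle, suffix)):
        return None
    return prefix, middle, suffix, hi < ti


def generate_templates(
    corpus: Sequence[TemplateSentence],
    n: int,
    seed: int = 0,
    generator: Optional[Callable[[Sequence[TemplateSentence], int, int], list[TemplateSentence]]] = None,
) -> list[TemplateSentence]:
    """Produce ``n`` new placeholder templates in the corpus's shape.

    The default generator recombines prefix/middle/suffix fragments of
    corpus sentences around the two signature placeholders; each output
    contains exactly one head-type and one tail-type placeholder.  A
    generative-LM backend with the same signature may be passed instead.
    Deterministic given the seed.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot generate from an empty template corpus")
    if generator is not None:
        return generator(corpus, n, seed)
    rtype = corpus[0].rtype
    head_ph, tail_ph = (placeholder(t) for t in RELATION_SIGNATURES[rtype])
    frags = [f for t in corpus if (f := _fragments(t, head_ph, tail_ph))]
    if not frags:
        raise ValueError(
            f"no corpus template has usable {head_ph}/{tail_ph} fragments"
        )
    rng = np.random.default_rng(seed)
    out: list[TemplateSentence] = []
    for _ in range(n):
        (p, _, _, fwd1) = frags[rng.integers(len(frags))]
        (_, m, _, _) = frags[rng.integers(len(frags))]
        (_, _, s, _) = frags[rng.integers(len(frags))]
        first, second = (head_ph, tail_ph) if fwd1 else (tail_ph, head_ph)
        out.append(TemplateSentence(f"{p}{first}{m}{second}{s}", rtype, "generated"))
    return out


def substitution_two(
    templates: Sequence[TemplateSentence],
    db: EntityDB,
    seed: int = 0,
) -> list[REExample]:
    """Realize templates into labelled examples with known related pairs.

    Every head-type placeholder is replaced by the sampled pair's head
    surface and every tail-type placeholder by its tail surface; the example
    is labelled with the template's relation type, origin ``augmented``.
    Templates whose relation type has no known pair are skipped and logged.
    """
    rng = np.random.default_rng(seed)
    out: list[REExample] = []
    for templ in templates:
        pairs = db.pairs.get(templ.rtype, [])
        if not pairs:
            logger.warning(
                "no known %s pair in entity DB; template skipped: %r",
                templ.rtype, templ.text,
            )
            continue
        head, tail = pairs[int(rng.integers(len(pairs)))]
        head_ph, tail_ph = (placeholder(t) for t in RELATION_SIGNATURES[templ.rtype])
        realized = templ.text.replace(head_ph, head).replace(tail_ph, tail)
        out.append(
            REExample(
                sentence_a=realized,
                head_text=head,
                tail_text=tail,
                label=templ.rtype,
                pmid=templ.source,
                origin="augmented",
            )
        )
    return out


def augment_training_set(
    train: Sequence[REExample],
    docs: Iterable[AnnotatedDocument],
    db: EntityDB,
    n_per_rtype: int,
    seed: int = 0,
) -> list[REExample]:
    """Append synthetic examples to a training set, one template corpus per
    positive relation type.  Original examples are preserved unchanged;
    augmented examples carry origin ``augmented`` and must never be added to
    test sets."""
    out = list(train)
    docs = list(docs)
    if n_per_rtype == 0:
        return out
    for k, rtype in enumerate(POSITIVE_RELATIONS):
        corpus = extract_template_corpus(docs, rtype)
        if not corpus:
            logger.info("no %s template sentences; skipping augmentation", rtype)
            continue
        templates = generate_templates(corpus, n_per_rtype, seed=seed + k)
        out.extend(substitution_two(templates, db, seed=seed + 100 + k))
    return out
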