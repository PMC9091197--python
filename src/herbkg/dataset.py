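"""Building the six-class relation-extraction dataset from annotated abstracts.

Every classification instance is a sentence pair: sentence A is the abstract
(title concatenated with body) and sentence B is the head and tail entity
surface forms joined by a single space.  Positive examples come directly
from the gold relation annotations; negatives are sampled from
type-compatible entity pairs of the same abstract that carry no annotation,
and are labelled ``Neg``.  The dataset is split 3:1 into train and test,
stratified by label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .ontology import (
    POSITIVE_RELATIONS,
    RELATION_SIGNATURES,
    RelationType,
    coerce_entity_type,
    coerce_relation,
)
from .pubtator import AnnotatedDocument
from ._util import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "REExample",
    "DatasetSplit",
    "DatasetStats",
    "LABEL_ORDER",
    "build_examples",
    "sample_negatives",
    "split_train_test",
    "compute_stats",
    "write_tsv",
    "read_tsv",
    "write_jsonl",
    "read_jsonl",
]

#: Display order of the six labels in dataset statistics.
LABEL_ORDER: tuple[RelationType, ...] = (
    RelationType.HHC,
    RelationType.HTD,
    RelationType.CAD,
    RelationType.CAG,
    RelationType.GID,
    RelationType.NEG,
)


@dataclass(frozen=True)
class REExample:
    """One sentence-pair classification instance.

    ``sentence_b`` is ``head_text + " " + tail_text``; the single separator
    space between the two (possibly multi-word) entity strings is the
    recorded split point, so the head and tail surfaces are kept as explicit
    fields.  ``origin`` records provenance: ``annotated``,
    ``sampled_negative`` or ``augmented``.
    """

    sentence_a: str
    head_text: str
    tail_text: str
    label: RelationType
    pmid: str = ""
    head_id: str = ""
    tail_id: str = ""
    origin: str = "annotated"

    @property
    def sentence_b(self) -> str:
        return f"{self.head_text} {self.tail_text}"

    @property
    def provenance_key(self) -> tuple[str, str, str]:
        return (self.pmid, self.head_id, self.tail_id)


@dataclass
class DatasetSplit:
    """A train/test partition with the seed and ratio that produced it."""

    train: list[REExample]
    test: list[REExample]
    seed: int
    ratio: tuple[int, int] = (3, 1)


@dataclass
class DatasetStats:
    """Per-label counts for train/test/total plus one-decimal percentages."""

    labels: tuple[RelationType, ...]
    train_counts: dict[RelationType, int]
    test_counts: dict[RelationType, int]
    total_counts: dict[RelationType, int]
    percentages: dict[RelationType, float] = field(default_factory=dict)

    @property
    def grand_total(self) -> int:
        return sum(self.total_counts.values())


def build_examples(docs: Iterable[AnnotatedDocument]) -> list[REExample]:
    """Extract one positive example per gold relation annotation.

    The head/tail surface form is the text of the first mention carrying the
    endpoint's concept id; relations with an unresolvable endpoint are
    skipped and logged.
    """
    examples: list[REExample] = []
    for doc in docs:
        sentence_a = doc.text
        for rel in doc.relations:
            head = doc.mention_by_id(rel.head_id)
            tail = doc.mention_by_id(rel.tail_id)
            if head is None or tail is None:
                logger.warning(
                    "doc %s: relation %s(%s, %s) endpoint has no mention; skipped",
                    doc.pmid, rel.rtype, rel.head_id, rel.tail_id,
                )
                continue
            examples.append(
                REExample(
                    sentence_a=sentence_a,
                    head_text=head.text,
                    tail_text=tail.text,
                    label=coerce_relation(rel.rtype),
                    pmid=doc.pmid,
                    head_id=rel.head_id,
                    tail_id=rel.tail_id,
                    origin="annotated",
                )
            )
    return examples


def eligible_negative_pairs(doc: AnnotatedDocument) -> list[tuple]:
    """All ordered within-document entity-id pairs that fit some positive
    signature but carry no annotation, as (head mention, tail mention)."""
    annotated = {(r.head_id, r.tail_id) for r in doc.relations}
    # first mention per entity id, document order
    first: dict[str, object] = {}
    for m in doc.mentions:
        first.setdefault(m.entity_id, m)
    signatures = set(RELATION_SIGNATURES.values())
    pairs = []
    for hid, hm in first.items():
        for tid, tm in first.items():
            if hid == tid or (hid, tid) in annotated:
                continue
            try:
                sig = (coerce_entity_type(hm.etype), coerce_entity_type(tm.etype))
            except ValueError:
                continue
            if sig in signatures:
                pairs.append((hm, tm))
    return pairs


def sample_negatives(
    docs: Sequence[AnnotatedDocument],
    n_per_doc: Union[int, None] = None,
    seed: int = 0,
) -> list[REExample]:
    """Sample ``Neg``-labelled examples from unannotated compatible pairs.

    Eligible pairs are ordered mention pairs within one abstract whose
    (head, tail) entity types match some positive signature and which carry
    no gold annotation; cross-document pairs are never sampled.  When a
    document has fewer eligible pairs than requested, all are returned and
    the shortfall logged.  With ``n_per_doc=None`` the per-document quota is
    chosen so that the negative class roughly balances the largest positive
    class.
    """
    docs = list(docs)
    if n_per_doc is None:
        label_counts: dict[str, int] = {}
        for doc in docs:
            for rel in doc.relations:
                label_counts[rel.rtype] = label_counts.get(rel.rtype, 0) + 1
        largest = max(label_counts.values(), default=0)
        n_per_doc = -(-largest // len(docs)) if docs else 0  # ceil
    if n_per_doc < 0:
        raise ValueError("n_per_doc must be >= 0")
    rng = np.random.default_rng(seed)
    negatives: list[REExample] = []
    for doc in docs:
        pairs = eligible_negative_pairs(doc)
        if len(pairs) < n_per_doc:
            logger.info(
                "doc %s: only %d eligible negative pairs (requested %d)",
                doc.pmid, len(pairs), n_per_doc,
            )
        take = min(n_per_doc, len(pairs))
        idx = rng.choice(len(pairs), size=take, replace=False) if pairs else []
        for i in sorted(int(j) for j in np.atleast_1d(idx)[:take]):
            hm, tm = pairs[i]
            negatives.append(
                REExample(
                    sentence_a=doc.text,
                    head_text=hm.text,
                    tail_text=tm.text,
                    label=RelationType.NEG,
                    pmid=doc.pmid,
                    head_id=hm.entity_id,
                    tail_id=tm.entity_id,
                    origin="sampled_negative",
                )
            )
    return negatives


def split_train_test(
    examples: Sequence[REExample],
    ratio: tuple[int, int] = (3, 1),
    seed: int = 0,
    stratify: bool = True,
) -> DatasetSplit:
    """Partition examples into train and test at the given ratio.

    Stratified by label by default.  Per-label test quotas are apportioned by
    the largest-remainder method so that the overall test fraction is exact
    (each label's proportion is preserved within one example); labels with
    fewer examples than ``ratio[0] + ratio[1]`` go entirely to train, with a
    warning.  Deterministic given the seed.
    """
    examples = list(examples)
    if not examples:
        raise ValueError("cannot split an empty example list")
    rng = np.random.default_rng(seed)
    total = len(examples)
    test_frac = ratio[1] / (ratio[0] + ratio[1])
    if not stratify:
        order = rng.permutation(total)
        n_test = int(round_half_up(total * test_frac, 0))
        test_idx = set(int(i) for i in order[:n_test])
        train = [e for i, e in enumerate(examples) if i not in test_idx]
        test = [e for i, e in enumerate(examples) if i in test_idx]
        return DatasetSplit(train, test, seed, ratio)

    by_label: dict[RelationType, list[int]] = {}
    for i, e in enumerate(examples):
        by_label.setdefault(e.label, []).append(i)

    min_count = ratio[0] + ratio[1]
    eligible = {lab: idxs for lab, idxs in by_label.items() if len(idxs) >= min_count}
    for lab, idxs in by_label.items():
        if lab not in eligible:
            logger.warning(
                "label %s has only %d examples; all assigned to train", lab, len(idxs)
            )
    target_test = int(round_half_up(sum(len(v) for v in eligible.values()) * test_frac, 0))
    quotas: dict[RelationType, int] = {}
    remainders: list[tuple[float, int, RelationType]] = []
    for lab, idxs in eligible.items():
        exact = len(idxs) * test_frac
        quotas[lab] = int(exact)
        remainders.append((exact - int(exact), len(idxs), lab))
    short = target_test - sum(quotas.values())
    # hand leftover test slots to the largest fractional remainders,
    # larger classes first on ties
    for _, _, lab in sorted(remainders, key=lambda t: (-t[0], -t[1], t[2].value))[:short]:
        quotas[lab] += 1

    test_idx: set[int] = set()
    for lab, idxs in eligible.items():
        perm = rng.permutation(len(idxs))
        test_idx.update(idxs[int(i)] for i in perm[: quotas[lab]])
    train = [e for i, e in enumerate(examples) if i not in test_idx]
    test = [e for i, e in enumerate(examples) if i in test_idx]
    return DatasetSplit(train, test, seed, ratio)


def compute_stats(data: Union[Sequence[REExample], DatasetSplit]) -> DatasetStats:
    """Per-label counts and one-decimal percentage shares of the total."""
    if isinstance(data, DatasetSplit):
        train, test = data.train, data.test
    else:
        train, test = list(data), []

    def count(items: Sequence[REExample]) -> dict[RelationType, int]:
        out = {lab: 0 for lab in LABEL_ORDER}
        for e in items:
            out[e.label] = out.get(e.label, 0) + 1
        return out

    train_c, test_c = count(train), count(test)
    total_c = {lab: train_c[lab] + test_c[lab] for lab in LABEL_ORDER}
    grand = sum(total_c.values())
    pct = {
        lab: (round_half_up(100.0 * total_c[lab] / grand, 1) if grand else 0.0)
        for lab in LABEL_ORDER
    }
    return DatasetStats(LABEL_ORDER, train_c, test_c, total_c, pct)


# ---------------------------------------------------------------------------
# serialization

def write_tsv(examples: Iterable[REExample], path: Union[str, Path]) -> None:
    """Three tab-separated columns: sentence A, sentence B, label."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in examples:
            fh.write(f"{e.sentence_a}\t{e.sentence_b}\t{e.label.value}\n")


def read_tsv(path: Union[str, Path]) -> list[REExample]:
    """Read the three-column TSV dialect.

    Sentence B is split at its first space to recover head and tail, which is
    exact for single-token heads; use the JSONL dialect when full provenance
    is needed.
    """
    out: list[REExample] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        a, b, label = line.split("\t")
        head, _, tail = b.partition(" ")
        out.append(REExample(a, head, tail, coerce_relation(label)))
    return out


def write_jsonl(examples: Iterable[REExample], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in examples:
            fh.write(
                json.dumps(
                    {
                        "sentence_a": e.sentence_a,
                        "head_text": e.head_text,
                        "tail_text": e.tail_text,
                        "label": e.label.value,
                        "pmid": e.pmid,
                        "head_id": e.head_id,
                        "tail_id": e.tail_id,
                        "origin": e.origin,
                    }
                )
                + "\n"
            )


def read_jsonl(path: Union[str, Path]) -> list[REExample]:
    out: list[REExample] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        out.append(
            REExample(
                d["sentence_a"], d["head_text"], d["tail_text"],
                coerce_relation(d["label"]), d.get("pmid", ""),
                d.get("head_id", ""), d.get("tail_id", ""),
                d.get("origin", "annotated"),
            )
        )
    return out
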