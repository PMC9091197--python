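"""Evaluation suite for the six-class relation-extraction task.

Per-class precision, recall and F1 follow the usual definitions

    Pre = TP / (TP + FP) x 100%,   Rec = TP / (TP + FN) x 100%,
    F1  = 2 x Pre x Rec / (Pre + Rec),

computed from a 6x6 confusion matrix (rows = gold, columns = predicted) in
the fixed label order CAG, HHC, HTD, CAD, GID, Neg.  Two reporting
conventions are reproduced exactly as printed in the benchmark tables this
suite mirrors:

* the per-class TN counts the correctly classified instances of the *other*
  classes, i.e. ``TN_k = trace(cm) - TP_k`` (the standard complement
  definition is available behind a flag), and
* the "Total" column is the unweighted macro mean of the per-class
  percentages, computed on the raw values and then rounded half-up to one
  decimal.

Average precision summarises the precision-recall curve as the step sum
``AP = sum_n (R_n - R_{n-1}) P_n``; multi-class AP is the unweighted mean of
one-vs-rest APs (micro-pooling available).

Token importance is occlusion-based: for an evidence sentence containing
both entities, each token in turn is replaced by a reserved never-trained
occlusion token and the drop ``d_i = c* - c_i`` in the gold-label confidence
is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence, Union

import numpy as np

from ._util import round_half_up, split_sentences
from .ontology import RelationType, coerce_relation

__all__ = [
    "EVAL_LABELS",
    "ConfusionMatrix6",
    "ClassMetrics",
    "SummaryMetrics",
    "PRCurve",
    "TokenImportanceResult",
    "confusion_matrix",
    "class_metrics",
    "average_precision",
    "multiclass_average_precision",
    "token_importance",
    "render_report",
]

#: Fixed label order of the confusion matrix and metric tables.
EVAL_LABELS: tuple[RelationType, ...] = (
    RelationType.CAG,
    RelationType.HHC,
    RelationType.HTD,
    RelationType.CAD,
    RelationType.GID,
    RelationType.NEG,
)
_IDX = {lab: i for i, lab in enumerate(EVAL_LABELS)}


@dataclass(frozen=True)
class ConfusionMatrix6:
    """6x6 integer counts, rows = gold label, columns = predicted label."""

    counts: tuple[tuple[int, ...], ...]
    labels: tuple[RelationType, ...] = EVAL_LABELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (6, 6) or (arr < 0).any():
            raise ValueError("confusion matrix must be 6x6 with counts >= 0")
        object.__setattr__(
            self, "counts", tuple(tuple(int(x) for x in row) for row in arr)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def trace(self) -> int:
        return int(np.trace(self.array))

    @property
    def total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class ClassMetrics:
    """One class's counts and percentage scores (one-decimal display)."""

    label: RelationType
    tp: int
    fp: int
    fn: int
    tn: int
    precision_raw: float
    recall_raw: float
    f1_raw: float
    precision_undefined: bool = False

    @property
    def precision(self) -> float:
        return round_half_up(self.precision_raw, 1)

    @property
    def recall(self) -> float:
        return round_half_up(self.recall_raw, 1)

    @property
    def f1(self) -> float:
        return round_half_up(self.f1_raw, 1)


@dataclass(frozen=True)
class SummaryMetrics:
    """The "Total" column: summed counts and unweighted macro means."""

    tp: int
    fp: int
    fn: int
    tn: int
    macro_precision_raw: float
    macro_recall_raw: float
    macro_f1_raw: float

    @property
    def macro_precision(self) -> float:
        return round_half_up(self.macro_precision_raw, 1)

    @property
    def macro_recall(self) -> float:
        return round_half_up(self.macro_recall_raw, 1)

    @property
    def macro_f1(self) -> float:
        return round_half_up(self.macro_f1_raw, 1)


def confusion_matrix(
    gold: Sequence[Union[str, RelationType]],
    pred: Sequence[Union[str, RelationType]],
) -> ConfusionMatrix6:
    """Count (gold, predicted) label pairs into the fixed 6x6 layout."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    arr = np.zeros((6, 6), dtype=int)
    for g, p in zip(gold, pred):
        arr[_IDX[coerce_relation(g)], _IDX[coerce_relation(p)]] += 1
    return ConfusionMatrix6(tuple(tuple(int(x) for x in row) for row in arr))


def class_metrics(
    cm: ConfusionMatrix6,
    tn_convention: str = "trace",
) -> tuple[dict[RelationType, ClassMetrics], SummaryMetrics]:
    """Per-class counts and scores plus the macro summary.

    ``tn_convention="trace"`` reports TN as the correctly classified
    instances of the other classes (trace minus the class's TP), matching
    the printed benchmark tables; ``"standard"`` reports the usual
    everything-else complement.  A class with ``TP + FP == 0`` has undefined
    precision, reported as 0.0 with ``precision_undefined`` set.
    """
    if tn_convention not in ("trace", "standard"):
        raise ValueError(f"unknown TN convention: {tn_convention!r}")
    arr = cm.array
    trace = cm.trace
    total = cm.total
    per_class: dict[RelationType, ClassMetrics] = {}
    for i, lab in enumerate(cm.labels):
        tp = int(arr[i, i])
        fp = int(arr[:, i].sum()) - tp
        fn = int(arr[i, :].sum()) - tp
        tn = trace - tp if tn_convention == "trace" else total - tp - fp - fn
        undefined = (tp + fp) == 0
        pre = 0.0 if undefined else 100.0 * tp / (tp + fp)
        rec = 0.0 if (tp + fn) == 0 else 100.0 * tp / (tp + fn)
        f1 = 0.0 if (pre + rec) == 0 else 2.0 * pre * rec / (pre + rec)
        per_class[lab] = ClassMetrics(lab, tp, fp, fn, tn, pre, rec, f1, undefined)
    vals = list(per_class.values())
    summary = SummaryMetrics(
        tp=sum(c.tp for c in vals),
        fp=sum(c.fp for c in vals),
        fn=sum(c.fn for c in vals),
        tn=sum(c.tn for c in vals),
        macro_precision_raw=float(np.mean([c.precision_raw for c in vals])),
        macro_recall_raw=float(np.mean([c.recall_raw for c in vals])),
        macro_f1_raw=float(np.mean([c.f1_raw for c in vals])),
    )
    return per_class, summary


# ---------------------------------------------------------------------------
# average precision

@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points in threshold order plus the AP step sum."""

    recall: tuple[float, ...]
    precision: tuple[float, ...]
    ap: float


def average_precision(scores: Sequence[float], gold: Sequence[int]) -> PRCurve:
    """One-vs-rest average precision by the recall-step weighted sum.

    Examples are ranked by descending score (stable for ties); at each rank
    ``n`` with precision ``P_n`` and recall ``R_n``,
    ``AP = sum_n (R_n - R_{n-1}) P_n``.  Requires at least one positive.
    """
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=int)
    if scores.shape != gold.shape:
        raise ValueError("scores and gold must have equal length")
    n_pos = int(gold.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined with no positive labels")
    order = np.argsort(-scores, kind="stable")
    ranked = gold[order]
    tp_cum = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_recall) * precision))
    return PRCurve(tuple(recall), tuple(precision), ap)


def multiclass_average_precision(
    score_matrix: np.ndarray,
    gold: Sequence[Union[str, RelationType]],
    average: str = "macro",
) -> float:
    """Mean one-vs-rest AP over the six classes.

    ``score_matrix`` is (n examples, 6) in the fixed label order.  Macro
    averages per-class APs (classes absent from the gold labels are
    skipped); micro pools all one-vs-rest decisions into a single ranking.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    gold_idx = np.array([_IDX[coerce_relation(g)] for g in gold])
    if average == "micro":
        flat_scores = score_matrix.ravel()
        flat_gold = np.zeros_like(score_matrix, dtype=int)
        flat_gold[np.arange(len(gold_idx)), gold_idx] = 1
        return average_precision(flat_scores, flat_gold.ravel()).ap
    if average != "macro":
        raise ValueError(f"unknown average: {average!r}")
    aps = []
    for i in range(6):
        binary = (gold_idx == i).astype(int)
        if binary.sum() == 0:
            continue
        aps.append(average_precision(score_matrix[:, i], binary).ap)
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# occlusion-based token importance

@dataclass(frozen=True)
class TokenImportanceResult:
    """Per-token confidence drops for one evidence sentence.

    ``baseline`` is the gold-label confidence c* on the unmodified sentence;
    ``scores[i]`` is ``d_i = c* - c_i`` after occluding token ``i``.
    """

    tokens: tuple[str, ...]
    baseline: float
    scores: tuple[float, ...]
    sentence: str


def token_importance(
    state,
    example,
    gold: Union[str, RelationType],
    occlusion_token: str = "[OCC]",
):
    """Occlusion attribution over the evidence sentence of an example.

    The first sentence of sentence A containing both the head and the tail
    surface form is extracted (an example without such a sentence is an
    error).  Each whitespace token is replaced in turn by the occlusion
    token and the sentence re-scored; the drop in the gold label's
    probability is that token's importance.
    """
    from .model import predict

    gold = coerce_relation(gold)
    sentence = None
    for sent in split_sentences(example.sentence_a):
        if example.head_text in sent and example.tail_text in sent:
            sentence = sent
            break
    if sentence is None:
        raise ValueError(
            "no evidence sentence: no sentence contains both "
            f"{example.head_text!r} and {example.tail_text!r}"
        )
    probe = dc_replace(example, sentence_a=sentence)
    baseline = predict(state, probe).scores[gold]
    tokens = sentence.split()
    drops = []
    for i in range(len(tokens)):
        occluded = tokens.copy()
        occluded[i] = occlusion_token
        variant = dc_replace(example, sentence_a=" ".join(occluded))
        c_i = predict(state, variant).scores[gold]
        drops.append(baseline - c_i)
    return TokenImportanceResult(tuple(tokens), float(baseline), tuple(drops), sentence)


# ---------------------------------------------------------------------------
# report rendering

def render_report(cm: ConfusionMatrix6, tn_convention: str = "trace") -> str:
    """Plain-text table: confusion matrix on top, metric rows below."""
    per_class, summary = class_metrics(cm, tn_convention)
    labels = [lab.value for lab in cm.labels]
    width = 8
    lines = ["".ljust(width) + "".join(s.ljust(width) for s in labels + ["Total"])]
    for i, lab in enumerate(labels):
        row = cm.array[i]
        lines.append(
            lab.ljust(width)
            + "".join(str(int(x)).ljust(width) for x in row)
            + str(int(row.sum())).ljust(width)
        )
    cms = [per_class[lab] for lab in cm.labels]
    for name, get, total in (
        ("TP", lambda c: c.tp, summary.tp),
        ("FP", lambda c: c.fp, summary.fp),
        ("FN", lambda c: c.fn, summary.fn),
        ("TN", lambda c: c.tn, summary.tn),
    ):
        lines.append(
            name.ljust(width)
            + "".join(str(get(c)).ljust(width) for c in cms)
            + str(total).ljust(width)
        )
    for name, get, total in (
        ("Pre", lambda c: c.precision, summary.macro_precision),
        ("Rec", lambda c: c.recall, summary.macro_recall),
        ("F1", lambda c: c.f1, summary.macro_f1),
    ):
        lines.append(
            name.ljust(width)
            + "".join(f"{get(c):.1f}%".ljust(width) for c in cms)
            + f"{total:.1f}%".ljust(width)
        )
    return "\n".join(lines)
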