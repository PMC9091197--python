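"""Published reference results for the herb relation-extraction benchmark.

These are the printed test-set confusion matrices of the three encoder
checkpoints evaluated on the human-annotated herb RE dataset (BERT, SciBERT
and BioBERT base models, no boosters), the dataset's per-class example
counts, and the hyperparameter ranges of the accompanying grid search.  The
evaluation suite recomputes every derived metric cell (TP/FP/FN/TN,
precision, recall, F1, macro totals) from these raw counts; nothing derived
is stored here.

Rows and columns follow the fixed label order CAG, HHC, HTD, CAD, GID, Neg
(rows = gold, columns = predicted).
"""

from __future__ import annotations

from .ontology import RelationType

__all__ = [
    "BENCHMARK_CONFUSIONS",
    "DATASET_CLASS_COUNTS",
    "TUNING_GRID",
]

#: model name -> printed 6x6 confusion matrix on the benchmark test set
BENCHMARK_CONFUSIONS: dict[str, tuple[tuple[int, ...], ...]] = {
    "bert": (
        (13, 2, 0, 1, 0, 0),
        (1, 338, 6, 0, 1, 0),
        (1, 5, 191, 3, 0, 1),
        (0, 1, 2, 64, 1, 0),
        (0, 0, 0, 4, 25, 0),
        (0, 2, 1, 1, 0, 220),
    ),
    "scibert": (
        (14, 1, 0, 1, 0, 0),
        (2, 338, 5, 0, 1, 0),
        (1, 5, 191, 3, 0, 1),
        (0, 0, 2, 66, 0, 0),
        (0, 0, 0, 4, 25, 0),
        (0, 2, 1, 1, 0, 220),
    ),
    "biobert": (
        (13, 2, 0, 1, 0, 0),
        (0, 341, 5, 0, 0, 0),
        (0, 5, 192, 3, 0, 1),
        (0, 0, 2, 66, 0, 0),
        (0, 0, 0, 4, 25, 0),
        (0, 2, 1, 0, 0, 221),
    ),
}

#: Total per-class example counts of the benchmark herb RE dataset.
DATASET_CLASS_COUNTS: dict[RelationType, int] = {
    RelationType.HHC: 1230,
    RelationType.HTD: 673,
    RelationType.CAD: 244,
    RelationType.CAG: 45,
    RelationType.GID: 110,
    RelationType.NEG: 1234,
}

#: Hyperparameter tuning ranges of the benchmark grid search.
TUNING_GRID: dict[str, list] = {
    "epochs": [1, 3, 5, 7, 9],
    "learning_rate": [0.0001, 0.0003, 0.001, 0.003, 0.01],
    "loss": ["cross_entropy", "weighted_cross_entropy"],
    "optimizer": ["sgd", "adam", "momentum"],
}
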