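"""The six-class sentence-pair relation classifier.

Architecture: token/segment/position embeddings -> a stack of ``N``
transformer encoder layers -> pooling -> dense -> softmax over the six
relation labels (the base preset mirrors the standard 12-layer, 12-head,
768-wide encoder; tests and desk-scale runs use a tiny from-scratch preset).
The encoder accepts external pretrained weights through
``EncoderConfig.pretrained_checkpoint``; the same stack is fine-tuned with
masked-language modelling to inject domain text before supervised training.

Hyperparameter search is an exhaustive grid over epochs, learning rate,
loss (plain or inverse-frequency-weighted cross-entropy) and optimizer
(SGD, Adam, SGD with momentum), selected by macro-F1.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import nn
from .dataset import REExample
from .ontology import RelationType
from .pubtator import AnnotatedDocument

logger = logging.getLogger(__name__)

__all__ = [
    "PAD", "UNK", "SEP", "MASK", "OCC",
    "MODEL_LABELS",
    "WordTokenizer",
    "EncoderConfig", "TrainConfig", "TokenizedPair", "PredictionDistribution",
    "ClassifierState",
    "tokenize_pair", "train_classifier", "predict", "predict_batch",
    "domain_finetune_mlm", "MLMResult",
    "default_grid", "enumerate_grid", "grid_search",
    "save_classifier", "load_classifier",
]

PAD, UNK, SEP, MASK, OCC = "[PAD]", "[UNK]", "[SEP]", "[MASK]", "[OCC]"
_SPECIALS = (PAD, UNK, SEP, MASK, OCC)

#: Fixed label order of the classifier output (matches the evaluation suite).
MODEL_LABELS: tuple[RelationType, ...] = (
    RelationType.CAG,
    RelationType.HHC,
    RelationType.HTD,
    RelationType.CAD,
    RelationType.GID,
    RelationType.NEG,
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(MODEL_LABELS)}


class WordTokenizer:
    """Whitespace tokenizer with a fixed vocabulary.

    Tokens are whitespace-separated words, case-preserving, so that
    detokenisation is the exact inverse on in-vocabulary text (entity surface
    forms survive a round trip).  Ids 0-4 are the reserved specials: padding,
    unknown, sentence separator, the MLM mask, and a never-trained occlusion
    token used by token-importance analysis.
    """

    def __init__(self, vocab: Sequence[str]):
        words = [w for w in vocab if w not in _SPECIALS]
        self.itos: list[str] = list(_SPECIALS) + list(dict.fromkeys(words))
        self.stoi: dict[str, int] = {w: i for i, w in enumerate(self.itos)}

    @classmethod
    def build(cls, texts: Iterable[str]) -> "WordTokenizer":
        seen: dict[str, None] = {}
        for text in texts:
            for tok in text.split():
                seen.setdefault(tok, None)
        return cls(sorted(seen))

    def __len__(self) -> int:
        return len(self.itos)

    def tokenize(self, text: str) -> list[str]:
        return text.split()

    def encode(self, text: str) -> list[int]:
        unk = self.stoi[UNK]
        return [self.stoi.get(tok, unk) for tok in text.split()]

    def decode(self, ids: Iterable[int]) -> str:
        return " ".join(self.itos[i] for i in ids)


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder architecture: ``num_layers`` stacked encoders with
    ``num_heads`` attention heads over ``hidden_dim``-wide states."""

    num_layers: int = 12
    num_heads: int = 12
    hidden_dim: int = 768
    max_seq_len: int = 512
    vocab_size: int = 0  # 0: size to the tokenizer at build time
    pretrained_checkpoint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hidden_dim % self.num_heads:
            raise ValueError("hidden_dim must be divisible by num_heads")
        if self.max_seq_len < 8:
            raise ValueError("max_seq_len must be >= 8")

    @classmethod
    def tiny(cls, max_seq_len: int = 64) -> "EncoderConfig":
        """Desk-scale preset used throughout the test suite."""
        return cls(num_layers=2, num_heads=2, hidden_dim=32, max_seq_len=max_seq_len)

    @classmethod
    def base(cls) -> "EncoderConfig":
        return cls()


@dataclass(frozen=True)
class TrainConfig:
    """One training configuration (a grid point during search)."""

    epochs: int = 5
    learning_rate: float = 0.001
    loss: str = "cross_entropy"  # or "weighted_cross_entropy"
    optimizer: str = "adam"      # "sgd" | "adam" | "momentum"
    seed: int = 0
    batch_size: int = 8

    def __post_init__(self) -> None:
        if self.loss not in ("cross_entropy", "weighted_cross_entropy"):
            raise ValueError(f"unknown loss: {self.loss!r}")
        if self.optimizer.lower() not in ("sgd", "adam", "momentum"):
            raise ValueError(f"unknown optimizer: {self.optimizer!r}")


@dataclass(frozen=True)
class TokenizedPair:
    """Encoded input: sentence A, separator, sentence B, separator."""

    token_ids: tuple[int, ...]
    segment_ids: tuple[int, ...]
    position_ids: tuple[int, ...]
    sep_positions: tuple[int, int]


@dataclass(frozen=True)
class PredictionDistribution:
    """Per-label confidence scores; non-negative and summing to one."""

    scores: dict[RelationType, float]

    @property
    def argmax(self) -> RelationType:
        return max(MODEL_LABELS, key=lambda lab: self.scores[lab])

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[lab] for lab in MODEL_LABELS])


@dataclass
class ClassifierState:
    """Trained weights plus the tokenizer and configs that produced them."""

    params: nn.Params
    tokenizer: WordTokenizer
    encoder: EncoderConfig
    train_config: Optional[TrainConfig] = None
    class_weights: Optional[np.ndarray] = None


def tokenize_pair(
    example: REExample,
    tokenizer: WordTokenizer,
    config: EncoderConfig,
) -> TokenizedPair:
    """Encode a sentence pair as ``A [SEP] B [SEP]`` with segment ids.

    When the sequence exceeds the token budget, sentence A is truncated from
    its tail (titles and openings carry the finding); sentence B is never
    truncated, and a sentence B that cannot fit at all is a degenerate input.
    """
    sep = tokenizer.stoi[SEP]
    a_ids = tokenizer.encode(example.sentence_a)
    b_ids = tokenizer.encode(example.sentence_b)
    budget = config.max_seq_len
    if len(b_ids) + 2 > budget:
        raise ValueError(
            f"sentence B ({len(b_ids)} tokens) exceeds the sequence budget {budget}"
        )
    a_keep = min(len(a_ids), budget - len(b_ids) - 2)
    a_ids = a_ids[:a_keep]
    ids = a_ids + [sep] + b_ids + [sep]
    segs = [0] * (len(a_ids) + 1) + [1] * (len(b_ids) + 1)
    return TokenizedPair(
        token_ids=tuple(ids),
        segment_ids=tuple(segs),
        position_ids=tuple(range(len(ids))),
        sep_positions=(len(a_ids), len(ids) - 1),
    )


def _pad_batch(pairs: Sequence[TokenizedPair], pad_id: int = 0):
    L = max(len(p.token_ids) for p in pairs)
    n = len(pairs)
    ids = np.full((n, L), pad_id, dtype=np.intp)
    seg = np.zeros((n, L), dtype=np.intp)
    mask = np.zeros((n, L), dtype=float)
    for i, p in enumerate(pairs):
        k = len(p.token_ids)
        ids[i, :k] = p.token_ids
        seg[i, :k] = p.segment_ids
        mask[i, :k] = 1.0
    return ids, seg, mask


def _class_weights(labels: Sequence[RelationType]) -> np.ndarray:
    """Inverse class-frequency weights normalised to mean one over the
    classes present; absent classes get weight zero (never sampled)."""
    counts = np.zeros(len(MODEL_LABELS))
    for lab in labels:
        counts[_LABEL_INDEX[lab]] += 1
    present = counts > 0
    w = np.zeros_like(counts)
    w[present] = 1.0 / counts[present]
    w[present] /= w[present].mean()
    return w


def _init_state(
    examples: Sequence[REExample],
    enc: EncoderConfig,
    seed: int,
    tokenizer: Optional[WordTokenizer],
) -> ClassifierState:
    if tokenizer is None:
        texts = [e.sentence_a for e in examples] + [e.sentence_b for e in examples]
        tokenizer = WordTokenizer.build(texts)
    vocab = enc.vocab_size or len(tokenizer)
    if vocab < len(tokenizer):
        raise ValueError("vocab_size smaller than tokenizer vocabulary")
    params = nn.init_params(
        enc.num_layers, enc.num_heads, enc.hidden_dim, enc.max_seq_len,
        vocab, len(MODEL_LABELS), seed,
    )
    enc = replace(enc, vocab_size=vocab)
    return ClassifierState(params=params, tokenizer=tokenizer, encoder=enc)


def train_classifier(
    train: Sequence[REExample],
    enc: EncoderConfig,
    tc: TrainConfig,
    tokenizer: Optional[WordTokenizer] = None,
    initial_state: Optional[ClassifierState] = None,
) -> ClassifierState:
    """Train the relation classifier; deterministic given the configs.

    ``initial_state`` continues from existing weights (e.g. an MLM
    fine-tuned checkpoint) instead of a fresh initialisation.
    """
    train = list(train)
    bad = [e for e in train if e.label not in _LABEL_INDEX]
    if bad:
        raise ValueError(f"label outside the six-class set: {bad[0].label!r}")
    if not train:
        raise ValueError("empty training set")
    if initial_state is not None:
        state = ClassifierState(
            params={k: v.copy() for k, v in initial_state.params.items()},
            tokenizer=initial_state.tokenizer,
            encoder=initial_state.encoder,
        )
    else:
        state = _init_state(train, enc, tc.seed, tokenizer)
    state.train_config = tc

    weights = None
    if tc.loss == "weighted_cross_entropy":
        weights = _class_weights([e.label for e in train])
    state.class_weights = weights

    pairs = [tokenize_pair(e, state.tokenizer, state.encoder) for e in train]
    labels = np.array([_LABEL_INDEX[e.label] for e in train], dtype=np.intp)
    rng = np.random.default_rng(tc.seed + 1)
    opt = nn.Optimizer(tc.optimizer, tc.learning_rate)
    if tc.learning_rate == 0.0:
        return state  # no-update limit: predictions equal the untrained state
    for _ in range(tc.epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            ids, seg, mask = _pad_batch([pairs[i] for i in idx])
            hidden, cache = nn.encoder_forward(state.params, ids, seg, mask)
            logits, hcache = nn.pooled_head_forward(state.params, hidden, mask)
            _, dlogits, _ = nn.cross_entropy(logits, labels[idx], weights)
            grads, d_hidden = nn.pooled_head_backward(
                state.params, dlogits, hcache, hidden.shape
            )
            grads.update(nn.encoder_backward(state.params, cache, d_hidden))
            opt.step(state.params, grads)
    return state


def predict_batch(
    state: ClassifierState, examples: Sequence[REExample]
) -> list[PredictionDistribution]:
    pairs = [tokenize_pair(e, state.tokenizer, state.encoder) for e in examples]
    out: list[PredictionDistribution] = []
    for start in range(0, len(pairs), 32):
        chunk = pairs[start : start + 32]
        ids, seg, mask = _pad_batch(chunk)
        hidden, _ = nn.encoder_forward(state.params, ids, seg, mask)
        logits, _ = nn.pooled_head_forward(state.params, hidden, mask)
        probs = nn.softmax(logits)
        for row in probs:
            out.append(
                PredictionDistribution(
                    {lab: float(row[i]) for i, lab in enumerate(MODEL_LABELS)}
                )
            )
    return out


def predict(state: ClassifierState, example: REExample) -> PredictionDistribution:
    """Score one example; the argmax of the distribution is the prediction."""
    return predict_batch(state, [example])[0]


# ---------------------------------------------------------------------------
# masked-language-model domain fine-tuning

@dataclass
class MLMResult:
    """Fine-tuned checkpoint with held-out masked-token losses."""

    state: ClassifierState
    initial_heldout_loss: float
    final_heldout_loss: float
    steps: int


def _mask_tokens(rng, ids, mask, mask_id, mask_fraction, vocab_size):
    """Pick positions to mask; returns (input ids, target ids, loss mask)."""
    inp = ids.copy()
    targets = ids.copy()
    pick = (rng.random(ids.shape) < mask_fraction) & (mask > 0) & (ids > 4)
    if not pick.any():  # always mask at least one real token
        rows, cols = np.nonzero((mask > 0) & (ids > 4))
        if len(rows):
            j = rng.integers(len(rows))
            pick = np.zeros_like(ids, dtype=bool)
            pick[rows[j], cols[j]] = True
    inp[pick] = mask_id
    return inp, targets, pick


def _mlm_loss(params, ids, seg, mask, inp, targets, pick, compute_grads=False):
    hidden, cache = nn.encoder_forward(params, inp, seg, mask)
    logits = nn.mlm_head_forward(params, hidden)
    rows, cols = np.nonzero(pick)
    if len(rows) == 0:
        return 0.0, None
    sel = logits[rows, cols]
    loss, dsel, _ = nn.cross_entropy(sel, targets[rows, cols])
    if not compute_grads:
        return loss, None
    dlogits = np.zeros_like(logits)
    dlogits[rows, cols] = dsel
    grads, d_hidden = nn.mlm_head_backward(params, dlogits, hidden)
    grads.update(nn.encoder_backward(params, cache, d_hidden))
    return loss, grads


def domain_finetune_mlm(
    corpus: Sequence[AnnotatedDocument],
    enc: EncoderConfig,
    mask_fraction: float = 0.15,
    steps: int = 500,
    seed: int = 0,
    batch_size: int = 8,
    learning_rate: float = 3e-4,
    heldout_fraction: float = 0.1,
    state: Optional[ClassifierState] = None,
) -> MLMResult:
    """Masked-language-model fine-tuning on title+abstract text.

    A held-out slice of the corpus is masked once (deterministically) and its
    masked-token cross-entropy is measured before and after training; with
    ``steps=0`` the checkpoint is returned unchanged.  Deterministic given
    the seed.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty fine-tuning corpus")
    texts = [doc.text for doc in corpus]
    if state is None:
        tokenizer = WordTokenizer.build(texts)
        params = nn.init_params(
            enc.num_layers, enc.num_heads, enc.hidden_dim, enc.max_seq_len,
            enc.vocab_size or len(tokenizer), len(MODEL_LABELS), seed,
        )
        enc = replace(enc, vocab_size=enc.vocab_size or len(tokenizer))
        state = ClassifierState(params=params, tokenizer=tokenizer, encoder=enc)
    else:
        state = ClassifierState(
            params={k: v.copy() for k, v in state.params.items()},
            tokenizer=state.tokenizer,
            encoder=state.encoder,
        )
    tok = state.tokenizer
    L = state.encoder.max_seq_len
    encoded = [tok.encode(t)[:L] for t in texts]

    n_held = max(1, int(len(encoded) * heldout_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(encoded))
    held = [encoded[i] for i in order[:n_held]]
    pool = [encoded[i] for i in order[n_held:]] or held

    def to_batch(seqs):
        Lb = max(len(s) for s in seqs)
        ids = np.zeros((len(seqs), Lb), dtype=np.intp)
        mask = np.zeros((len(seqs), Lb))
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            mask[i, : len(s)] = 1.0
        return ids, np.zeros_like(ids), mask

    h_ids, h_seg, h_mask = to_batch(held)
    h_rng = np.random.default_rng(seed + 7)
    h_inp, h_tgt, h_pick = _mask_tokens(
        h_rng, h_ids, h_mask, tok.stoi[MASK], mask_fraction, state.encoder.vocab_size
    )
    initial, _ = _mlm_loss(state.params, h_ids, h_seg, h_mask, h_inp, h_tgt, h_pick)

    opt = nn.Optimizer("adam", learning_rate)
    step_rng = np.random.default_rng(seed + 13)
    for _ in range(steps):
        idx = step_rng.integers(len(pool), size=min(batch_size, len(pool)))
        ids, seg, mask = to_batch([pool[i] for i in idx])
        inp, tgt, pick = _mask_tokens(
            step_rng, ids, mask, tok.stoi[MASK], mask_fraction, state.encoder.vocab_size
        )
        _, grads = _mlm_loss(state.params, ids, seg, mask, inp, tgt, pick, True)
        if grads:
            opt.step(state.params, grads)
    final, _ = _mlm_loss(state.params, h_ids, h_seg, h_mask, h_inp, h_tgt, h_pick)
    return MLMResult(state=state, initial_heldout_loss=float(initial),
                     final_heldout_loss=float(final), steps=steps)


# ---------------------------------------------------------------------------
# grid search

def default_grid() -> dict[str, list]:
    """The standard hyperparameter tuning ranges (150 grid points)."""
    return {
        "epochs": [1, 3, 5, 7, 9],
        "learning_rate": [0.0001, 0.0003, 0.001, 0.003, 0.01],
        "loss": ["cross_entropy", "weighted_cross_entropy"],
        "optimizer": ["sgd", "adam", "momentum"],
    }


def enumerate_grid(
    grid: dict[str, list], seed: int = 0, batch_size: int = 8
) -> list[TrainConfig]:
    """Every combination of the grid's ranges, in deterministic order."""
    keys = ["epochs", "learning_rate", "loss", "optimizer"]
    for k in grid:
        if k not in keys:
            raise ValueError(f"unknown grid axis: {k!r}")
    ranges = [grid.get(k, [getattr(TrainConfig(), k)]) for k in keys]
    return [
        TrainConfig(epochs=e, learning_rate=lr, loss=lo, optimizer=op,
                    seed=seed, batch_size=batch_size)
        for e, lr, lo, op in itertools.product(*ranges)
    ]


def grid_search(
    train: Sequence[REExample],
    eval_set: Sequence[REExample],
    enc: EncoderConfig,
    grid: dict[str, list],
    seed: int = 0,
    tokenizer: Optional[WordTokenizer] = None,
    batch_size: int = 8,
) -> list[tuple[TrainConfig, float]]:
    """Exhaustively train/evaluate every grid point; ranked by macro-F1.

    Ties are broken toward fewer epochs, then lower learning rate.  The
    evaluation set should be a held-out validation split; passing the test
    set reproduces the tuning-on-test convention and is the caller's choice.
    """
    from .metrics import class_metrics, confusion_matrix

    configs = enumerate_grid(grid, seed=seed, batch_size=batch_size)
    if not configs:
        raise ValueError("empty grid")
    if tokenizer is None:
        texts = [e.sentence_a for e in list(train) + list(eval_set)]
        texts += [e.sentence_b for e in list(train) + list(eval_set)]
        tokenizer = WordTokenizer.build(texts)
    gold = [e.label for e in eval_set]
    results: list[tuple[TrainConfig, float]] = []
    for tc in configs:
        state = train_classifier(train, enc, tc, tokenizer=tokenizer)
        pred = [p.argmax for p in predict_batch(state, eval_set)]
        cm = confusion_matrix(gold, pred)
        _, summary = class_metrics(cm)
        results.append((tc, summary.macro_f1_raw))
    results.sort(key=lambda t: (-t[1], t[0].epochs, t[0].learning_rate))
    return results


# ---------------------------------------------------------------------------
# serialization

def save_classifier(state: ClassifierState, path: Union[str, Path]) -> None:
    """Persist weights (.npz) and config/vocabulary (.json) side by side."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **state.params)
    meta = {
        "vocab": state.tokenizer.itos,
        "encoder": {
            "num_layers": state.encoder.num_layers,
            "num_heads": state.encoder.num_heads,
            "hidden_dim": state.encoder.hidden_dim,
            "max_seq_len": state.encoder.max_seq_len,
            "vocab_size": state.encoder.vocab_size,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")


def load_classifier(path: Union[str, Path]) -> ClassifierState:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k].copy() for k in data.files}
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    tokenizer = WordTokenizer([])
    tokenizer.itos = list(meta["vocab"])
    tokenizer.stoi = {w: i for i, w in enumerate(tokenizer.itos)}
    enc = EncoderConfig(**meta["encoder"])
    return ClassifierState(params=params, tokenizer=tokenizer, encoder=enc)
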