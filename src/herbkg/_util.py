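"""Small shared helpers."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "split_sentences"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed metric tables do.

    Python's built-in ``round`` uses banker's rounding (81.25 -> 81.2); the
    reporting convention here requires 81.25 -> 81.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9\[])")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence segmentation.

    Splits on sentence-final punctuation followed by whitespace and an
    uppercase letter, digit or placeholder bracket.  Deliberately simple and
    deterministic; abbreviations with capitalised continuations will
    over-split, which downstream consumers tolerate.
    """
    parts = _SENT_BOUNDARY.split(text)
    return [p for p in (s.strip() for s in parts) if p]


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of :func:`split_sentences` segments within ``text``."""
    spans = []
    cursor = 0
    for sent in split_sentences(text):
        start = text.index(sent, cursor)
        spans.append((start, start + len(sent)))
        cursor = start + len(sent)
    return spans
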