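"""Reading, writing and validating the PubTator annotation exchange format.

A PubTator file is plain UTF-8 text in which documents are separated by blank
lines.  Each document block carries four sections, every line starting with
the PubMed identifier:

* a title line and an abstract line (two fields),
* zero or more entity-mention lines — six fields: pmid, start offset, end
  offset, surface text, entity type, concept identifier,
* zero or more relation lines — four fields: pmid, relation label, head
  concept id, tail concept id.

Mention offsets are 0-based, end-exclusive character positions into the
concatenation ``title + " " + abstract`` (title offsets start at 0, abstract
mentions continue past the title).  Both the tab-delimited dialect and the
pipe-delimited dialect (``pmid|t|...`` / ``pmid|a|...`` header lines) are
accepted on input; output is tab-delimited.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = [
    "EntityMention",
    "RelationAnnotation",
    "AnnotatedDocument",
    "Violation",
    "PubTatorParseError",
    "parse_pubtator",
    "write_pubtator",
    "validate_document",
    "read_file",
    "write_file",
]

#: Separator inserted between title and abstract when concatenating the
#: document text that mention offsets index.  Kept configurable because
#: exports in the wild differ on the number of separator characters.
TITLE_ABSTRACT_SEP = " "


class PubTatorParseError(ValueError):
    """Malformed PubTator input; the message names the offending line."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity mention located by character offsets.

    ``start``/``end`` are 0-based, end-exclusive offsets into the document's
    concatenated title-plus-abstract text; ``text`` is the surface form at
    that slice; ``etype`` is an ontology type (Herb, Chemical, Disease, Gene)
    or a raw NER tag (Species, Mutation, Cellline) before adaptation;
    ``entity_id`` is the normalized concept identifier.
    """

    pmid: str
    start: int
    end: int
    text: str
    etype: str
    entity_id: str


@dataclass(frozen=True)
class RelationAnnotation:
    """A document-level relation between two concept identifiers."""

    pmid: str
    rtype: str
    head_id: str
    tail_id: str


@dataclass(frozen=True)
class AnnotatedDocument:
    """One abstract with its entity mentions and gold relations."""

    pmid: str
    title: str
    abstract: str
    mentions: tuple[EntityMention, ...] = ()
    relations: tuple[RelationAnnotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mentions", tuple(self.mentions))
        object.__setattr__(self, "relations", tuple(self.relations))

    @property
    def text(self) -> str:
        """Concatenated title + separator + abstract, the offset frame."""
        return self.concat_text()

    def concat_text(self, sep: str = TITLE_ABSTRACT_SEP) -> str:
        return f"{self.title}{sep}{self.abstract}" if self.abstract else self.title

    def mention_by_id(self, entity_id: str) -> Union[EntityMention, None]:
        """First mention carrying ``entity_id`` (document order), if any."""
        for m in self.mentions:
            if m.entity_id == entity_id:
                return m
        return None


@dataclass(frozen=True)
class Violation:
    """One validation finding; violations are data, never exceptions."""

    code: str
    message: str
    pmid: str


def _split_fields(line: str) -> list[str]:
    """Split a PubTator line, accepting tab or pipe delimiters."""
    if "\t" in line:
        return line.split("\t")
    return line.split("|")


def _parse_block(lines: list[tuple[int, str]]) -> AnnotatedDocument:
    pmid = None
    title = None
    abstract = ""
    mentions: list[EntityMention] = []
    relations: list[RelationAnnotation] = []
    for lineno, line in lines:
        # pipe-dialect header lines pmid|t|... / pmid|a|...
        if "|" in line and "\t" not in line:
            head, _, rest = line.partition("|")
            marker, _, payload = rest.partition("|")
            if marker in ("t", "a"):
                pmid = pmid or head
                if marker == "t":
                    title = payload
                else:
                    abstract = payload
                continue
        fields = _split_fields(line)
        if len(fields) == 6:
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise PubTatorParseError(
                    f"line {lineno}: non-integer mention offsets: {line!r}"
                ) from None
            mentions.append(
                EntityMention(fields[0], start, end, fields[3], fields[4], fields[5])
            )
            pmid = pmid or fields[0]
        elif len(fields) == 4:
            relations.append(
                RelationAnnotation(fields[0], fields[1], fields[2], fields[3])
            )
            pmid = pmid or fields[0]
        elif len(fields) == 2:
            pmid = pmid or fields[0]
            if title is None:
                title = fields[1]
            else:
                abstract = fields[1]
        else:
            raise PubTatorParseError(
                f"line {lineno}: expected 2, 4 or 6 fields, got {len(fields)}: {line!r}"
            )
    if pmid is None or title is None:
        first = lines[0][0] if lines else "?"
        raise PubTatorParseError(f"block at line {first}: missing title line")
    return AnnotatedDocument(pmid, title, abstract, tuple(mentions), tuple(relations))


def parse_pubtator(stream: Union[str, Iterable[str]]) -> list[AnnotatedDocument]:
    """Parse PubTator text (a string or an iterable of lines) into documents.

    Blocks are separated by blank lines; section order within a block does
    not affect the result.  Malformed lines raise
    :class:`PubTatorParseError` naming the line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    docs: list[AnnotatedDocument] = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.strip() == "":
            if block:
                docs.append(_parse_block(block))
                block = []
            continue
        block.append((lineno, line))
    if block:
        docs.append(_parse_block(block))
    return docs


def validate_document(doc: AnnotatedDocument) -> list[Violation]:
    """Check mention offsets and relation endpoints; return all violations.

    The report is empty iff every mention's ``[start, end)`` slice of the
    concatenated text equals its surface text and every relation endpoint
    resolves to some mention's concept id.
    """
    violations: list[Violation] = []
    text = doc.text
    ids = {m.entity_id for m in doc.mentions}
    for m in doc.mentions:
        if m.pmid != doc.pmid:
            violations.append(
                Violation("pmid-mismatch", f"mention {m.text!r} carries pmid {m.pmid}", doc.pmid)
            )
        if m.start >= m.end:
            violations.append(
                Violation("empty-span", f"mention {m.text!r} has start {m.start} >= end {m.end}", doc.pmid)
            )
            continue
        if m.start < 0 or m.end > len(text):
            violations.append(
                Violation(
                    "out-of-range",
                    f"mention {m.text!r} spans [{m.start}, {m.end}) outside text of length {len(text)}",
                    doc.pmid,
                )
            )
            continue
        if text[m.start : m.end] != m.text:
            violations.append(
                Violation(
                    "slice-mismatch",
                    f"mention text {m.text!r} != slice {text[m.start:m.end]!r} at [{m.start}, {m.end})",
                    doc.pmid,
                )
            )
    for r in doc.relations:
        if r.pmid != doc.pmid:
            violations.append(
                Violation("pmid-mismatch", f"relation {r.rtype} carries pmid {r.pmid}", doc.pmid)
            )
        for endpoint in (r.head_id, r.tail_id):
            if endpoint not in ids:
                violations.append(
                    Violation(
                        "unresolved-endpoint",
                        f"relation {r.rtype} endpoint {endpoint!r} matches no mention id",
                        doc.pmid,
                    )
                )
    return violations


def write_pubtator(docs: Iterable[AnnotatedDocument]) -> str:
    """Serialize documents to tab-delimited PubTator text.

    Sections are emitted in the order title, abstract, mentions, relations,
    with one blank line between documents; the output re-parses to an equal
    value.  Mention-level invariant violations (bad offsets, slice
    mismatches) abort the write; unresolved relation endpoints are written
    through, since truncated exports legitimately contain them.
    """
    blocks: list[str] = []
    for doc in docs:
        fatal = [
            v
            for v in validate_document(doc)
            if v.code in ("empty-span", "out-of-range", "slice-mismatch")
        ]
        if fatal:
            raise ValueError(
                f"document {doc.pmid}: refusing to write invalid mentions: "
                + "; ".join(v.message for v in fatal)
            )
        lines = [f"{doc.pmid}\t{doc.title}", f"{doc.pmid}\t{doc.abstract}"]
        for m in doc.mentions:
            lines.append(
                f"{m.pmid}\t{m.start}\t{m.end}\t{m.text}\t{m.etype}\t{m.entity_id}"
            )
        for r in doc.relations:
            lines.append(f"{r.pmid}\t{r.rtype}\t{r.head_id}\t{r.tail_id}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_file(path: Union[str, Path]) -> list[AnnotatedDocument]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_pubtator(fh)


def write_file(docs: Iterable[AnnotatedDocument], path: Union[str, Path]) -> None:
    Path(path).write_text(write_pubtator(docs), encoding="utf-8")
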