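"""Readers and writers for brat/shared-task standoff and parser output.

The standoff layout is the shared-task distribution format: raw text in
``.txt``, protein mentions in ``.a1`` (``T<id>\\t<Type> <start> <end>\\t<text>``),
and triggers plus events in ``.a2`` (trigger ``T``-lines in the same shape,
event lines ``E<id>\\t<Type>:T<id> Theme:<ref> [Theme2:<ref> ...] [Cause:<ref>]``).

Dependency parses and predicate-argument structures arrive as parser OUTPUT
in a CoNLL-style TSV dialect: one token per line
(``index  surface  stem  pos  head  label``, head ``-1`` for the root),
blank line between sentences, and per-sentence PAS rows
``PAS\\t<pred_index>\\t<role>:<arg_index> ...``.  This package never runs a
parser itself.
"""

from __future__ import annotations

import re

from .errors import AlignmentError, IntegrityError, SerializationError, StandoffParseError
from .model import (
    DependencyArc,
    Document,
    EventRecord,
    PASPredicate,
    ProteinMention,
    Sentence,
    Token,
    Trigger,
    event_reference_order,
    validate_document,
)

_SPAN_LINE = re.compile(r"^(T\w+)\t(\S+) (\d+) (\d+)\t(.*)$")
_EVENT_LINE = re.compile(r"^(E\w+)\t(\S+):(T\w+)((?: \S+:\S+)*)\s*$")
_THEME_KEY = re.compile(r"^Theme\d*$")


def _parse_span_lines(block: str, what: str):
    out = []
    for lineno, line in enumerate(block.splitlines(), start=1):
        if not line.strip():
            continue
        m = _SPAN_LINE.match(line)
        if m is None:
            if line.startswith("T"):
                raise StandoffParseError(f"{what} line {lineno}: malformed span line {line!r}")
            yield ("other", lineno, line)
            continue
        tid, ann_type, start, end, text = m.groups()
        yield ("span", lineno, (tid, ann_type, int(start), int(end), text))
    return out


def read_standoff(txt_text: str, a1_text: str, a2_text: str | None = None) -> Document:
    """Build a Document from raw text plus .a1/.a2 annotation content.

    ``a2_text`` may be omitted or empty, in which case the document carries
    protein mentions only.  Every annotated span is checked against the text
    slice at its offsets; a mismatch raises :class:`IntegrityError`.
    """
    doc = Document(doc_id="doc", text=txt_text)
    for kind, lineno, payload in _parse_span_lines(a1_text, ".a1"):
        if kind != "span":
            raise StandoffParseError(f".a1 line {lineno}: unexpected line {payload!r}")
        tid, ann_type, start, end, text = payload
        doc.proteins.append(ProteinMention(id=tid, char_start=start, char_end=end, text=text))

    if a2_text:
        event_lines: list[tuple[int, str]] = []
        for kind, lineno, payload in _parse_span_lines(a2_text, ".a2"):
            if kind == "span":
                tid, ann_type, start, end, text = payload
                doc.triggers.append(
                    Trigger(id=tid, event_type=ann_type, char_start=start, char_end=end, text=text)
                )
            else:
                event_lines.append((lineno, payload))
        for lineno, line in event_lines:
            m = _EVENT_LINE.match(line)
            if m is None:
                raise StandoffParseError(f".a2 line {lineno}: malformed event line {line!r}")
            eid, etype, trig_id, arg_blob = m.groups()
            themes: list[str] = []
            cause = None
            for part in arg_blob.split():
                key, _, ref = part.partition(":")
                if _THEME_KEY.match(key):
                    themes.append(ref)
                elif key == "Cause":
                    if cause is not None:
                        raise StandoffParseError(f".a2 line {lineno}: multiple Cause arguments")
                    cause = ref
                else:
                    raise StandoffParseError(f".a2 line {lineno}: unknown argument key {key!r}")
            doc.events.append(
                EventRecord(id=eid, event_type=etype, trigger_id=trig_id, themes=themes, cause=cause)
            )
    validate_document(doc)
    return doc


def write_a1(document: Document) -> str:
    """Serialize protein mentions to .a1 content."""
    lines = [
        f"{p.id}\tProtein {p.char_start} {p.char_end}\t{p.text}"
        for p in document.proteins
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_a2(document: Document) -> str:
    """Serialize triggers and events to .a2 content (T-lines, then E-lines).

    Raises :class:`SerializationError` on dangling or cyclic references.
    """
    known = {p.id for p in document.proteins}
    known |= {t.id for t in document.triggers}
    known |= {e.id for e in document.events}
    trigger_ids = {t.id for t in document.triggers}
    for ev in document.events:
        refs = [ev.trigger_id] + list(ev.themes) + ([ev.cause] if ev.cause else [])
        for ref in refs:
            if ref not in known:
                raise SerializationError(f"{ev.id}: reference to unknown id {ref!r}")
        if ev.trigger_id not in trigger_ids:
            raise SerializationError(f"{ev.id}: trigger reference {ev.trigger_id!r} is not a trigger")
    try:
        event_reference_order(document.events)
    except IntegrityError as exc:
        raise SerializationError(str(exc)) from exc

    lines = [
        f"{t.id}\t{t.event_type} {t.char_start} {t.char_end}\t{t.text}"
        for t in sorted(document.triggers, key=lambda t: _id_key(t.id))
    ]
    for ev in sorted(document.events, key=lambda e: _id_key(e.id)):
        parts = [f"{ev.id}\t{ev.event_type}:{ev.trigger_id}"]
        for i, theme in enumerate(ev.themes):
            key = "Theme" if i == 0 else f"Theme{i + 1}"
            parts.append(f"{key}:{theme}")
        if ev.cause:
            parts.append(f"Cause:{ev.cause}")
        lines.append(parts[0] + (" " + " ".join(parts[1:]) if len(parts) > 1 else ""))
    return "\n".join(lines) + ("\n" if lines else "")


def _id_key(ann_id: str) -> tuple:
    m = re.match(r"^([A-Za-z]+)(\d+)$", ann_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (ann_id, 0)


def read_parses(parse_text: str, document: Document) -> Document:
    """Attach tokens, dependency arcs and PAS records to a document.

    Token character offsets are recovered by aligning each surface form
    against the document text left to right (whitespace skipped between
    tokens).  Sentences are created to tile the text; when the document
    already carries sentences the block count must match.
    """
    blocks = [b for b in re.split(r"\n\s*\n", parse_text) if b.strip()]
    if document.sentences and len(blocks) != len(document.sentences):
        raise AlignmentError(
            f"{document.doc_id}: parse has {len(blocks)} sentences, "
            f"document has {len(document.sentences)}"
        )

    text = document.text
    cursor = 0
    sentences: list[Sentence] = []
    for block in blocks:
        tokens: list[Token] = []
        arcs: list[DependencyArc] = []
        predicates: list[PASPredicate] = []
        heads: list[tuple[int, int, str]] = []
        for raw in block.splitlines():
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if cols[0] == "PAS":
                if len(cols) < 2:
                    raise StandoffParseError(f"malformed PAS row {line!r}")
                pred_idx = int(cols[1])
                args = []
                for part in cols[2:]:
                    for item in part.split():
                        role, _, arg = item.partition(":")
                        args.append((role, int(arg)))
                predicates.append(PASPredicate(predicate_index=pred_idx, arguments=tuple(args)))
                continue
            if len(cols) != 6:
                raise StandoffParseError(f"expected 6 columns in parse line {line!r}")
            idx, surface, stem, pos, head, label = cols
            idx, head = int(idx), int(head)
            if idx != len(tokens):
                raise StandoffParseError(f"non-consecutive token index {idx} in {line!r}")
            if head == idx:
                raise StandoffParseError(f"self-loop at token {idx} in parse")
            # align surface against the document text
            while cursor < len(text) and text[cursor].isspace():
                cursor += 1
            if text[cursor:cursor + len(surface)] != surface:
                raise AlignmentError(
                    f"{document.doc_id}: token {surface!r} does not align at char {cursor}"
                )
            tokens.append(Token(index=idx, surface=surface, stem=stem, pos=pos,
                                char_start=cursor, char_end=cursor + len(surface)))
            cursor += len(surface)
            if head >= 0:
                heads.append((head, idx, label))
        n = len(tokens)
        for head, dep, label in heads:
            if not (0 <= head < n):
                raise StandoffParseError(f"head index {head} out of range for {n}-token sentence")
            arcs.append(DependencyArc(head_index=head, dependent_index=dep, label=label))
        for pred in predicates:
            indices = [pred.predicate_index] + [a for _, a in pred.arguments]
            if any(not (0 <= i < n) for i in indices):
                raise StandoffParseError(f"PAS index out of range in {n}-token sentence")
        sentences.append(Sentence(tokens=tokens, arcs=arcs, predicates=predicates))

    # tail whitespace belongs to the last sentence
    while cursor < len(text) and text[cursor].isspace():
        cursor += 1
    if cursor < len(text):
        raise AlignmentError(
            f"{document.doc_id}: parse covers only {cursor}/{len(text)} characters"
        )
    start = 0
    for i, sent in enumerate(sentences):
        end = len(text) if i == len(sentences) - 1 else sentences[i + 1].tokens[0].char_start
        sent.sent_start, sent.sent_end = start, end
        start = end
    document.sentences = sentences
    validate_document(document)
    return document


def split_sentences(text: str) -> list[str]:
    """Deterministic sentence split (". " or newline) for the fixtures path."""
    pieces = re.split(r"(?<=\.)\s+|\n+", text)
    return [p for p in pieces if p.strip()]
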