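"""Offset-anchored document model for biomedical event annotations.

Documents carry raw text, protein mentions, typed trigger spans and nested
events in the 4-tuple representation (type, trigger, themes, cause), plus
per-sentence dependency arcs and predicate-argument structures ingested from
parser output.  Character offsets are 0-based half-open throughout, matching
the brat standoff convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import IntegrityError

# The closed registry of event types (GENIA-style shared-task ontology).
SIMPLE_TYPES = (
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Phosphorylation",
    "Localization",
)
BINDING_TYPE = "Binding"
REGULATION_TYPES = ("Regulation", "Positive_regulation", "Negative_regulation")
EVENT_TYPES = SIMPLE_TYPES + (BINDING_TYPE,) + REGULATION_TYPES

NEGATIVE_LABEL = "NEGATIVE"
TRIGGER_LABELS = EVENT_TYPES + (NEGATIVE_LABEL,)

THEME = "THEME"
CAUSE = "CAUSE"
EDGE_LABELS = (THEME, CAUSE, NEGATIVE_LABEL)


def is_regulation(event_type: str) -> bool:
    return event_type in REGULATION_TYPES


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    stem: str
    pos: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class DependencyArc:
    head_index: int
    dependent_index: int
    label: str


@dataclass(frozen=True)
class PASPredicate:
    predicate_index: int
    arguments: tuple[tuple[str, int], ...]  # (role, token index)


@dataclass
class Sentence:
    tokens: list[Token]
    arcs: list[DependencyArc] = field(default_factory=list)
    predicates: list[PASPredicate] = field(default_factory=list)
    sent_start: int = 0
    sent_end: int = 0

    def __len__(self) -> int:
        return len(self.tokens)

    def token_at_char(self, char_offset: int) -> Optional[int]:
        """Index of the token whose span contains ``char_offset``, if any."""
        for tok in self.tokens:
            if tok.char_start <= char_offset < tok.char_end:
                return tok.index
        return None


@dataclass(frozen=True)
class ProteinMention:
    id: str
    char_start: int
    char_end: int
    text: str


@dataclass(frozen=True)
class Trigger:
    id: str
    event_type: str
    char_start: int
    char_end: int
    text: str


@dataclass
class EventRecord:
    id: str
    event_type: str
    trigger_id: str
    themes: list[str]  # ProteinMention ids or EventRecord ids, ordered
    cause: Optional[str] = None


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    proteins: list[ProteinMention] = field(default_factory=list)
    triggers: list[Trigger] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)

    # ---- lookups -------------------------------------------------------

    def protein_by_id(self) -> dict[str, ProteinMention]:
        return {p.id: p for p in self.proteins}

    def trigger_by_id(self) -> dict[str, Trigger]:
        return {t.id: t for t in self.triggers}

    def event_by_id(self) -> dict[str, EventRecord]:
        return {e.id: e for e in self.events}

    def sentence_of_span(self, char_start: int, char_end: int) -> int:
        """Index of the unique sentence containing [char_start, char_end)."""
        for i, sent in enumerate(self.sentences):
            if sent.sent_start <= char_start and char_end <= sent.sent_end:
                return i
        raise IntegrityError(
            f"{self.doc_id}: span [{char_start},{char_end}) lies in no sentence"
        )

    def anchor_token(self, char_start: int, char_end: int) -> tuple[int, int]:
        """(sentence index, token index) anchoring a span.

        Multi-token spans anchor at the token containing their last
        character (head-token convention for token labeling).
        """
        si = self.sentence_of_span(char_start, char_end)
        ti = self.sentences[si].token_at_char(char_end - 1)
        if ti is None:
            raise IntegrityError(
                f"{self.doc_id}: no token covers char {char_end - 1}"
            )
        return si, ti

    def protein_token_indices(self, sentence_index: int) -> set[int]:
        """Token indices inside any protein span of the given sentence."""
        sent = self.sentences[sentence_index]
        covered: set[int] = set()
        for prot in self.proteins:
            if prot.char_end <= sent.sent_start or prot.char_start >= sent.sent_end:
                continue
            for tok in sent.tokens:
                if tok.char_start < prot.char_end and prot.char_start < tok.char_end:
                    covered.add(tok.index)
        return covered


def event_reference_order(events: Iterable[EventRecord]) -> list[EventRecord]:
    """Topologically order events so referenced sub-events come first.

    Raises IntegrityError if the event-reference graph contains a cycle.
    """
    events = list(events)
    by_id = {e.id: e for e in events}
    order: list[EventRecord] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(eid: str, stack: list[str]) -> None:
        if state.get(eid) == 1:
            return
        if state.get(eid) == 0:
            raise IntegrityError(f"cyclic event references: {' -> '.join(stack + [eid])}")
        state[eid] = 0
        ev = by_id[eid]
        for ref in list(ev.themes) + ([ev.cause] if ev.cause else []):
            if ref in by_id:
                visit(ref, stack + [eid])
        state[eid] = 1
        order.append(ev)

    for ev in events:
        visit(ev.id, [])
    return order


def validate_event(event: EventRecord, protein_ids: set[str], event_ids: set[str]) -> None:
    """Enforce per-type argument arity on a single event record."""
    etype = event.event_type
    if etype not in EVENT_TYPES:
        raise IntegrityError(f"{event.id}: unknown event type {etype!r}")
    refs = set(event.themes) | ({event.cause} if event.cause else set())
    unknown = refs - protein_ids - event_ids
    if unknown:
        raise IntegrityError(f"{event.id}: unresolved references {sorted(unknown)}")
    if etype in SIMPLE_TYPES:
        if len(event.themes) != 1 or event.cause is not None:
            raise IntegrityError(f"{event.id}: {etype} takes exactly one theme, no cause")
        if event.themes[0] not in protein_ids:
            raise IntegrityError(f"{event.id}: {etype} theme must be a protein")
    elif etype == BINDING_TYPE:
        if len(event.themes) < 1 or event.cause is not None:
            raise IntegrityError(f"{event.id}: Binding takes >=1 themes, no cause")
        if any(t not in protein_ids for t in event.themes):
            raise IntegrityError(f"{event.id}: Binding themes must be proteins")
    else:  # regulation family: one theme (protein or event), optional cause
        if len(event.themes) != 1:
            raise IntegrityError(f"{event.id}: {etype} takes exactly one theme")


def validate_document(doc: Document) -> None:
    """Check document-level invariants (spans, uniqueness, acyclicity)."""
    seen_ids: set[str] = set()
    for ann in list(doc.proteins) + list(doc.triggers):
        if ann.id in seen_ids:
            raise IntegrityError(f"{doc.doc_id}: duplicate annotation id {ann.id}")
        seen_ids.add(ann.id)
        if not (0 <= ann.char_start < ann.char_end <= len(doc.text)):
            raise IntegrityError(f"{doc.doc_id}: bad span on {ann.id}")
        if doc.text[ann.char_start:ann.char_end] != ann.text:
            raise IntegrityError(
                f"{doc.doc_id}: {ann.id} text {ann.text!r} does not match "
                f"document slice {doc.text[ann.char_start:ann.char_end]!r}"
            )
    for trig in doc.triggers:
        if trig.event_type not in EVENT_TYPES:
            raise IntegrityError(f"{doc.doc_id}: {trig.id} has unknown type {trig.event_type}")
    protein_ids = {p.id for p in doc.proteins}
    event_ids = {e.id for e in doc.events}
    trigger_ids = {t.id for t in doc.triggers}
    for ev in doc.events:
        if ev.trigger_id not in trigger_ids:
            raise IntegrityError(f"{doc.doc_id}: {ev.id} references missing trigger")
        validate_event(ev, protein_ids, event_ids)
    event_reference_order(doc.events)  # raises on cycles
    if doc.sentences:
        cursor = 0
        for sent in doc.sentences:
            if sent.sent_start != cursor:
                raise IntegrityError(f"{doc.doc_id}: sentences do not tile the text")
            cursor = sent.sent_end
        if cursor != len(doc.text):
            raise IntegrityError(f"{doc.doc_id}: sentences do not cover the text")
        for ann in list(doc.proteins) + list(doc.triggers):
            doc.sentence_of_span(ann.char_start, ann.char_end)
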