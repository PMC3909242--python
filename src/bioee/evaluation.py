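"""Scoring predicted events against gold annotations.

Events match when their types agree, their trigger spans agree (exactly in
``strict`` mode, or up to a one-token extension on either side in
``approximate`` mode) and their theme/cause references match recursively —
protein arguments by identity, event arguments by a matching sub-event.
Matching is greedy one-to-one per document; precision, recall and F1 are
reported per event type and micro-averaged, with 0/0 scored as 0.  A
trigger-level report (span + type only) is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

from .errors import AlignmentError
from .model import Document, EventRecord, Trigger

STRICT = "strict"
APPROXIMATE = "approximate"
MODES = (STRICT, APPROXIMATE)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision/recall/F1 with the 0/0 -> 0 convention."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class TypeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def scores(self) -> tuple[float, float, float]:
        return prf(self.tp, self.fp, self.fn)


@dataclass
class EvalReport:
    mode: str
    per_type: dict[str, TypeCounts] = field(default_factory=dict)
    trigger_per_type: dict[str, TypeCounts] = field(default_factory=dict)

    def _micro(self, table: dict[str, TypeCounts]) -> tuple[int, int, int]:
        return (sum(c.tp for c in table.values()),
                sum(c.fp for c in table.values()),
                sum(c.fn for c in table.values()))

    @property
    def micro(self) -> tuple[float, float, float]:
        return prf(*self._micro(self.per_type))

    @property
    def micro_counts(self) -> tuple[int, int, int]:
        return self._micro(self.per_type)

    @property
    def trigger_micro(self) -> tuple[float, float, float]:
        return prf(*self._micro(self.trigger_per_type))

    def to_tsv(self) -> str:
        lines = ["level\ttype\ttp\tfp\tfn\tprecision\trecall\tf1"]
        for level, table in (("event", self.per_type), ("trigger", self.trigger_per_type)):
            for etype in sorted(table):
                c = table[etype]
                p, r, f1 = c.scores
                lines.append(f"{level}\t{etype}\t{c.tp}\t{c.fp}\t{c.fn}\t{p:.4f}\t{r:.4f}\t{f1:.4f}")
            tp, fp, fn = self._micro(table)
            p, r, f1 = prf(tp, fp, fn)
            lines.append(f"{level}\tMICRO\t{tp}\t{fp}\t{fn}\t{p:.4f}\t{r:.4f}\t{f1:.4f}")
        return "\n".join(lines) + "\n"

    def pretty(self) -> str:
        p, r, f1 = self.micro
        tp_, rr, tf = self.trigger_micro
        return (f"[{self.mode}] events  P={p:.3f} R={r:.3f} F1={f1:.3f} | "
                f"triggers P={tp_:.3f} R={rr:.3f} F1={tf:.3f}")


# ---------------------------------------------------------------------------
# span and event matching
# ---------------------------------------------------------------------------

def _token_span(doc: Document, char_start: int, char_end: int) -> Optional[tuple[int, int, int]]:
    """(sentence, first token, last token) covering a character span."""
    if not doc.sentences:
        return None
    si = doc.sentence_of_span(char_start, char_end)
    sent = doc.sentences[si]
    covered = [t.index for t in sent.tokens
               if t.char_start < char_end and char_start < t.char_end]
    if not covered:
        return None
    return si, min(covered), max(covered)


def spans_match(gold_doc: Document, pred_doc: Document,
                gold: tuple[int, int], pred: tuple[int, int], mode: str) -> bool:
    if gold == pred:
        return True
    if mode == STRICT:
        return False
    gspan = _token_span(gold_doc, *gold)
    pspan = _token_span(pred_doc, *pred)
    if gspan is None or pspan is None:
        return False
    if gspan[0] != pspan[0]:
        return False
    return abs(gspan[1] - pspan[1]) <= 1 and abs(gspan[2] - pspan[2]) <= 1


class _Matcher:
    """Recursive event compatibility with memoisation, per document pair."""

    def __init__(self, gold_doc: Document, pred_doc: Document, mode: str):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.gold_doc, self.pred_doc = gold_doc, pred_doc
        self.g_events = gold_doc.event_by_id()
        self.p_events = pred_doc.event_by_id()
        self.g_triggers = gold_doc.trigger_by_id()
        self.p_triggers = pred_doc.trigger_by_id()
        self._memo: dict[tuple[str, str], bool] = {}

    def trigger_match(self, g: Trigger, p: Trigger) -> bool:
        return g.event_type == p.event_type and spans_match(
            self.gold_doc, self.pred_doc,
            (g.char_start, g.char_end), (p.char_start, p.char_end), self.mode)

    def ref_match(self, g_ref: str, p_ref: str) -> bool:
        g_is_event = g_ref in self.g_events
        p_is_event = p_ref in self.p_events
        if g_is_event != p_is_event:
            return False
        if not g_is_event:
            return g_ref == p_ref  # proteins share the .a1 id space
        return self.event_match(self.g_events[g_ref], self.p_events[p_ref])

    def event_match(self, g: EventRecord, p: EventRecord) -> bool:
        key = (g.id, p.id)
        if key in self._memo:
            return self._memo[key]
        self._memo[key] = False  # cycles (impossible in valid docs) fail closed
        ok = (g.event_type == p.event_type
              and self.trigger_match(self.g_triggers[g.trigger_id],
                                     self.p_triggers[p.trigger_id])
              and len(g.themes) == len(p.themes)
              and ((g.cause is None) == (p.cause is None)))
        if ok and g.cause is not None:
            ok = self.ref_match(g.cause, p.cause)
        if ok and g.themes:
            ok = any(all(self.ref_match(gt, pt) for gt, pt in zip(g.themes, perm))
                     for perm in permutations(p.themes))
        self._memo[key] = ok
        return ok


def match_events(gold_doc: Document, pred_doc: Document,
                 mode: str = STRICT) -> list[tuple[str, str]]:
    """Greedy one-to-one matching of gold to predicted events; returns the
    matched (gold id, pred id) pairs."""
    matcher = _Matcher(gold_doc, pred_doc, mode)
    taken: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for g in gold_doc.events:
        for p in pred_doc.events:
            if p.id in taken:
                continue
            if matcher.event_match(g, p):
                pairs.append((g.id, p.id))
                taken.add(p.id)
                break
    return pairs


def _match_triggers(gold_doc: Document, pred_doc: Document,
                    mode: str) -> list[tuple[str, str]]:
    matcher = _Matcher(gold_doc, pred_doc, mode)
    taken: set[str] = set()
    pairs = []
    for g in gold_doc.triggers:
        for p in pred_doc.triggers:
            if p.id in taken:
                continue
            if matcher.trigger_match(g, p):
                pairs.append((g.id, p.id))
                taken.add(p.id)
                break
    return pairs


def evaluate(gold_docs: Sequence[Document], pred_docs: Sequence[Document],
             mode: str = STRICT) -> EvalReport:
    """Aggregate event- and trigger-level scores over aligned documents."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    preds = {d.doc_id: d for d in pred_docs}
    if sorted(preds) != sorted(d.doc_id for d in gold_docs):
        raise AlignmentError("gold and predicted document ids do not align")
    report = EvalReport(mode=mode)

    def tally(table: dict[str, TypeCounts], gold_items, pred_items, matched_pairs,
              type_of_gold, type_of_pred):
        matched_g = {g for g, _ in matched_pairs}
        matched_p = {p for _, p in matched_pairs}
        for item in gold_items:
            c = table.setdefault(type_of_gold(item), TypeCounts())
            if item.id in matched_g:
                c.tp += 1
            else:
                c.fn += 1
        for item in pred_items:
            if item.id not in matched_p:
                table.setdefault(type_of_pred(item), TypeCounts()).fp += 1

    for gold in gold_docs:
        pred = preds[gold.doc_id]
        tally(report.per_type, gold.events, pred.events,
              match_events(gold, pred, mode),
              lambda e: e.event_type, lambda e: e.event_type)
        tally(report.trigger_per_type, gold.triggers, pred.triggers,
              _match_triggers(gold, pred, mode),
              lambda t: t.event_type, lambda t: t.event_type)
    return report
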