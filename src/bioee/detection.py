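"""Trigger and argument detectors plus rule-based event assembly.

Trigger detection is token labeling: every non-protein token becomes an
instance labeled with one of the nine event types or NEGATIVE, and a
one-vs-rest linear SVM picks the class.  Argument (edge) detection
classifies directed trigger->protein and trigger->trigger candidates as
THEME, CAUSE or NEGATIVE.  Assembly turns the predicted triggers and edges
into nested event records respecting per-type argument arities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import MaxAbsScaler
from sklearn.svm import SVC

from .efcg import CGFIndex, CoocStats, FCDTable, cgf_vector, tpf_features
from .errors import AssemblyError, TrainingError
from .features import (
    EDF_FAMILIES,
    FeatureDictionaries,
    FeatureVector,
    merge,
    ngram_pair_features,
    ngram_window_features,
    pair_context_features,
    pas_features,
    parse_feature_name,
    token_features,
    walk_features,
)
from .model import (
    BINDING_TYPE,
    CAUSE,
    Document,
    EventRecord,
    NEGATIVE_LABEL,
    ProteinMention,
    SIMPLE_TYPES,
    THEME,
    Trigger,
    is_regulation,
    validate_event,
)

FEATURE_SETS = ("bf", "bf+tpf", "bf+tpf+cgf")


def _int32_indices(x):
    # libsvm-backed SVC rejects 64-bit sparse indices
    x = x.tocsr()
    x.indices = x.indices.astype(np.int32, copy=False)
    x.indptr = x.indptr.astype(np.int32, copy=False)
    return x


@dataclass
class Resources:
    """Shared statistical resources behind the optional feature families."""
    dicts: Optional[FeatureDictionaries] = None
    tpf_labeled: Optional[CoocStats] = None
    tpf_unlabeled: Optional[CoocStats] = None
    cgf_index: Optional[CGFIndex] = None
    cgf_table: Optional[FCDTable] = None


@dataclass
class TriggerInstance:
    doc_id: str
    sentence_index: int
    token_index: int
    features: FeatureVector
    label: str = NEGATIVE_LABEL


@dataclass
class EdgeInstance:
    doc_id: str
    source: str               # trigger id
    target: str               # trigger or protein id
    target_is_trigger: bool
    features: FeatureVector
    label: str = NEGATIVE_LABEL


def _sentence_proteins(doc: Document, si: int) -> list[tuple[ProteinMention, int]]:
    """Proteins anchored in sentence ``si`` with their anchor token index."""
    out = []
    for prot in doc.proteins:
        psi, pti = doc.anchor_token(prot.char_start, prot.char_end)
        if psi == si:
            out.append((prot, pti))
    return out


def _edf_names(fv: FeatureVector) -> list[str]:
    return [n for n in fv if parse_feature_name(n)[0] in EDF_FAMILIES]


def _instance_cgf(edf_source: FeatureVector, resources: Resources) -> FeatureVector:
    if resources.cgf_index is None or resources.cgf_table is None:
        return {}
    edfs = [e for e in _edf_names(edf_source) if e in resources.cgf_index.root_of]
    return cgf_vector(edfs, resources.cgf_index, resources.cgf_table)


def generate_trigger_instances(document: Document, with_gold: bool = False,
                               resources: Resources | None = None,
                               feature_set: str = "bf") -> list[TriggerInstance]:
    """One instance per non-protein token.

    Basic features are always on; ``feature_set`` adds TPF and/or CGF when
    the corresponding resources are available.  With ``with_gold`` the label
    comes from the gold trigger anchored at the token (head-token
    convention), otherwise NEGATIVE.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    res = resources or Resources()
    gold_anchor: dict[tuple[int, int], str] = {}
    if with_gold:
        for trig in document.triggers:
            gold_anchor[document.anchor_token(trig.char_start, trig.char_end)] = trig.event_type

    instances: list[TriggerInstance] = []
    for si, sent in enumerate(document.sentences):
        protein_tokens = document.protein_token_indices(si)
        sent_pas = pas_features(sent)
        sent_prots = _sentence_proteins(document, si)
        for ti in range(len(sent.tokens)):
            if ti in protein_tokens:
                continue
            fv = merge(token_features(sent, ti),
                       ngram_window_features(sent, ti),
                       walk_features(sent, ti),
                       sent_pas)
            if feature_set in ("bf+tpf", "bf+tpf+cgf"):
                fv = merge(fv, tpf_features(sent, ti, [p for p, _ in sent_prots],
                                            res.tpf_labeled, res.tpf_unlabeled))
            if feature_set == "bf+tpf+cgf" and sent_prots and res.dicts is not None:
                # EDFs for a trigger candidate come from its pair with the
                # nearest in-sentence protein
                nearest = min(sent_prots, key=lambda pt: (abs(pt[1] - ti), pt[1]))
                pti = nearest[1]
                if pti != ti:
                    t1, t2 = sorted((ti, pti))
                    edfs = pair_context_features(sent, t1, t2, res.dicts)
                    fv = merge(fv, _instance_cgf(edfs, res))
            label = gold_anchor.get((si, ti), NEGATIVE_LABEL) if with_gold else NEGATIVE_LABEL
            instances.append(TriggerInstance(document.doc_id, si, ti, fv, label))
    return instances


def _gold_edge_labels(document: Document) -> dict[tuple[str, str], str]:
    """Map (source trigger id, target id) -> THEME/CAUSE from gold events.

    Targets that are events resolve to their trigger; THEME wins on the rare
    pair carrying both roles.
    """
    events = document.event_by_id()
    labels: dict[tuple[str, str], str] = {}

    def resolve(ref: str) -> str:
        return events[ref].trigger_id if ref in events else ref

    for ev in document.events:
        if ev.cause:
            labels.setdefault((ev.trigger_id, resolve(ev.cause)), CAUSE)
    for ev in document.events:
        for theme in ev.themes:
            labels[(ev.trigger_id, resolve(theme))] = THEME
    return labels


def generate_edge_instances(document: Document, triggers: Sequence[Trigger],
                            with_gold: bool = False,
                            resources: Resources | None = None,
                            feature_set: str = "bf") -> list[EdgeInstance]:
    """Candidate edges: every trigger to every same-sentence protein, and —
    for regulation-type triggers only — to every other same-sentence trigger.
    Candidates never cross sentence boundaries."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    res = resources or Resources()
    gold = _gold_edge_labels(document) if with_gold else {}

    anchors = {t.id: document.anchor_token(t.char_start, t.char_end) for t in triggers}
    instances: list[EdgeInstance] = []
    for trig in triggers:
        si, ti = anchors[trig.id]
        sent = document.sentences[si]
        candidates: list[tuple[str, int, bool]] = []
        for prot, pti in _sentence_proteins(document, si):
            candidates.append((prot.id, pti, False))
        if is_regulation(trig.event_type):
            for other in triggers:
                if other.id == trig.id:
                    continue
                osi, oti = anchors[other.id]
                if osi == si and oti != ti:
                    candidates.append((other.id, oti, True))
        for target_id, tj, is_trig in candidates:
            if tj == ti:
                continue
            t1, t2 = sorted((ti, tj))
            fv = merge(ngram_pair_features(sent, t1, t2),
                       walk_features(sent, ti),
                       walk_features(sent, tj))
            if res.dicts is not None:
                edfs = pair_context_features(sent, t1, t2, res.dicts)
                fv = merge(fv, edfs)
                if feature_set == "bf+tpf+cgf":
                    fv = merge(fv, _instance_cgf(edfs, res))
            label = gold.get((trig.id, target_id), NEGATIVE_LABEL) if with_gold else NEGATIVE_LABEL
            instances.append(EdgeInstance(document.doc_id, trig.id, target_id,
                                          is_trig, fv, label))
    return instances


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

@dataclass
class ClassifierPart:
    """One trained one-vs-rest linear SVM with its feature index.

    Real-valued feature families (coupling scores) live on much smaller or
    larger scales than the binary indicators; a max-abs scaler fitted on the
    training matrix puts every column on [0, 1] so the margin treats them
    comparably.  Binary columns are unchanged by it.
    """
    vectorizer: DictVectorizer
    classifier: OneVsRestClassifier
    classes: tuple[str, ...]
    probability: bool
    scaler: MaxAbsScaler | None = None

    @property
    def feature_index(self) -> dict[str, int]:
        return dict(self.vectorizer.vocabulary_)

    def predict(self, feature_vectors: Sequence[FeatureVector]) -> tuple[list[str], np.ndarray]:
        """Argmax labels and per-class scores (probabilities when enabled,
        decision values otherwise) for a batch of instances.  Features never
        seen at training time are dropped by the vectorizer."""
        if not feature_vectors:
            return [], np.zeros((0, len(self.classes)))
        x = _int32_indices(self.vectorizer.transform(feature_vectors))
        if self.scaler is not None:
            x = _int32_indices(self.scaler.transform(x))
        if self.probability:
            scores = self.classifier.predict_proba(x)
        else:
            scores = self.classifier.decision_function(x)
            if scores.ndim == 1:
                scores = np.column_stack([-scores, scores])
        labels = [self.classes[i] for i in np.asarray(scores).argmax(axis=1)]
        return labels, np.asarray(scores)


@dataclass
class ModelBundle:
    trigger_model: Optional[ClassifierPart] = None
    edge_model: Optional[ClassifierPart] = None
    resources: Resources = field(default_factory=Resources)
    config: dict = field(default_factory=dict)


def train(instances: Sequence[TriggerInstance] | Sequence[EdgeInstance],
          seed: int = 13, c: float = 1.0, probability: bool = True) -> ClassifierPart:
    """Fit the one-vs-rest linear-kernel SVM.

    Shrinking and probability estimates are enabled (solver defaults
    otherwise); a one-vs-rest wrapper supplies the "Kth class positive"
    multi-class contract on top of the binary solver.  Deterministic for a
    fixed instance order and seed.
    """
    if not instances:
        raise TrainingError("no training instances")
    labels = [inst.label for inst in instances]
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise TrainingError(f"need at least 2 classes, got {classes}")
    vectorizer = DictVectorizer(sparse=True, sort=True)
    x = _int32_indices(vectorizer.fit_transform([inst.features for inst in instances]))
    scaler = MaxAbsScaler().fit(x)
    x = _int32_indices(scaler.transform(x))
    y = np.array([classes.index(lbl) for lbl in labels])
    base = SVC(kernel="linear", C=c, shrinking=True, probability=probability,
               random_state=seed)
    clf = OneVsRestClassifier(base)
    clf.fit(x, y)
    return ClassifierPart(vectorizer=vectorizer, classifier=clf,
                          classes=classes, probability=probability, scaler=scaler)


def _next_t_number(document: Document) -> int:
    num = 0
    for ann_id in [p.id for p in document.proteins] + [t.id for t in document.triggers]:
        if ann_id.startswith("T") and ann_id[1:].isdigit():
            num = max(num, int(ann_id[1:]))
    return num + 1


def predict_triggers(document: Document, bundle: ModelBundle,
                     feature_set: str = "bf") -> list[Trigger]:
    """Label every candidate token and merge adjacent tokens sharing a
    predicted non-NEGATIVE class into one trigger span."""
    if bundle.trigger_model is None:
        raise TrainingError("bundle has no trigger model")
    instances = generate_trigger_instances(document, with_gold=False,
                                           resources=bundle.resources,
                                           feature_set=feature_set)
    labels, _ = bundle.trigger_model.predict([inst.features for inst in instances])
    by_pos = {(inst.sentence_index, inst.token_index): lbl
              for inst, lbl in zip(instances, labels)}
    triggers: list[Trigger] = []
    counter = _next_t_number(document)
    for si, sent in enumerate(document.sentences):
        ti = 0
        while ti < len(sent.tokens):
            lbl = by_pos.get((si, ti), NEGATIVE_LABEL)
            if lbl == NEGATIVE_LABEL:
                ti += 1
                continue
            end = ti
            while end + 1 < len(sent.tokens) and by_pos.get((si, end + 1)) == lbl:
                end += 1
            start_char = sent.tokens[ti].char_start
            end_char = sent.tokens[end].char_end
            triggers.append(Trigger(id=f"T{counter}", event_type=lbl,
                                    char_start=start_char, char_end=end_char,
                                    text=document.text[start_char:end_char]))
            counter += 1
            ti = end + 1
    return triggers


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    target_is_trigger: bool
    label: str
    score: float = 1.0


def predict_edges(document: Document, triggers: Sequence[Trigger],
                  bundle: ModelBundle, feature_set: str = "bf") -> list[Edge]:
    """Classify every candidate pair; the edge keeps the argmax label and
    its score (probability of the predicted class)."""
    if bundle.edge_model is None:
        raise TrainingError("bundle has no edge model")
    instances = generate_edge_instances(document, triggers, with_gold=False,
                                        resources=bundle.resources,
                                        feature_set=feature_set)
    labels, scores = bundle.edge_model.predict([inst.features for inst in instances])
    edges = []
    for inst, lbl, row in zip(instances, labels, scores):
        edges.append(Edge(source=inst.source, target=inst.target,
                          target_is_trigger=inst.target_is_trigger,
                          label=lbl, score=float(row.max())))
    return edges


def gold_edges(document: Document) -> list[Edge]:
    """The gold THEME/CAUSE edges of a document (score 1), for sanity runs."""
    trigger_ids = {t.id for t in document.triggers}
    return [Edge(source=src, target=tgt, target_is_trigger=tgt in trigger_ids,
                 label=lbl, score=1.0)
            for (src, tgt), lbl in sorted(_gold_edge_labels(document).items())]


# ---------------------------------------------------------------------------
# event assembly
# ---------------------------------------------------------------------------

def assemble_events(triggers: Sequence[Trigger], edges: Sequence[Edge],
                    protein_ids: set[str]) -> list[EventRecord]:
    """Turn labeled edges into nested event records.

    Simple types emit one event per protein THEME edge (CAUSE edges are
    dropped); Binding collects all protein themes of a trigger into one
    event; regulation types emit one event per THEME edge, attaching the
    trigger's single highest-scoring CAUSE edge if any.  Themes pointing at
    triggers resolve recursively to that trigger's events, one event per
    resolved combination.  Reference cycles among triggers are broken by
    greedily keeping edges in descending score order and dropping any edge
    that would close a cycle, so the lowest-scoring closing edge goes first.
    """
    trig_by_id = {t.id: t for t in triggers}
    for edge in edges:
        if edge.source not in trig_by_id:
            raise AssemblyError(f"edge source {edge.source!r} is not a known trigger")
        if edge.target not in trig_by_id and edge.target not in protein_ids:
            raise AssemblyError(f"edge target {edge.target!r} is unknown")

    active = [e for e in edges if e.label in (THEME, CAUSE)]
    # break cycles among trigger->trigger edges, highest score first
    kept: list[Edge] = []
    succ: dict[str, set[str]] = {}

    def reaches(frm: str, to: str) -> bool:
        stack, seen = [frm], set()
        while stack:
            node = stack.pop()
            if node == to:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(succ.get(node, ()))
        return False

    for edge in sorted(active, key=lambda e: (-e.score, e.source, e.target, e.label)):
        if edge.target_is_trigger:
            if reaches(edge.target, edge.source):
                continue  # this edge would close a cycle: drop it
            succ.setdefault(edge.source, set()).add(edge.target)
        kept.append(edge)

    # assemble in dependency order: triggers whose trigger-themes are done first
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(tid: str) -> None:
        if state.get(tid) == 1:
            return
        state[tid] = 0
        for nxt in succ.get(tid, ()):
            if state.get(nxt) != 0:
                visit(nxt)
        state[tid] = 1
        order.append(tid)

    for trig in triggers:
        visit(trig.id)

    events: list[EventRecord] = []
    events_of: dict[str, list[str]] = {t.id: [] for t in triggers}
    counter = 1

    def new_event(etype: str, trig_id: str, themes: list[str],
                  cause: Optional[str]) -> None:
        nonlocal counter
        ev = EventRecord(id=f"E{counter}", event_type=etype, trigger_id=trig_id,
                         themes=themes, cause=cause)
        counter += 1
        events.append(ev)
        events_of[trig_id].append(ev.id)

    for tid in order:
        trig = trig_by_id[tid]
        theme_edges = [e for e in kept if e.source == tid and e.label == THEME]
        cause_edges = [e for e in kept if e.source == tid and e.label == CAUSE]
        if trig.event_type in SIMPLE_TYPES:
            for edge in theme_edges:
                if not edge.target_is_trigger:
                    new_event(trig.event_type, tid, [edge.target], None)
        elif trig.event_type == BINDING_TYPE:
            prots = [e.target for e in theme_edges if not e.target_is_trigger]
            if prots:
                new_event(trig.event_type, tid, prots, None)
        else:  # regulation family
            cause_ref: Optional[str] = None
            for edge in sorted(cause_edges, key=lambda e: (-e.score, e.target)):
                if edge.target_is_trigger:
                    sub = events_of.get(edge.target, [])
                    if sub:
                        cause_ref = sub[0]
                        break
                else:
                    cause_ref = edge.target
                    break
            for edge in theme_edges:
                if edge.target_is_trigger:
                    for sub_id in events_of.get(edge.target, []):
                        new_event(trig.event_type, tid, [sub_id], cause_ref)
                else:
                    new_event(trig.event_type, tid, [edge.target], cause_ref)

    event_ids = {e.id for e in events}
    for ev in events:
        validate_event(ev, protein_ids, event_ids)
    return events


def extract_events(document: Document, bundle: ModelBundle,
                   feature_set: str = "bf") -> Document:
    """Run the full pipeline on a parsed document, returning a copy carrying
    the predicted triggers and events."""
    triggers = predict_triggers(document, bundle, feature_set)
    edges = predict_edges(document, triggers, bundle, feature_set)
    events = assemble_events(triggers, edges, {p.id for p in document.proteins})
    used = {e.trigger_id for e in events}
    kept_triggers = [t for t in triggers if t.id in used]
    return Document(doc_id=document.doc_id, text=document.text,
                    sentences=document.sentences, proteins=list(document.proteins),
                    triggers=kept_triggers, events=events)
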