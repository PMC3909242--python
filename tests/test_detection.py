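"""Instance generation, SVM training/prediction, event assembly."""

import random

import pytest

from bioee.detection import (
    Edge,
    assemble_events,
    generate_edge_instances,
    generate_trigger_instances,
    gold_edges,
    predict_triggers,
    train,
    ModelBundle,
)
from bioee.errors import AssemblyError, TrainingError
from bioee.evaluation import evaluate
from bioee.model import (
    EVENT_TYPES,
    NEGATIVE_LABEL,
    Document,
    Trigger,
    event_reference_order,
    validate_event,
)


class TestTriggerInstances:
    def test_gold_labels_anchor_at_trigger_tokens(self, rflat_document):
        instances = generate_trigger_instances(rflat_document, with_gold=True)
        by_token = {rflat_document.sentences[i.sentence_index].tokens[i.token_index].surface: i.label
                    for i in instances}
        assert by_token["activates"] == "Positive_regulation"
        assert by_token["expression"] == "Gene_expression"
        others = {s: l for s, l in by_token.items() if s not in ("activates", "expression")}
        assert set(others.values()) == {NEGATIVE_LABEL}

    def test_protein_tokens_are_skipped(self, rflat_document):
        instances = generate_trigger_instances(rflat_document, with_gold=True)
        n_tokens = len(rflat_document.sentences[0].tokens)
        assert len(instances) == n_tokens - 2  # RFLAT-1 and RANTES excluded

    def test_document_without_gold_is_all_negative(self, rflat_document):
        instances = generate_trigger_instances(rflat_document, with_gold=False)
        assert {i.label for i in instances} == {NEGATIVE_LABEL}


class TestEdgeInstances:
    def test_candidates_and_gold_labels(self, rflat_document):
        doc = rflat_document
        instances = generate_edge_instances(doc, doc.triggers, with_gold=True)
        labels = {(i.source, i.target): i.label for i in instances}
        # T3 = activates (Positive_regulation), T4 = expression (Gene_expression)
        assert labels[("T4", "T2")] == "THEME"      # expression -> RANTES
        assert labels[("T3", "T4")] == "THEME"      # activates -> expression
        assert labels[("T3", "T1")] == "CAUSE"      # activates -> RFLAT-1
        assert labels[("T4", "T1")] == NEGATIVE_LABEL

    def test_non_regulation_trigger_never_sources_trigger_edges(self, rflat_document):
        doc = rflat_document
        instances = generate_edge_instances(doc, doc.triggers, with_gold=True)
        for inst in instances:
            if inst.target_is_trigger:
                assert inst.source == "T3"  # only the regulation trigger

    def test_trigger_with_no_candidates_yields_nothing(self):
        doc = Document(doc_id="d", text="xxx yyy")
        from conftest import make_sentence
        doc.sentences = [make_sentence([("xxx", "xxx", "NN"), ("yyy", "yyy", "NN")])]
        doc.sentences[0].sent_end = len(doc.text)
        doc.triggers = [Trigger("T1", "Gene_expression", 0, 3, "xxx")]
        assert generate_edge_instances(doc, doc.triggers) == []


def toy_instances(n_per_class=5):
    from bioee.detection import TriggerInstance
    out = []
    for i in range(n_per_class):
        out.append(TriggerInstance("d", 0, i, {"a": 1.0, f"x{i}": 1.0}, "pos"))
        out.append(TriggerInstance("d", 0, i, {"b": 1.0, f"y{i}": 1.0}, "neg"))
    return out


class TestTraining:
    def test_separable_toy_set_is_memorized(self):
        instances = toy_instances()
        model = train(instances, seed=13, probability=False)
        labels, _ = model.predict([i.features for i in instances])
        assert labels == [i.label for i in instances]

    def test_training_is_deterministic(self):
        probe = [{"a": 1.0}, {"b": 1.0}, {"a": 1.0, "b": 1.0}]
        m1 = train(toy_instances(), seed=13, probability=False)
        m2 = train(toy_instances(), seed=13, probability=False)
        assert m1.predict(probe)[0] == m2.predict(probe)[0]

    def test_single_class_input_is_training_error(self):
        from bioee.detection import TriggerInstance
        instances = [TriggerInstance("d", 0, i, {"a": 1.0}, "pos") for i in range(4)]
        with pytest.raises(TrainingError):
            train(instances)

    def test_unknown_features_are_dropped_at_prediction(self):
        model = train(toy_instances(), seed=13, probability=False)
        labels, _ = model.predict([{"a": 1.0, "never_seen": 1.0}])
        assert labels == ["pos"]


class TestPredictTriggers:
    def _self_train_bundle(self, doc):
        instances = generate_trigger_instances(doc, with_gold=True)
        return ModelBundle(trigger_model=train(instances, seed=13, probability=False))

    def test_gold_feature_sanity_recovers_both_triggers(self, rflat_document):
        bundle = self._self_train_bundle(rflat_document)
        predicted = predict_triggers(rflat_document, bundle)
        assert {(t.text, t.event_type) for t in predicted} == {
            ("activates", "Positive_regulation"),
            ("expression", "Gene_expression"),
        }

    def test_adjacent_same_class_tokens_merge(self, rflat_document):
        doc = rflat_document
        # gold with two adjacent trigger tokens of one class: "gene expression"
        start = doc.text.index("gene")
        doc2 = Document(doc_id=doc.doc_id, text=doc.text, sentences=doc.sentences,
                        proteins=doc.proteins,
                        triggers=[Trigger("T3", "Gene_expression", start, start + 4, "gene"),
                                  Trigger("T4", "Gene_expression",
                                          doc.text.index("expression"),
                                          doc.text.index("expression") + 10, "expression")])
        bundle = self._self_train_bundle(doc2)
        predicted = predict_triggers(doc2, bundle)
        merged = [t for t in predicted if t.text == "gene expression"]
        assert len(merged) == 1


class TestAssembleEvents:
    def test_worked_example_from_gold_edges(self, rflat_document):
        doc = rflat_document
        events = assemble_events(doc.triggers, gold_edges(doc),
                                 {p.id for p in doc.proteins})
        assert len(events) == 2
        simple = next(e for e in events if e.event_type == "Gene_expression")
        reg = next(e for e in events if e.event_type == "Positive_regulation")
        assert simple.themes == ["T2"] and simple.cause is None
        assert reg.themes == [simple.id] and reg.cause == "T1"

    def test_cause_without_theme_yields_no_event(self):
        trig = Trigger("T1", "Positive_regulation", 0, 3, "act")
        edges = [Edge("T1", "P1", False, "CAUSE", 0.9)]
        assert assemble_events([trig], edges, {"P1"}) == []

    def test_mutual_regulation_cycle_is_broken(self):
        t1 = Trigger("T1", "Positive_regulation", 0, 3, "aaa")
        t2 = Trigger("T2", "Negative_regulation", 4, 7, "bbb")
        edges = [
            Edge("T1", "T2", True, "THEME", 0.9),
            Edge("T2", "T1", True, "THEME", 0.5),
            Edge("T1", "P1", False, "THEME", 0.8),
            Edge("T2", "P1", False, "THEME", 0.8),
        ]
        events = assemble_events([t1, t2], edges, {"P1"})
        event_reference_order(events)  # must not raise
        # the lower-scoring closing edge (T2 -> T1) was dropped, so no event
        # of T2 may reference an event of T1
        t1_event_ids = {e.id for e in events if e.trigger_id == "T1"}
        for ev in events:
            if ev.trigger_id == "T2":
                assert not set(ev.themes) & t1_event_ids

    def test_binding_collects_all_protein_themes_into_one_event(self):
        trig = Trigger("T1", "Binding", 0, 3, "bnd")
        edges = [Edge("T1", "P1", False, "THEME", 0.9),
                 Edge("T1", "P2", False, "THEME", 0.8)]
        events = assemble_events([trig], edges, {"P1", "P2"})
        assert len(events) == 1 and sorted(events[0].themes) == ["P1", "P2"]

    def test_simple_type_drops_cause_edges(self):
        trig = Trigger("T1", "Gene_expression", 0, 3, "exp")
        edges = [Edge("T1", "P1", False, "THEME", 0.9),
                 Edge("T1", "P2", False, "CAUSE", 0.9)]
        events = assemble_events([trig], edges, {"P1", "P2"})
        assert len(events) == 1 and events[0].cause is None

    def test_dangling_reference_is_assembly_error(self):
        trig = Trigger("T1", "Gene_expression", 0, 3, "exp")
        with pytest.raises(AssemblyError):
            assemble_events([trig], [Edge("T1", "GHOST", False, "THEME", 1.0)], set())

    def test_output_is_idempotent_under_reassembly(self, rflat_document):
        doc = rflat_document
        protein_ids = {p.id for p in doc.proteins}
        events = assemble_events(doc.triggers, gold_edges(doc), protein_ids)
        derived = Document(doc_id=doc.doc_id, text=doc.text, sentences=doc.sentences,
                           proteins=doc.proteins, triggers=doc.triggers, events=events)
        again = assemble_events(doc.triggers, gold_edges(derived), protein_ids)
        assert evaluate([derived], [Document(doc_id=doc.doc_id, text=doc.text,
                                             sentences=doc.sentences, proteins=doc.proteins,
                                             triggers=doc.triggers, events=again)]
                        ).micro == (1.0, 1.0, 1.0)


def random_edge_fuzz(seed, n_trials=200):
    """Random triggers + edges must always assemble into valid, acyclic events."""
    rng = random.Random(seed)
    protein_ids = {f"P{i}" for i in range(3)}
    for _ in range(n_trials):
        triggers = [Trigger(f"T{i}", rng.choice(EVENT_TYPES), i * 4, i * 4 + 3, "www")
                    for i in range(rng.randint(1, 5))]
        ids = [t.id for t in triggers]
        edges = []
        for _ in range(rng.randint(0, 8)):
            src = rng.choice(ids)
            if rng.random() < 0.4 and len(ids) > 1:
                tgt = rng.choice([i for i in ids if i != src])
                is_trig = True
            else:
                tgt = rng.choice(sorted(protein_ids))
                is_trig = False
            edges.append(Edge(src, tgt, is_trig,
                              rng.choice(["THEME", "CAUSE", "NEGATIVE"]),
                              rng.random()))
        events = assemble_events(triggers, edges, protein_ids)
        event_ids = {e.id for e in events}
        for ev in events:
            validate_event(ev, protein_ids, event_ids)
        event_reference_order(events)  # acyclic


def test_assembly_fuzz_respects_arities_and_acyclicity():
    random_edge_fuzz(seed=99, n_trials=200)
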