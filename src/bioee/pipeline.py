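"""End-to-end orchestration: resources, training, prediction, ablation.

This module wires the pieces together the way the experiments are meant to
run: build dictionaries and co-occurrence statistics from a labeled training
section plus an unlabeled stream, select CDFs, score feature coupling,
train the trigger and edge detectors, and measure held-out performance for
the three feature configurations (basic features alone, plus trigger-protein
scores, plus coupling-generalization features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .detection import (
    FEATURE_SETS,
    ModelBundle,
    Resources,
    extract_events,
    generate_edge_instances,
    generate_trigger_instances,
    predict_triggers,
    train,
)
from .efcg import (
    build_cgf_index,
    build_fcd_table,
    collect_cooccurrence,
    pair_stats,
    select_cdfs,
)
from .evaluation import STRICT, EvalReport, evaluate
from .features import EDF_FAMILIES, FeatureDictionaries, pair_context_features, parse_feature_name
from .fixtures import FixtureConfig, generate_labeled, generate_unlabeled
from .model import Document


def build_dictionaries(train_docs: Sequence[Document],
                       unlabeled: Sequence[Sequence[str]]) -> FeatureDictionaries:
    """Word and 2-3-gram vocabularies: l* from the labeled training section,
    u* from the unlabeled stream."""
    dicts = FeatureDictionaries()
    for doc in train_docs:
        for sent in doc.sentences:
            dicts.add_labeled([t.surface for t in sent.tokens])
    for sentence in unlabeled:
        dicts.add_unlabeled(list(sentence))
    return dicts


def build_tpf_stats(train_docs: Sequence[Document], all_docs: Sequence[Document],
                    unlabeled: Sequence[Sequence[str]]):
    """(labeled, unlabeled) co-occurrence statistics for trigger-protein
    scoring.

    The stem vocabulary covers candidate tokens of every document (labels
    are never consulted); protein surfaces come from the given .a1
    annotations.  Labeled counts use only the training sentences.
    """
    stems: set[str] = set()
    prots: set[str] = set()
    for doc in all_docs:
        for sent in doc.sentences:
            stems.update(t.stem.lower() for t in sent.tokens)
        prots.update(p.text.lower() for p in doc.proteins)
    stems -= prots
    if not stems or not prots:
        raise ValueError("no candidate stems or proteins found")
    train_sentences = [[t.stem for t in sent.tokens]
                       for doc in train_docs for sent in doc.sentences]
    labeled = pair_stats(train_sentences, stems, prots)
    unlabeled_stats = pair_stats(unlabeled, stems, prots) if unlabeled else None
    return labeled, unlabeled_stats


def collect_edf_vocabulary(docs: Sequence[Document],
                           dicts: FeatureDictionaries) -> set[str]:
    """Every lexical-context feature observable on candidate/nearest-protein
    and trigger-argument pairs across the given documents."""
    vocab: set[str] = set()
    for doc in docs:
        for si, sent in enumerate(doc.sentences):
            anchors = sorted({doc.anchor_token(p.char_start, p.char_end)[1]
                              for p in doc.proteins
                              if doc.anchor_token(p.char_start, p.char_end)[0] == si})
            if not anchors:
                continue
            for ti in range(len(sent.tokens)):
                nearest = min(anchors, key=lambda a: (abs(a - ti), a))
                if nearest == ti:
                    continue
                t1, t2 = sorted((ti, nearest))
                vocab.update(pair_context_features(sent, t1, t2, dicts))
    return {v for v in vocab if parse_feature_name(v)[0] in EDF_FAMILIES}


@dataclass
class PipelineResult:
    feature_set: str
    trigger_report: EvalReport
    event_report: EvalReport | None = None

    @property
    def trigger_f1(self) -> float:
        return self.trigger_report.trigger_micro[2]


@dataclass
class Experiment:
    """One seeded experiment: fixture corpora, resources, trained models."""
    config: FixtureConfig
    train_docs: list[Document] = field(default_factory=list)
    eval_docs: list[Document] = field(default_factory=list)
    unlabeled: list[list[str]] = field(default_factory=list)
    resources: Resources = field(default_factory=Resources)

    @classmethod
    def from_config(cls, config: FixtureConfig, n_cdfs: int = 400) -> "Experiment":
        docs, ledger = generate_labeled(config)
        unlabeled = generate_unlabeled(config, ledger)
        train_ids = set(ledger.train_doc_ids)
        exp = cls(config=config,
                  train_docs=[d for d in docs if d.doc_id in train_ids],
                  eval_docs=[d for d in docs if d.doc_id not in train_ids],
                  unlabeled=unlabeled)
        exp.ledger = ledger
        exp.build_resources(n_cdfs=n_cdfs)
        return exp

    def build_resources(self, n_cdfs: int = 400) -> Resources:
        dicts = build_dictionaries(self.train_docs, self.unlabeled)
        tpf_labeled, tpf_unlabeled = build_tpf_stats(
            self.train_docs, self.train_docs + self.eval_docs, self.unlabeled)
        res = Resources(dicts=dicts, tpf_labeled=tpf_labeled,
                        tpf_unlabeled=tpf_unlabeled)
        # CDFs from the labeled basic-feature vocabulary, EDFs from the
        # lexical-context families; coupling scored on the unlabeled stream
        instances = []
        for doc in self.train_docs:
            instances.extend(generate_trigger_instances(doc, with_gold=True))
        cdfs = select_cdfs([i.features for i in instances],
                           [i.label for i in instances], k=n_cdfs)
        edf_vocab = collect_edf_vocabulary(self.train_docs + self.eval_docs, dicts)
        if self.unlabeled and edf_vocab and cdfs:
            stats = collect_cooccurrence(self.unlabeled, edf_vocab, cdfs)
            res.cgf_table = build_fcd_table(stats, b=1.0)
            res.cgf_index = build_cgf_index(edf_vocab, cdfs)
        self.resources = res
        return res

    def train_bundle(self, feature_set: str = "bf+tpf+cgf", seed: int = 13,
                     probability: bool = True, with_edges: bool = True) -> ModelBundle:
        trig_instances = []
        edge_instances = []
        for doc in self.train_docs:
            trig_instances.extend(generate_trigger_instances(
                doc, with_gold=True, resources=self.resources, feature_set=feature_set))
            if with_edges:
                edge_instances.extend(generate_edge_instances(
                    doc, doc.triggers, with_gold=True,
                    resources=self.resources, feature_set=feature_set))
        bundle = ModelBundle(resources=self.resources,
                             config={"feature_set": feature_set, "seed": seed})
        bundle.trigger_model = train(trig_instances, seed=seed, probability=probability)
        if with_edges:
            bundle.edge_model = train(edge_instances, seed=seed, probability=probability)
        return bundle

    def evaluate_triggers(self, bundle: ModelBundle, feature_set: str) -> EvalReport:
        preds = []
        for doc in self.eval_docs:
            triggers = predict_triggers(doc, bundle, feature_set)
            preds.append(Document(doc_id=doc.doc_id, text=doc.text,
                                  sentences=doc.sentences,
                                  proteins=list(doc.proteins), triggers=triggers))
        gold = [Document(doc_id=d.doc_id, text=d.text, sentences=d.sentences,
                         proteins=list(d.proteins), triggers=list(d.triggers))
                for d in self.eval_docs]
        return evaluate(gold, preds, mode=STRICT)

    def evaluate_events(self, bundle: ModelBundle, feature_set: str) -> EvalReport:
        preds = [extract_events(doc, bundle, feature_set) for doc in self.eval_docs]
        return evaluate(self.eval_docs, preds, mode=STRICT)


def run_ablation(seed: int, config: FixtureConfig | None = None,
                 feature_sets: Sequence[str] = FEATURE_SETS,
                 probability: bool = False) -> dict[str, PipelineResult]:
    """Train and score the trigger detector under each feature configuration
    on one seeded fixture; returns per-configuration held-out reports.

    Probability estimation is off by default here (decision values suffice
    for argmax trigger labeling and it avoids the solver's internal
    cross-validation); the edge detector, which needs scores for cause
    selection, is trained separately with probabilities on.
    """
    cfg = config or FixtureConfig(seed=seed)
    exp = Experiment.from_config(cfg)
    out: dict[str, PipelineResult] = {}
    for fs in feature_sets:
        bundle = exp.train_bundle(feature_set=fs, seed=seed,
                                  probability=probability, with_edges=False)
        out[fs] = PipelineResult(feature_set=fs,
                                 trigger_report=exp.evaluate_triggers(bundle, fs))
    return out


def ablation_means(seeds: Sequence[int],
                   feature_sets: Sequence[str] = FEATURE_SETS) -> dict[str, float]:
    """Mean held-out trigger micro-F per feature configuration over seeds."""
    sums = {fs: 0.0 for fs in feature_sets}
    for seed in seeds:
        results = run_ablation(seed, config=FixtureConfig(seed=seed),
                               feature_sets=feature_sets)
        for fs in feature_sets:
            sums[fs] += results[fs].trigger_f1
    return {fs: sums[fs] / len(seeds) for fs in feature_sets}
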