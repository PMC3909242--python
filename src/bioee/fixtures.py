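"""Seeded synthetic corpora with planted, recoverable statistical structure.

The generator emulates the shape of a shared-task event corpus plus a large
unlabeled text stream, at desk scale:

* **Labeled documents** contain template sentences of the form
  ``<protein> ... <trigger word> ... <protein>`` with gold triggers, edges
  and events of all nine types, including nested regulation chains, plus
  synthesized parses (flat head-chain dependencies and one predicate per
  trigger).  Each event type owns a small trigger lexicon and a cue-word
  lexicon; only the first half of each lexicon appears in training
  documents, the second half only in held-out documents.  This plants the
  out-of-vocabulary sparsity that semi-supervised generalization is meant
  to overcome: a held-out trigger or cue word is frequently one the
  supervised learner has never seen.

* **Unlabeled sentences** are background noise in which trigger words,
  cue words and proteins of the same event type are co-inserted at
  ``cooc_boost`` times their independent background rate.  The whole
  lexicons — including the held-out halves — participate, so trigger-protein
  scores and coupling-generalization features computed from this stream
  carry signal that transfers to unseen words.

Every planted fact is tallied in a ground-truth ledger while sentences are
emitted, so tests can verify corpus statistics against the ledger instead
of against the code under test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    BINDING_TYPE,
    Document,
    EventRecord,
    EVENT_TYPES,
    PASPredicate,
    DependencyArc,
    ProteinMention,
    REGULATION_TYPES,
    SIMPLE_TYPES,
    Sentence,
    Token,
    Trigger,
    is_regulation,
    validate_document,
)

_TYPE_SLUGS = {
    "Gene_expression": "genex",
    "Transcription": "transc",
    "Protein_catabolism": "catab",
    "Phosphorylation": "phos",
    "Localization": "local",
    "Binding": "bind",
    "Regulation": "reg",
    "Positive_regulation": "posreg",
    "Negative_regulation": "negreg",
}


def default_trigger_lexicon(words_per_type: int = 4) -> dict[str, list[str]]:
    return {t: [f"trg{_TYPE_SLUGS[t]}{i}" for i in range(words_per_type)]
            for t in EVENT_TYPES}


def default_cue_lexicon(words_per_type: int = 4) -> dict[str, list[str]]:
    return {t: [f"cue{_TYPE_SLUGS[t]}{i}" for i in range(words_per_type)]
            for t in EVENT_TYPES}


def default_protein_lexicon(n: int = 6) -> list[str]:
    return [f"PROT{chr(65 + i)}" for i in range(n)]


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic corpora.

    ``cue_strength`` is the probability that an event sentence carries its
    type's cue word; ``cooc_boost`` multiplies the planted trigger-protein
    and cue-class co-insertion rate in the unlabeled stream relative to the
    independent background rate (boost 1 plants at background level).
    """
    seed: int = 13
    n_docs: int = 20
    sentences_per_doc: int = 10
    vocab_size: int = 3000
    trigger_lexicon: dict[str, list[str]] = field(default_factory=default_trigger_lexicon)
    cue_lexicon: dict[str, list[str]] = field(default_factory=default_cue_lexicon)
    protein_lexicon: list[str] = field(default_factory=default_protein_lexicon)
    cue_strength: float = 0.9
    unlabeled_sentences: int = 5000
    cooc_boost: float = 10.0
    holdout_fraction: float = 0.3
    train_lexicon_fraction: float = 0.5
    event_sentence_fraction: float = 0.7
    # unlabeled-stream rates
    plant_base_rate: float = 0.03          # per-sentence bundle rate at boost 1
    background_protein_rate: float = 0.01  # independent protein mention rate
    background_lexicon_rate: float = 0.002 # independent trigger/cue word rate

    def __post_init__(self) -> None:
        pools = [set(self.protein_lexicon)]
        for lex in (self.trigger_lexicon, self.cue_lexicon):
            pools.append({w for ws in lex.values() for w in ws})
        pools.append({f"w{i:04d}" for i in range(self.vocab_size)})
        seen: set[str] = set()
        for pool in pools:
            if pool & seen:
                raise ValueError(f"lexicons overlap: {sorted(pool & seen)[:5]}")
            seen |= pool
        for p in (self.cue_strength, self.holdout_fraction,
                  self.train_lexicon_fraction, self.event_sentence_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def background_vocab(self) -> list[str]:
        return [f"w{i:04d}" for i in range(self.vocab_size)]

    def train_words(self, lexicon: dict[str, list[str]], etype: str) -> list[str]:
        words = lexicon[etype]
        cut = max(1, round(len(words) * self.train_lexicon_fraction))
        return words[:cut]


@dataclass
class SentenceRecord:
    doc_id: str
    sentence_index: int
    kind: str                    # event / nested / negative
    event_type: str | None = None
    trigger_word: str | None = None
    cue_word: str | None = None
    theme_proteins: tuple[str, ...] = ()
    cause_protein: str | None = None
    sub_event_type: str | None = None
    sub_trigger_word: str | None = None
    sub_cue_word: str | None = None


@dataclass
class Ledger:
    """Ground truth for everything the generator planted."""
    train_doc_ids: list[str] = field(default_factory=list)
    eval_doc_ids: list[str] = field(default_factory=list)
    sentences: list[SentenceRecord] = field(default_factory=list)
    event_counts: dict[str, int] = field(default_factory=dict)
    # unlabeled-stream tallies (sentence-level membership counts)
    unlabeled_sentence_count: int = 0
    planted_bundle_count: int = 0
    word_sentence_counts: dict[str, int] = field(default_factory=dict)
    trigger_protein_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    cue_trigger_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def labeled_sentence_count(self) -> int:
        return len(self.sentences)


# ---------------------------------------------------------------------------
# labeled corpus
# ---------------------------------------------------------------------------

def _filler(rng: random.Random, cfg: FixtureConfig) -> str:
    return f"w{rng.randrange(cfg.vocab_size):04d}"


def _plan_sentence(rng: random.Random, cfg: FixtureConfig, etype: str,
                   is_train: bool, rec: SentenceRecord):
    """Return (words, trigger plan, event plan) for one event sentence.

    Trigger plans are (token index, type, word); event plans are dicts
    consumed by the document builder.
    """
    trig_pool = cfg.train_words(cfg.trigger_lexicon, etype) if is_train \
        else cfg.trigger_lexicon[etype]
    cue_pool = cfg.train_words(cfg.cue_lexicon, etype) if is_train \
        else cfg.cue_lexicon[etype]
    trig = rng.choice(trig_pool)
    cue = rng.choice(cue_pool) if rng.random() < cfg.cue_strength else None
    prots = cfg.protein_lexicon
    theme = rng.choice(prots)
    distractor = rng.choice([p for p in prots if p != theme])
    f = lambda: _filler(rng, cfg)

    rec.event_type, rec.trigger_word, rec.cue_word = etype, trig, cue
    if etype == BINDING_TYPE:
        theme2 = rng.choice([p for p in prots if p != theme])
        words = [f(), cue or f(), f(), trig, theme, f(), theme2, f(), distractor]
        rec.theme_proteins = (theme, theme2)
        triggers = [(3, etype, trig)]
        events = [{"type": etype, "trigger": 3, "themes": [4, 6], "cause": None}]
    elif etype in REGULATION_TYPES:
        cause = rng.choice([p for p in prots if p != theme])
        words = [f(), cause, cue or f(), trig, theme, f(), distractor]
        rec.theme_proteins, rec.cause_protein = (theme,), cause
        triggers = [(3, etype, trig)]
        events = [{"type": etype, "trigger": 3, "themes": [4], "cause": 1}]
    else:
        words = [f(), cue or f(), f(), trig, theme, f(), distractor, f()]
        rec.theme_proteins = (theme,)
        triggers = [(3, etype, trig)]
        events = [{"type": etype, "trigger": 3, "themes": [4], "cause": None}]
    return words, triggers, events


def _plan_nested(rng: random.Random, cfg: FixtureConfig, etype: str,
                 is_train: bool, rec: SentenceRecord):
    """Regulation event whose theme is a simple sub-event in the same sentence."""
    sub_type = rng.choice(SIMPLE_TYPES)
    pick = lambda lex, t: rng.choice(cfg.train_words(lex, t) if is_train else lex[t])
    reg_trig, sub_trig = pick(cfg.trigger_lexicon, etype), pick(cfg.trigger_lexicon, sub_type)
    reg_cue = pick(cfg.cue_lexicon, etype) if rng.random() < cfg.cue_strength else None
    sub_cue = pick(cfg.cue_lexicon, sub_type) if rng.random() < cfg.cue_strength else None
    prots = cfg.protein_lexicon
    cause, theme = rng.choice(prots), rng.choice(prots)
    f = lambda: _filler(rng, cfg)
    words = [cause, reg_trig, reg_cue or f(), f(), sub_cue or f(), sub_trig, theme, f()]
    rec.kind = "nested"
    rec.event_type, rec.trigger_word, rec.cue_word = etype, reg_trig, reg_cue
    rec.theme_proteins, rec.cause_protein = (theme,), cause
    rec.sub_event_type, rec.sub_trigger_word, rec.sub_cue_word = sub_type, sub_trig, sub_cue
    triggers = [(1, etype, reg_trig), (5, sub_type, sub_trig)]
    events = [
        {"type": sub_type, "trigger": 5, "themes": [6], "cause": None},
        {"type": etype, "trigger": 1, "themes": [("event", 0)], "cause": 0},
    ]
    return words, triggers, events


def _build_document(doc_id: str, planned: list[tuple[list[str], list, list]],
                    cfg: FixtureConfig) -> Document:
    """Assemble token offsets, annotations, head-chain parses and PAS rows."""
    protein_set = set(cfg.protein_lexicon)
    text_parts: list[str] = []
    sentences: list[Sentence] = []
    proteins: list[ProteinMention] = []
    triggers: list[Trigger] = []
    events: list[EventRecord] = []
    offset = 0
    t_counter = 1
    e_counter = 1

    for words, trig_plan, event_plan in planned:
        tokens: list[Token] = []
        pos = offset
        for i, word in enumerate(words):
            tokens.append(Token(index=i, surface=word, stem=word.lower(),
                                pos="NNP" if word in protein_set else "NN",
                                char_start=pos, char_end=pos + len(word)))
            pos += len(word) + 1
        arcs = [DependencyArc(head_index=i - 1, dependent_index=i, label="NMOD")
                for i in range(1, len(words))]
        prot_idx = [i for i, w in enumerate(words) if w in protein_set]
        predicates = []
        for ti, _, _ in trig_plan:
            args = [(f"ARG{n + 1}", i) for n, i in enumerate(prot_idx)]
            predicates.append(PASPredicate(predicate_index=ti, arguments=tuple(args)))
        sent = Sentence(tokens=tokens, arcs=arcs, predicates=predicates)
        text_parts.append(" ".join(words))

        tok_protein_ids: dict[int, str] = {}
        for i in prot_idx:
            pid = f"T{t_counter}"
            t_counter += 1
            tok = tokens[i]
            proteins.append(ProteinMention(id=pid, char_start=tok.char_start,
                                           char_end=tok.char_end, text=tok.surface))
            tok_protein_ids[i] = pid
        tok_trigger_ids: dict[int, str] = {}
        for ti, etype, word in trig_plan:
            tid = f"T{t_counter}"
            t_counter += 1
            tok = tokens[ti]
            triggers.append(Trigger(id=tid, event_type=etype, char_start=tok.char_start,
                                    char_end=tok.char_end, text=tok.surface))
            tok_trigger_ids[ti] = tid
        sent_event_ids: list[str] = []
        for plan in event_plan:
            eid = f"E{e_counter}"
            e_counter += 1
            themes = []
            for ref in plan["themes"]:
                if isinstance(ref, tuple):  # ("event", local index)
                    themes.append(sent_event_ids[ref[1]])
                else:
                    themes.append(tok_protein_ids[ref])
            cause = tok_protein_ids[plan["cause"]] if plan["cause"] is not None else None
            events.append(EventRecord(id=eid, event_type=plan["type"],
                                      trigger_id=tok_trigger_ids[plan["trigger"]],
                                      themes=themes, cause=cause))
            sent_event_ids.append(eid)
        sentences.append(sent)
        offset = pos  # includes the separator position (newline)

    text = "\n".join(text_parts)
    start = 0
    for i, sent in enumerate(sentences):
        end = len(text) if i == len(sentences) - 1 else sentences[i + 1].tokens[0].char_start
        sent.sent_start, sent.sent_end = start, end
        start = end
    doc = Document(doc_id=doc_id, text=text, sentences=sentences,
                   proteins=proteins, triggers=triggers, events=events)
    validate_document(doc)
    return doc


def generate_labeled(config: FixtureConfig) -> tuple[list[Document], Ledger]:
    """Deterministic labeled corpus: documents with gold annotations and
    synthesized parses, plus the ground-truth ledger.

    Documents are split into a training and a held-out section; held-out
    documents draw trigger and cue words from the full lexicons, so roughly
    half their lexical anchors are unseen in training.
    """
    rng = random.Random(config.seed)
    ledger = Ledger()
    n_eval = round(config.n_docs * config.holdout_fraction)
    type_cycle = 0
    docs: list[Document] = []
    for d in range(config.n_docs):
        doc_id = f"D{d:03d}"
        is_train = d < config.n_docs - n_eval
        (ledger.train_doc_ids if is_train else ledger.eval_doc_ids).append(doc_id)
        n_event = round(config.sentences_per_doc * config.event_sentence_fraction)
        kinds = ["event"] * n_event + ["negative"] * (config.sentences_per_doc - n_event)
        rng.shuffle(kinds)
        planned = []
        for s, kind in enumerate(kinds):
            rec = SentenceRecord(doc_id=doc_id, sentence_index=s, kind=kind)
            if kind == "event":
                etype = EVENT_TYPES[type_cycle % len(EVENT_TYPES)]
                type_cycle += 1
                if is_regulation(etype) and rng.random() < 0.5:
                    plan = _plan_nested(rng, config, etype, is_train, rec)
                else:
                    plan = _plan_sentence(rng, config, etype, is_train, rec)
                for ev in plan[2]:
                    ledger.event_counts[ev["type"]] = ledger.event_counts.get(ev["type"], 0) + 1
            else:
                words = [_filler(rng, config) for _ in range(rng.randint(6, 9))]
                if rng.random() < 0.6:
                    words[rng.randrange(len(words))] = rng.choice(config.protein_lexicon)
                plan = (words, [], [])
            ledger.sentences.append(rec)
            planned.append(plan)
        docs.append(_build_document(doc_id, planned, config))
    return docs, ledger


# ---------------------------------------------------------------------------
# unlabeled stream
# ---------------------------------------------------------------------------

def generate_unlabeled(config: FixtureConfig, ledger: Ledger) -> list[list[str]]:
    """Unlabeled sentence stream with boosted same-type co-insertions.

    Each sentence is background vocabulary; proteins, trigger words and cue
    words additionally appear independently at small background rates.  With
    probability ``plant_base_rate * cooc_boost`` a sentence receives a
    correlated bundle — one event type's trigger word and cue word plus a
    protein — planting the trigger-protein and cue-class co-occurrence that
    the coupling scores are meant to recover.  At boost 1 the bundle rate
    is statistically indistinguishable from the background at this corpus
    size.  True sentence-membership counts are tallied into the ledger.
    """
    rng = random.Random(config.seed + 9973)
    all_lexicon = [(t, w) for t in EVENT_TYPES
                   for w in config.trigger_lexicon[t] + config.cue_lexicon[t]]
    bundle_rate = min(0.95, config.plant_base_rate * config.cooc_boost)
    sentences: list[list[str]] = []
    for _ in range(config.unlabeled_sentences):
        words = [_filler(rng, config) for _ in range(rng.randint(8, 12))]
        extras: list[str] = []
        for prot in config.protein_lexicon:
            if rng.random() < config.background_protein_rate:
                extras.append(prot)
        for _, w in all_lexicon:
            if rng.random() < config.background_lexicon_rate:
                extras.append(w)
        if rng.random() < bundle_rate:
            etype = rng.choice(EVENT_TYPES)
            extras.extend([rng.choice(config.trigger_lexicon[etype]),
                           rng.choice(config.cue_lexicon[etype]),
                           rng.choice(config.protein_lexicon)])
            ledger.planted_bundle_count += 1
        for word in extras:
            words.insert(rng.randrange(len(words) + 1), word)
        sentences.append(words)

        present = set(words)
        ledger.unlabeled_sentence_count += 1
        for w in present:
            ledger.word_sentence_counts[w] = ledger.word_sentence_counts.get(w, 0) + 1
        for etype in EVENT_TYPES:
            trig_here = [w for w in config.trigger_lexicon[etype] if w in present]
            cue_here = [c for c in config.cue_lexicon[etype] if c in present]
            for w in trig_here:
                for prot in config.protein_lexicon:
                    if prot in present:
                        key = (w, prot)
                        ledger.trigger_protein_counts[key] = \
                            ledger.trigger_protein_counts.get(key, 0) + 1
                for c in cue_here:
                    key = (c, w)
                    ledger.cue_trigger_counts[key] = \
                        ledger.cue_trigger_counts.get(key, 0) + 1
    return sentences


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def write_parse(document: Document) -> str:
    """Serialize a document's sentences in the parse TSV dialect."""
    blocks = []
    for sent in document.sentences:
        head_of = {a.dependent_index: (a.head_index, a.label) for a in sent.arcs}
        lines = []
        for tok in sent.tokens:
            head, label = head_of.get(tok.index, (-1, "ROOT"))
            lines.append(f"{tok.index}\t{tok.surface}\t{tok.stem}\t{tok.pos}\t{head}\t{label}")
        for pred in sent.predicates:
            args = " ".join(f"{role}:{idx}" for role, idx in pred.arguments)
            lines.append(f"PAS\t{pred.predicate_index}\t{args}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def corpus_files(document: Document) -> dict[str, str]:
    """txt/a1/a2/parse file contents for one document."""
    from .corpus_io import write_a1, write_a2
    return {
        f"{document.doc_id}.txt": document.text,
        f"{document.doc_id}.a1": write_a1(document),
        f"{document.doc_id}.a2": write_a2(document),
        f"{document.doc_id}.parse": write_parse(document),
    }
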