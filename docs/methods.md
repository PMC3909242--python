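# Methods

This note documents the models and procedures implemented in `bioee`, the
choices made where the design was genuinely open, and what the synthetic
corpora do and do not establish.

## Data model and formats

Documents are offset-anchored: raw text plus protein mentions (`.a1`),
trigger spans and events (`.a2`) in brat/shared-task standoff, all spans
0-based half-open.  Dependency parses and predicate-argument structures
(PAS) arrive as external parser output in a CoNLL-style TSV dialect (one
token per line: index, surface, stem, POS, head index with −1 for the
root, relation label; `PAS` rows per sentence).  Token offsets are
recovered by left-to-right surface alignment against the text; any
misalignment, self-loop, or span/text disagreement is a hard error rather
than a warning, because every downstream statistic keys on these offsets.
Stems are taken from the parse file; where text has no parse (the
unlabeled stream) the stem is the lowercased token.

A multi-token trigger is anchored, for token labeling, at the token
containing its last character (head-token convention).  Event arity is
enforced on read, write and assembly: the five simple types take exactly
one protein theme and no cause; Binding takes one or more protein themes;
the three regulation types take one theme (protein or event) and at most
one cause, and the event-reference graph must be acyclic.

## Feature space

Basic features (all binary, namespaced `family:payload`; lexical payloads
lowercased, POS payloads case-preserving):

* `tok` — surface, stem, POS, plus surfaces at offsets ±1..±3;
* `ngw` — all word n-grams (n = 1..4) in the window of 4 tokens on each
  side of the candidate, candidate included (≤ 30 features per token);
* `ngp` — for a token pair: word n-grams (n = 1..4) strictly between the
  targets plus stem+POS composite 2–3-grams on the inclusive path;
* `wv`/`posv`/`ew` — dependency walks: for each arc incident to a token a
  head-(label)-modifier vertex walk in word and POS form; for each pair of
  incident arcs an edge walk label₁(node)label₂ with the node rendered
  both ways.  Incidence is undirected (a token's walks include arcs where
  it is head and where it is modifier); direction survives in the name;
* `pas` — key-word features for tokens linked to strictly more than 3
  distinct tokens across the sentence's predicate-argument records.

Lexical-context (EDF) families for a target pair t₁ < t₂: general regions
(left/inner/right), 4-token surrounding windows, specific locations within
±5 of either target, and conjunct locations keyed by the bucketed
inter-target distance (buckets 0–4, (5~6), (7~9), (10~14), (15~19),
(20~29), (30~39), (40~); the bucket function is total on non-negative
integers).  Offset features are named `<d>_From_Tar=<gram>` with `d` the
unsigned distance from the target to the gram's first token — the naming
that reproduces the documented exemplars (`2_From_Tar=due to`,
`Token_In_Left_Location=gene`).  Payloads are filtered through
dictionaries: words/2–3-grams of the labeled training text (LWD/LND)
united with those of the unlabeled stream (UWD/UND).  The union matters:
an EDF must be countable in the unlabeled corpus anyway, and it is exactly
the contexts *unseen* in labeled data that generalization should reach.

## Coupling generalization

CDF selection scores every labeled feature with
`(t·k − m·n)² / ((t+m)(k+n))` from the 2×2 contingency counts (t/m =
positives/negatives containing the feature, n/k = lacking it), computed
one-vs-rest per class with the maximum over classes; ties break
lexicographically.  The formula is used exactly as defined — it is not the
textbook chi-square (two marginal factors are absent), and a feature
present in every instance has an undefined score and is skipped.  The
default of K = 400 CDFs reflects the operating point where more CDFs stop
helping.

The feature coupling degree on unlabeled data is

    FCD(U, e, c) = log10(co(e,c) + b) / ( log10(count(e) + b) · log10(count(c) + b) ),  b = 1,

with sentence-level counts: `count(·)` is the number of unlabeled
sentences containing the item's lexical payload as a contiguous token
sequence, `co` the number containing both.  The score is undefined when a
marginal log factor is non-positive (count + b ≤ 1); table construction
propagates this, while TPF scoring maps undefined to 0 (an unseen pair is
simply absent evidence).  One counting pass over the stream serves all
pairs; only co-occurring pairs are stored.

Generated features: `root(e)` maps an EDF to its family × region concept
(the name before the lexical payload), the coarsest grouping that keeps
location structure.  The CGF component for (r, c, t) is the sum of
FCD_t(U, e, c) over the instance's EDFs with root r — linear in the EDF
indicator vector by construction.  The type axis T is the singleton
`pmi_mod`; the axis exists in the data model for extensibility only.

A property of this score worth knowing: because the denominator uses raw
log-counts, *rare* items get a small denominator, so a hapax context word
that co-occurs once with a target can outscore a genuinely coupled pair.
At realistic vocabulary sizes this is a small tail; with a very small
vocabulary (every background word frequent) it dominates, which is why the
synthetic corpora use a few thousand background types.

## Trigger–protein features (TPF)

For each candidate token, its stem is paired with every in-sentence
protein surface and scored with the same FCD measure under two separate
count tables — labeled training sentences and the unlabeled stream.  The
maxima over proteins enter the feature space as real values (the "soft"
strategy; thresholding pairs away is deliberately not implemented).  Two
implementation details make the scores usable by a margin classifier:
the design matrix is max-abs scaled (binary columns unaffected), and each
score is accompanied by cumulative `score ≥ edge` indicators at edges
0.05–0.25 (thermometer encoding), so the SVM can place independent weight
on each threshold instead of relying on one coefficient for a feature of
magnitude ~0.2.

## Classifiers

Both detectors are one-vs-rest linear-kernel SVMs (libsvm-backed) with
shrinking on and all other solver settings at their defaults; the
one-vs-rest wrapper provides the "class K vs rest" contract (the solver's
native multiclass mode is one-vs-one).  Probability estimates are enabled
for the edge model, whose scores drive cause selection and cycle breaking;
the trigger model in the ablation experiment uses decision-value argmax,
which is equivalent for labeling and avoids the internal cross-validation
of probability calibration.  Features unseen at training time are dropped
at prediction.  Training is deterministic given instance order and seed.
Negative instances are not subsampled.

Trigger instances are generated for every non-protein token (proteins are
given a priori and are not trigger candidates).  One label per token: a
token cannot trigger two event types at once — a known expressiveness
limit of the argmax design, since corpora contain triggers shared across
types.  Edge candidates go from every trigger to every same-sentence
protein and, for regulation-type triggers only, to every other
same-sentence trigger; candidates never cross sentences.  CGF features
attach to edge instances via the pair's own EDFs and to trigger instances
via the pair (candidate, nearest in-sentence protein).

## Event assembly

Adjacent tokens predicted with the same non-negative class merge into one
trigger span.  Assembly then proceeds: simple types emit one event per
protein THEME edge (CAUSE edges are dropped); Binding collects all protein
themes of a trigger into a single event (a configurable alternative would
split per theme); regulation emits one event per THEME edge with the
trigger's highest-scoring CAUSE edge attached, resolving trigger-valued
themes recursively into one event per resolved sub-event (a trigger-valued
cause resolves to that trigger's first event).  Cycles among
trigger→trigger edges are broken by keeping edges greedily in descending
score order, so the lowest-scoring edge that would close a cycle is
dropped; assembly output is checked against the arity and acyclicity
invariants, and re-assembling an assembled document's own edges reproduces
the same events.

## Evaluation

Events match when types agree, trigger spans agree, and theme/cause
references match recursively — proteins by identity (both sides share the
`.a1` id space), events by a matching sub-event.  Matching is greedy
one-to-one per document.  `strict` requires exact character spans;
`approximate` allows a one-token extension on either boundary, a stand-in
for the shared tasks' "approximate span" criterion whose official
definition varies.  Reports carry per-type and micro precision/recall/F1
with 0/0 = 0, plus a trigger-level report (span + type only).

## Synthetic corpora

The generator emulates the *shape* of the real task at desk scale, with a
ground-truth ledger recording everything planted:

* **Labeled documents** (default 20 × 10 sentences, 70/30 train/held-out
  by document): template sentences with one protein-flanked trigger per
  event sentence, all nine types cycled, nested regulation chains, flat
  head-chain parses, one PAS record per trigger, ~30% negative sentences.
  Each type owns 4 trigger words and 4 cue words; training documents draw
  from the first half of each lexicon, held-out documents from the whole —
  planting the out-of-vocabulary sparsity that motivates semi-supervision.
  A cue word appears in its event sentence with probability 0.9
  (`cue_strength`) at a position that does not identify the trigger.
* **Unlabeled stream** (default 5,000 sentences): background words from a
  3,000-type vocabulary; proteins, trigger and cue words appear
  independently at small background rates (0.01 and 0.002 per sentence),
  and with probability `plant_base_rate · cooc_boost` (0.03 · 10 by
  default) a sentence receives a correlated same-type bundle (trigger word
  + cue word + protein).  At boost 1 the bundle rate is statistically
  indistinguishable from background at this corpus size; at boost 10 the
  planted trigger–protein and cue–type couplings are recoverable by the
  FCD score.

What the fixtures do **not** model: linguistic realism (no grammar, no
real parses, no multi-token triggers or discontinuous mentions), protein
name variation (TPF matches unlabeled protein mentions by exact surface
dictionary lookup, as no NER procedure is defined for unlabeled text),
annotation noise, or corpus-level topic drift.  Passing tests therefore
demonstrate that the statistical machinery recovers planted structure
under controlled conditions — not performance on real corpora, whose
headline scores require the full shared-task data and a PubMed-scale
unlabeled stream.

## Experiment sizes and defaults

The ablation experiment trains the trigger detector under three feature
configurations (`bf`, `bf+tpf`, `bf+tpf+cgf`) on the training section and
scores strict trigger micro-F on held-out documents; the acceptance script
averages 5 seeds (~200 labeled and 5,000 unlabeled sentences per seed, a
size chosen so a full run completes in minutes on one CPU).  The ablation
is measured at the trigger level, where both semi-supervised families
attach naturally; the end-to-end event-level score (edge model with
probabilities, full assembly) is computed separately on one seed.
Smoothing b = 1, K = 400 CDFs, SVM C = 1, global seed threaded through
generation, training and the experiment driver.

## Known limitations

* The one-label-per-token design cannot emit two event types from one
  trigger token.
* Secondary arguments (Site etc.), cross-sentence events and coreference
  are out of scope.
* Regulation-type coupling features are the least reliable — directed
  relations with asymmetric roles are poorly captured by symmetric
  sentence co-occurrence, so CGF gains concentrate in simple and Binding
  types.
* The FCD measure's rare-item affinity (above) makes it sensitive to the
  frequency profile of the unlabeled corpus.
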