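# bioee — semi-supervised biomedical event extraction

`bioee` extracts **biomolecular events** — typed, possibly nested
associations like *Positive_regulation(Theme = Gene_expression(Theme =
RANTES), Cause = RFLAT-1)* — from parsed biomedical text annotated in the
BioNLP/brat standoff format.  It is aimed at text-mining researchers who
want a complete, testable trigger → argument → event pipeline whose feature
space combines supervised "basic features" with features generalized from
a large **unlabeled** corpus, attacking the data-sparseness problem of
small labeled event corpora.

## The method

The pipeline has three classification stages over dependency-parsed
sentences (the package ingests parser *output*; it never runs a parser):

1. **Trigger detection** — token labeling with a one-vs-rest linear SVM:
   every non-protein token gets one of 9 event types or NEGATIVE.
2. **Argument (edge) detection** — each trigger→protein and (for regulation
   types) trigger→trigger candidate is classified THEME / CAUSE / NEGATIVE.
3. **Event assembly** — edges become nested event records respecting
   per-type arities (simple types: one protein theme; Binding: ≥1 protein
   themes; regulation: one theme, optional cause, recursive).

On top of the basic features (token/stem/POS, n-grams, dependency v-walks
and e-walks, predicate-argument key words), two semi-supervised feature
families are built from an unlabeled sentence stream `U`:

* **TPF (trigger–protein features)** — for a candidate token `e` and an
  in-sentence protein `c`, the coupling score

  ```
  score(e, c) = log10(co(e,c) + b) / ( log10(count(e) + b) · log10(count(c) + b) ),   b = 1
  ```

  a smoothed, log-scaled PMI variant computed separately on labeled and
  unlabeled counts, added to the feature space as real values ("soft"
  strategy — no threshold).

* **CGF (coupling-generalization features)** — *example-distinguishing
  features* (EDFs: location-tagged lexical context features) are mapped to
  root concepts `r = root(e)`; *class-distinguishing features* (CDFs `c`)
  are the top-K features by `(t·k − m·n)² / ((t+m)(k+n))` over the labeled
  contingency counts (default K = 400); the generated feature indexed by
  `(r, c, t)` has value `Σ_{root(e)=r} FCD_t(U, e, c)` — low-frequency
  context words inherit the statistics of everything sharing their root.

Because the real labeled/unlabeled corpora are license- and scale-bound,
the package ships a seeded synthetic-corpus generator that plants the same
statistical structure (out-of-vocabulary trigger words, class-correlated
cue words, boosted trigger–protein co-occurrence in the unlabeled stream)
with a ground-truth ledger, so every claim is testable at desk scale.

## Worked example

```python
from bioee import read_standoff, read_parses, assemble_events, gold_edges, evaluate

text = ("RFLAT-1: a new zinc finger transcription factor that activates "
        "RANTES gene expression in T lymphocytes")
a1 = "T1\tProtein 0 7\tRFLAT-1\nT2\tProtein 63 69\tRANTES\n"
a2 = ("T3\tPositive_regulation 53 62\tactivates\n"
      "T4\tGene_expression 75 85\texpression\n"
      "E1\tGene_expression:T4 Theme:T2\n"
      "E2\tPositive_regulation:T3 Theme:E1 Cause:T1\n")
doc = read_standoff(text, a1, a2)
parse = "\n".join(f"{i}\t{s}\t{s.lower()}\tNN\t{i-1 if i else -1}\tNMOD"
                  for i, s in enumerate(text.split(" "))) + "\n"
read_parses(parse, doc)
events = assemble_events(doc.triggers, gold_edges(doc), {p.id for p in doc.proteins})
for e in events:
    print(e.id, e.event_type, "themes:", e.themes, "cause:", e.cause)
```

prints

```
E1 Gene_expression themes: ['T2'] cause: None
E2 Positive_regulation themes: ['E1'] cause: T1
```

— the inner expression event on RANTES, and the regulation event whose
theme is that event and whose cause is the RFLAT-1 protein.  Evaluating the
assembled events against the gold annotation gives precision = recall =
F1 = 1.0 in both strict and approximate span matching.

A full experiment (generate corpora, build coupling statistics, train,
score) is one call:

```python
from bioee import run_ablation
results = run_ablation(seed=1)
for fs, r in results.items():
    print(fs, "held-out trigger F1 = %.3f" % r.trigger_f1)
```

```
bf held-out trigger F1 = 0.648
bf+tpf held-out trigger F1 = 0.685
bf+tpf+cgf held-out trigger F1 = 0.841
```

The basic-feature model misses held-out triggers whose surface never
occurred in training; the trigger–protein scores recover trigger-ness and
the coupling-generalization features recover the event *type* from unseen
cue words, which is exactly the sparsity argument the method is built on.

A thin CLI mirrors these calls: `bioee fixtures`, `bioee ablate`,
`bioee run`, `bioee evaluate` (see `bioee --help`).

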