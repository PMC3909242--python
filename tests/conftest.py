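"""Shared fixtures: a hand-parsed passive clause, the nested-regulation
worked example with its standoff encoding, and small generated corpora."""

from __future__ import annotations

import pytest

from bioee.corpus_io import read_parses, read_standoff
from bioee.fixtures import FixtureConfig, generate_labeled
from bioee.model import DependencyArc, Sentence, Token


def make_sentence(rows, arcs=(), predicates=(), start=0):
    """Build a Sentence from (surface, stem, pos) rows, offsets from 0."""
    tokens = []
    pos = start
    for i, (surface, stem, tag) in enumerate(rows):
        tokens.append(Token(index=i, surface=surface, stem=stem, pos=tag,
                            char_start=pos, char_end=pos + len(surface)))
        pos += len(surface) + 1
    return Sentence(tokens=tokens, arcs=list(arcs), predicates=list(predicates),
                    sent_start=start, sent_end=pos - 1)


NEUTROPHIL_ROWS = [
    ("neutrophils", "neutrophil", "NNS"),
    ("were", "be", "VBD"),
    ("activated", "activ", "VBN"),
    ("by", "by", "IN"),
    ("phenylalanine", "phenylalanin", "NN"),
]


@pytest.fixture
def passive_sentence():
    """The passive clause with only the two arcs around 'activated'."""
    arcs = [
        DependencyArc(head_index=2, dependent_index=0, label="SUB"),
        DependencyArc(head_index=1, dependent_index=2, label="VC"),
    ]
    return make_sentence(NEUTROPHIL_ROWS, arcs)


@pytest.fixture
def passive_parse_text():
    """Full 4-arc parse of the passive clause in the TSV dialect."""
    heads = [(2, "SUB"), (-1, "ROOT"), (1, "VC"), (2, "VMOD"), (3, "PMOD")]
    lines = [
        f"{i}\t{surface}\t{stem}\t{pos}\t{head}\t{label}"
        for i, ((surface, stem, pos), (head, label)) in enumerate(zip(NEUTROPHIL_ROWS, heads))
    ]
    return "\n".join(lines) + "\n"


RFLAT_TEXT = ("RFLAT-1: a new zinc finger transcription factor that activates "
              "RANTES gene expression in T lymphocytes")

_RFLAT_TOKENS = [
    ("RFLAT-1", "rflat-1", "NN"), (":", ":", ":"), ("a", "a", "DT"),
    ("new", "new", "JJ"), ("zinc", "zinc", "NN"), ("finger", "finger", "NN"),
    ("transcription", "transcript", "NN"), ("factor", "factor", "NN"),
    ("that", "that", "WDT"), ("activates", "activ", "VBZ"),
    ("RANTES", "rantes", "NN"), ("gene", "gene", "NN"),
    ("expression", "express", "NN"), ("in", "in", "IN"),
    ("T", "t", "NN"), ("lymphocytes", "lymphocyt", "NNS"),
]


def rflat_standoff():
    i_act = RFLAT_TEXT.index("activates")
    i_ran = RFLAT_TEXT.index("RANTES")
    i_exp = RFLAT_TEXT.index("expression")
    a1 = (f"T1\tProtein 0 7\tRFLAT-1\n"
          f"T2\tProtein {i_ran} {i_ran + 6}\tRANTES\n")
    a2 = (f"T3\tPositive_regulation {i_act} {i_act + 9}\tactivates\n"
          f"T4\tGene_expression {i_exp} {i_exp + 10}\texpression\n"
          f"E1\tGene_expression:T4 Theme:T2\n"
          f"E2\tPositive_regulation:T3 Theme:E1 Cause:T1\n")
    return RFLAT_TEXT, a1, a2


def rflat_parse_text():
    lines = [f"{i}\t{s}\t{st}\t{p}\t{i - 1 if i else -1}\tNMOD"
             for i, (s, st, p) in enumerate(_RFLAT_TOKENS)]
    return "\n".join(lines) + "\n"


@pytest.fixture
def rflat_document():
    """The transcription-factor sentence with its two nested gold events,
    fully parsed."""
    text, a1, a2 = rflat_standoff()
    doc = read_standoff(text, a1, a2)
    return read_parses(rflat_parse_text(), doc)


@pytest.fixture(scope="session")
def small_config():
    return FixtureConfig(seed=5, n_docs=4, sentences_per_doc=6, vocab_size=200,
                         unlabeled_sentences=300)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_labeled(small_config)
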