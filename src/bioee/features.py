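"""Basic feature extractors for trigger and argument classification.

All extractors return a sparse ``FeatureVector`` (dict mapping feature name
to real value); basic features are binary (value 1.0).  Names are namespaced
``family:payload`` so every emitted feature parses back into its family.

Families
--------
``tok``            token surface / stem / POS plus a symmetric surface window
``ngw``            word n-grams (n = 1..4) in the 4-token window around a candidate
``ngp``            n-grams between a token pair, plus stem+POS composites on the path
``wv`` / ``posv``  vertex walks: head -(label)-> modifier in word / POS form
``ew``             edge walks: label1 (node) label2 patterns, word and POS variants
``pas``            predicate-argument key words (connectivity strictly greater than 3)
``glbow``/``glng`` bag of dictionary tokens / 2-3-grams per general region
``srng``           2-3-grams inside the 4-token surrounding windows
``sloff``          dictionary n-grams at specific offsets within +/-5 of a target
``clng``           conjunct-location n-grams keyed by orientation and distance bucket

The last five families are the lexical-context features used as
example-distinguishing features (EDFs) by the coupling-generalization step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Sentence

FeatureVector = dict[str, float]

EDF_FAMILIES = ("glbow", "glng", "srng", "sloff", "clng")

# context sizes
TOKEN_WINDOW = 3      # symmetric surface window for token features
NGRAM_WINDOW = 4      # tokens on each side for the n-gram window
SL_WINDOW = 5         # specific-location window around each target
SR_WINDOW = 4         # surrounding-region window size


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split a feature name into (family, payload)."""
    family, _, payload = name.partition(":")
    return family, payload


def merge(*vectors: FeatureVector) -> FeatureVector:
    """Union of feature vectors; later vectors win on (rare) name collisions."""
    out: FeatureVector = {}
    for vec in vectors:
        out.update(vec)
    return out


def _surfaces(sentence: Sentence) -> list[str]:
    return [t.surface.lower() for t in sentence.tokens]


# ---------------------------------------------------------------------------
# token / n-gram / walk / PAS features
# ---------------------------------------------------------------------------

def token_features(sentence: Sentence, index: int) -> FeatureVector:
    """Surface, stem and POS of a token plus surfaces in a symmetric window.

    Lexical payloads are lowercased; POS payloads keep their case.
    """
    if not 0 <= index < len(sentence.tokens):
        raise IndexError(f"token index {index} out of range")
    tok = sentence.tokens[index]
    fv: FeatureVector = {
        f"tok:surf={tok.surface.lower()}": 1.0,
        f"tok:stem={tok.stem.lower()}": 1.0,
        f"tok:pos={tok.pos}": 1.0,
    }
    for off in range(-TOKEN_WINDOW, TOKEN_WINDOW + 1):
        if off == 0:
            continue
        j = index + off
        if 0 <= j < len(sentence.tokens):
            fv[f"tok:win[{off:+d}]={sentence.tokens[j].surface.lower()}"] = 1.0
    return fv


def ngram_window_features(sentence: Sentence, index: int) -> FeatureVector:
    """All contiguous word n-grams (n = 1..4) in the 4-token window around
    ``index`` (candidate included, clipped at sentence bounds)."""
    if not 0 <= index < len(sentence.tokens):
        raise IndexError(f"token index {index} out of range")
    words = _surfaces(sentence)
    lo = max(0, index - NGRAM_WINDOW)
    hi = min(len(words), index + NGRAM_WINDOW + 1)
    window = words[lo:hi]
    fv: FeatureVector = {}
    for n in range(1, 5):
        for start in range(0, len(window) - n + 1):
            fv[f"ngw:{' '.join(window[start:start + n])}"] = 1.0
    return fv


def ngram_pair_features(sentence: Sentence, i: int, j: int) -> FeatureVector:
    """Pair features for argument detection: word n-grams (n = 1..4) strictly
    between the targets, plus stem+POS composite 2-3-grams on the i..j path."""
    if i >= j:
        raise ValueError(f"require i < j, got i={i}, j={j}")
    words = _surfaces(sentence)
    fv: FeatureVector = {}
    between = words[i + 1:j]
    for n in range(1, 5):
        for start in range(0, len(between) - n + 1):
            fv[f"ngp:btw={' '.join(between[start:start + n])}"] = 1.0
    path = [f"{t.stem.lower()}/{t.pos}" for t in sentence.tokens[i:j + 1]]
    for n in (2, 3):
        for start in range(0, len(path) - n + 1):
            fv[f"ngp:wp={' '.join(path[start:start + n])}"] = 1.0
    return fv


def walk_features(sentence: Sentence, index: int) -> FeatureVector:
    """Dependency-walk features around a token.

    For every arc incident to the token a vertex walk head-(label)->modifier
    is emitted in word form (``wv``) and POS form (``posv``); for every pair
    of incident arcs an edge walk label1(node)label2 is emitted with the node
    rendered both as word and as POS (``ew``).  Incidence is undirected; the
    arc direction survives in the head->modifier rendering.
    """
    if not 0 <= index < len(sentence.tokens):
        raise IndexError(f"token index {index} out of range")
    toks = sentence.tokens
    incident = [a for a in sentence.arcs
                if a.head_index == index or a.dependent_index == index]
    fv: FeatureVector = {}
    for arc in incident:
        head, dep = toks[arc.head_index], toks[arc.dependent_index]
        fv[f"wv:{head.surface.lower()}({arc.label}){dep.surface.lower()}"] = 1.0
        fv[f"posv:{head.pos}({arc.label}){dep.pos}"] = 1.0
    node = toks[index]
    for a in range(len(incident)):
        for b in range(a + 1, len(incident)):
            l1, l2 = sorted((incident[a].label, incident[b].label))
            fv[f"ew:w={l1}({node.surface.lower()}){l2}"] = 1.0
            fv[f"ew:p={l1}({node.pos}){l2}"] = 1.0
    return fv


def pas_connectivity(sentence: Sentence) -> dict[int, int]:
    """Distinct-token connectivity of each token across all PAS records."""
    links: dict[int, set[int]] = {}
    for pred in sentence.predicates:
        p = pred.predicate_index
        for _, a in pred.arguments:
            links.setdefault(p, set()).add(a)
            links.setdefault(a, set()).add(p)
    return {i: len(s) for i, s in links.items()}


def pas_features(sentence: Sentence) -> FeatureVector:
    """Key-word features for tokens linked to more than 3 distinct tokens in
    the predicate-argument structure (strict inequality)."""
    fv: FeatureVector = {}
    for idx, degree in pas_connectivity(sentence).items():
        if degree > 3:
            fv[f"pas:keyword={sentence.tokens[idx].surface.lower()}"] = 1.0
    return fv


# ---------------------------------------------------------------------------
# regions and lexical-context (EDF) features
# ---------------------------------------------------------------------------

DISTANCE_BUCKETS = (
    "0", "1", "2", "3", "4",
    "(5~6)", "(7~9)", "(10~14)", "(15~19)", "(20~29)", "(30~39)", "(40~)",
)


def distance_bucket(space: int) -> str:
    """Bucket a non-negative token distance into the closed 12-bucket set."""
    if space < 0:
        raise ValueError("distance must be non-negative")
    if space <= 4:
        return str(space)
    for hi, name in ((6, "(5~6)"), (9, "(7~9)"), (14, "(10~14)"),
                     (19, "(15~19)"), (29, "(20~29)"), (39, "(30~39)")):
        if space <= hi:
            return name
    return "(40~)"


@dataclass
class RegionMap:
    """Token-index regions around an ordered target pair (t1 < t2).

    Intervals are inclusive (start, end) pairs, possibly empty when
    ``start > end`` after clipping; the inner region excludes both targets.
    """
    t1: int
    t2: int
    left: tuple[int, int]
    inner: tuple[int, int]
    right: tuple[int, int]
    sr: dict[str, tuple[int, int]] = field(default_factory=dict)
    cl_bucket: str = ""

    def region_tokens(self, interval: tuple[int, int]) -> range:
        lo, hi = interval
        return range(lo, hi + 1)


def region_partition(sentence: Sentence, t1: int, t2: int) -> RegionMap:
    """Split a sentence into general regions, surrounding windows and the
    conjunct-location distance bucket for a target pair."""
    if t1 >= t2:
        raise ValueError(f"require t1 < t2, got t1={t1}, t2={t2}")
    last = len(sentence.tokens) - 1

    def clip(lo: int, hi: int) -> tuple[int, int]:
        return (max(0, lo), min(last, hi))

    return RegionMap(
        t1=t1,
        t2=t2,
        left=clip(0, t1 - 1),
        inner=clip(t1 + 1, t2 - 1),
        right=clip(t2 + 1, last),
        sr={
            "T1_Left": clip(t1 - SR_WINDOW, t1 - 1),
            "T1_Right": clip(t1 + 1, t1 + SR_WINDOW),
            "T2_Left": clip(t2 - SR_WINDOW, t2 - 1),
            "T2_Right": clip(t2 + 1, t2 + SR_WINDOW),
        },
        cl_bucket=distance_bucket(t2 - t1),
    )


@dataclass
class FeatureDictionaries:
    """Token and 2-3-gram vocabularies from labeled (l*) and unlabeled (u*)
    data; grams are lowercased, space-joined.

    The lexical-context families filter their payloads through the union of
    the labeled and unlabeled vocabularies: a context word unseen in the
    labeled corpus still forms a feature when the unlabeled corpus knows it,
    which is what lets the coupling-generalization step transfer statistics
    to out-of-vocabulary contexts.
    """
    lwd: set[str] = field(default_factory=set)
    uwd: set[str] = field(default_factory=set)
    lnd: set[str] = field(default_factory=set)
    und: set[str] = field(default_factory=set)
    _word_cache: set[str] | None = field(default=None, repr=False, compare=False)
    _gram_cache: set[str] | None = field(default=None, repr=False, compare=False)

    @property
    def word_vocab(self) -> set[str]:
        if self._word_cache is None:
            self._word_cache = self.lwd | self.uwd
        return self._word_cache

    @property
    def gram_vocab(self) -> set[str]:
        if self._gram_cache is None:
            self._gram_cache = self.lnd | self.und
        return self._gram_cache

    @staticmethod
    def grams(words: list[str]) -> set[str]:
        out: set[str] = set()
        for n in (2, 3):
            for start in range(0, len(words) - n + 1):
                out.add(" ".join(words[start:start + n]))
        return out

    def add_labeled(self, words: list[str]) -> None:
        words = [w.lower() for w in words]
        self.lwd.update(words)
        self.lnd.update(self.grams(words))
        self._word_cache = self._gram_cache = None

    def add_unlabeled(self, words: list[str]) -> None:
        words = [w.lower() for w in words]
        self.uwd.update(words)
        self.und.update(self.grams(words))
        self._word_cache = self._gram_cache = None


def pair_context_features(sentence: Sentence, t1: int, t2: int,
                          dicts: FeatureDictionaries) -> FeatureVector:
    """Lexical-context features (families glbow/glng/srng/sloff/clng) for a
    target pair, filtered through the labeled dictionaries.

    These are the EDFs consumed by coupling generalization: location-tagged
    bags of dictionary words and n-grams, offset-anchored n-grams within
    +/-5 of either target, and conjunct bigrams keyed by the bucketed
    inter-target distance.
    """
    regions = region_partition(sentence, t1, t2)
    words = _surfaces(sentence)
    fv: FeatureVector = {}

    # (7) general-region bag of words and (8) bag of 2-3-grams
    for name, interval in (("Left", regions.left), ("Inner", regions.inner),
                           ("Right", regions.right)):
        span = [i for i in regions.region_tokens(interval) if i not in (t1, t2)]
        for i in span:
            if words[i] in dicts.word_vocab:
                fv[f"glbow:Token_In_{name}_Location={words[i]}"] = 1.0
        # grams over the contiguous region
        seg = [words[i] for i in span]
        for gram in FeatureDictionaries.grams(seg):
            if gram in dicts.gram_vocab:
                fv[f"glng:Ngram_In_{name}_Location={gram}"] = 1.0

    # (9) surrounding-window 2-3-grams
    for wname, interval in regions.sr.items():
        lo, hi = interval
        seg = words[lo:hi + 1] if lo <= hi else []
        for gram in FeatureDictionaries.grams(seg):
            if gram in dicts.gram_vocab:
                fv[f"srng:{wname}={gram}"] = 1.0

    # (10) specific-location n-grams with unsigned offsets from either target
    for target in (t1, t2):
        for n in (1, 2, 3):
            for start in range(0, len(words) - n + 1):
                span = range(start, start + n)
                if target in span:
                    continue
                d = abs(start - target)
                if d > SL_WINDOW:
                    continue
                gram = " ".join(words[start:start + n])
                vocab = dicts.word_vocab if n == 1 else dicts.gram_vocab
                if gram in vocab:
                    fv[f"sloff:{d}_From_Tar={gram}"] = 1.0

    # (11) conjunct-location bigrams near both targets, keyed by distance bucket
    for o1 in ("Left", "Right"):
        for o2 in ("Left", "Right"):
            g1 = _adjacent_bigram(words, t1, o1)
            g2 = _adjacent_bigram(words, t2, o2)
            if g1 in dicts.gram_vocab and g2 in dicts.gram_vocab:
                fv[f"clng:T1_{o1}^T2_{o2}^{regions.cl_bucket}={g1}|{g2}"] = 1.0
    return fv


def _adjacent_bigram(words: list[str], t: int, orient: str) -> str | None:
    if orient == "Left":
        lo = t - 2
        if lo < 0:
            return None
        return " ".join(words[lo:t])
    hi = t + 3
    if hi > len(words):
        return None
    return " ".join(words[t + 1:hi])
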