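"""Event Feature Coupling Generalization (EFCG) and trigger-protein scores.

The semi-supervised core of the package.  Two kinds of prior features are
drawn from the labeled data: example-distinguishing features (EDFs, the
sparse lexical-context families) and class-distinguishing features (CDFs,
selected by a chi-square-like statistic over the labeled contingency
counts).  The relatedness of an (EDF, CDF) pair — the feature coupling
degree, FCD — is then estimated from sentence co-occurrence in a large
unlabeled corpus with a smoothed, log-scaled variant of pointwise mutual
information:

    FCD(U, e, c) = log10(co(e,c) + b) / (log10(count(e) + b) * log10(count(c) + b))

with smoothing factor b = 1 by default.  Each instance's EDFs are finally
folded into a dense generated feature space G = R x C x T indexed by
(root concept, CDF, FCD type), summing the FCDs of the instance's EDFs that
share a root.  The same FCD score, applied to (trigger stem, protein
surface) pairs counted separately in labeled and unlabeled text, yields the
real-valued trigger-protein features (TPF) — the "soft" strategy of adding
scores to the feature space instead of thresholding pairs away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import MappingError, UndefinedScoreError
from .features import FeatureVector
from .model import ProteinMention, Sentence

PMI_MOD = "pmi_mod"


# ---------------------------------------------------------------------------
# CDF selection (labeled contingency counts)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of labeled instances for one feature under a binary partition:
    t/m = positives/negatives containing the feature, n/k = lacking it."""
    t: int
    m: int
    n: int
    k: int


def cdf_score(counts: ContingencyCounts) -> float:
    """Class-distinguishing score (t*k - m*n)^2 / ((t+m)*(k+n)).

    Vanishes for class-independent features and is symmetric under swapping
    the positive/negative labels.  Raises :class:`UndefinedScoreError` when
    a denominator factor is zero (feature present in all or no instances).
    """
    t, m, n, k = counts.t, counts.m, counts.n, counts.k
    if min(t, m, n, k) < 0:
        raise ValueError("contingency counts must be non-negative")
    denom = (t + m) * (k + n)
    if denom == 0:
        raise UndefinedScoreError(f"degenerate contingency table {counts}")
    return (t * k - m * n) ** 2 / denom


def select_cdfs(instances: Sequence[FeatureVector], labels: Sequence[str],
                k: int = 400) -> list[str]:
    """Select the top-``k`` class-distinguishing features.

    The score is computed one-vs-rest for every class present and a feature
    keeps its maximum over classes; ties break lexicographically by feature
    name.  ``k`` larger than the vocabulary returns every feature; the
    default of 400 follows the operating point where adding further CDFs
    stops improving the generated features.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if not instances:
        raise ValueError("need at least one labeled instance")
    if len(instances) != len(labels):
        raise ValueError("instances and labels must align")
    classes = sorted(set(labels))
    total = len(instances)
    class_total = {c: labels.count(c) for c in classes}
    # per feature: total presence and per-class presence
    present_total: dict[str, int] = {}
    present_by_class: dict[str, dict[str, int]] = {}
    for fv, label in zip(instances, labels):
        for name in fv:
            present_total[name] = present_total.get(name, 0) + 1
            per = present_by_class.setdefault(name, {})
            per[label] = per.get(label, 0) + 1

    scored: list[tuple[float, str]] = []
    for name, tot_with in present_total.items():
        best = 0.0
        for cls in classes:
            t = present_by_class[name].get(cls, 0)
            m = tot_with - t
            n = class_total[cls] - t
            kk = (total - class_total[cls]) - m
            counts = ContingencyCounts(t=t, m=m, n=n, k=kk)
            try:
                best = max(best, cdf_score(counts))
            except UndefinedScoreError:
                continue  # feature present in every instance: cannot distinguish
        scored.append((best, name))
    scored.sort(key=lambda sn: (-sn[0], sn[1]))
    return [name for _, name in scored[:k]]


# ---------------------------------------------------------------------------
# FCD on unlabeled co-occurrence
# ---------------------------------------------------------------------------

def fcd_score(co: int, count_e: int, count_c: int, b: float = 1.0) -> float:
    """Feature coupling degree: smoothed, log-scaled PMI variant.

    ``log10(co+b) / (log10(count_e+b) * log10(count_c+b))``.  Undefined
    (raises) when a marginal count plus smoothing is <= 1, since the log
    factor is then non-positive.
    """
    if b <= 0:
        raise ValueError("smoothing factor b must be positive")
    if min(co, count_e, count_c) < 0:
        raise ValueError("counts must be non-negative")
    d1 = math.log10(count_e + b)
    d2 = math.log10(count_c + b)
    if d1 <= 0 or d2 <= 0:
        raise UndefinedScoreError(
            f"fcd undefined for count_e={count_e}, count_c={count_c}, b={b}"
        )
    return math.log10(co + b) / (d1 * d2)


def _safe_fcd(co: int, count_e: int, count_c: int, b: float) -> float:
    """fcd_score with undefined cases mapped to 0 (for soft TPF scoring)."""
    try:
        return fcd_score(co, count_e, count_c, b)
    except UndefinedScoreError:
        return 0.0


def lexical_key(item: str) -> tuple[tuple[str, ...], ...]:
    """Token sequences a vocabulary item stands for in running text.

    Feature names keep only the lexical payload (text after ``=``); conjunct
    payloads split on ``|`` into several sequences that must all occur.
    Plain words/n-grams pass through unchanged.
    """
    if "=" in item:
        payload = item.split("=", 1)[1]
    elif ":" in item:
        payload = item.split(":", 1)[1]
    else:
        payload = item
    parts = [p for p in payload.split("|") if p]
    return tuple(tuple(part.lower().split()) for part in parts)


@dataclass
class CoocStats:
    """Sentence-level occurrence and co-occurrence counts in a corpus."""
    count_e: dict[str, int] = field(default_factory=dict)
    count_c: dict[str, int] = field(default_factory=dict)
    co: dict[tuple[str, str], int] = field(default_factory=dict)
    n_sentences: int = 0

    def to_tsv(self) -> str:
        lines = [f"#sentences\t{self.n_sentences}"]
        for name, counts in (("e", self.count_e), ("c", self.count_c)):
            for item in sorted(counts):
                lines.append(f"{name}\t{item}\t{counts[item]}")
        for (e, c) in sorted(self.co):
            lines.append(f"co\t{e}\t{c}\t{self.co[(e, c)]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CoocStats":
        stats = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            cols = line.split("\t")
            if cols[0] == "#sentences":
                stats.n_sentences = int(cols[1])
            elif cols[0] == "e":
                stats.count_e[cols[1]] = int(cols[2])
            elif cols[0] == "c":
                stats.count_c[cols[1]] = int(cols[2])
            elif cols[0] == "co":
                stats.co[(cols[1], cols[2])] = int(cols[3])
        return stats


def _contains(words: list[str], positions: dict[str, list[int]],
              key: tuple[tuple[str, ...], ...]) -> bool:
    for part in key:
        if not part:
            return False
        first = part[0]
        hit = False
        for pos in positions.get(first, ()):
            if tuple(words[pos:pos + len(part)]) == part:
                hit = True
                break
        if not hit:
            return False
    return True


def collect_cooccurrence(unlabeled_sentences: Iterable[Sequence[str]],
                         edf_vocab: Iterable[str],
                         cdf_vocab: Iterable[str]) -> CoocStats:
    """Single-pass sentence-level (co-)occurrence counting.

    ``count_e``/``count_c`` hold the number of sentences containing each
    vocabulary item at least once; ``co`` the number containing both members
    of a pair.  Items are matched through their lexical payloads
    (contiguous, lowercased token sequences).
    """
    edf_items = [(item, lexical_key(item)) for item in sorted(set(edf_vocab))]
    cdf_items = [(item, lexical_key(item)) for item in sorted(set(cdf_vocab))]
    if not edf_items or not cdf_items:
        raise ValueError("vocabularies must be non-empty")
    # index items by the first token of their first part for fast screening
    e_by_tok: dict[str, list[int]] = {}
    for i, (_, key) in enumerate(edf_items):
        if key and key[0]:
            e_by_tok.setdefault(key[0][0], []).append(i)
    c_by_tok: dict[str, list[int]] = {}
    for i, (_, key) in enumerate(cdf_items):
        if key and key[0]:
            c_by_tok.setdefault(key[0][0], []).append(i)

    stats = CoocStats()
    for sentence in unlabeled_sentences:
        words = [w.lower() for w in sentence]
        positions: dict[str, list[int]] = {}
        for pos, w in enumerate(words):
            positions.setdefault(w, []).append(pos)
        stats.n_sentences += 1

        def present(items, by_tok):
            seen: set[int] = set()
            for w in positions:
                seen.update(by_tok.get(w, ()))
            out = []
            for i in sorted(seen):
                item, key = items[i]
                if _contains(words, positions, key):
                    out.append(item)
            return out

        present_e = present(edf_items, e_by_tok)
        present_c = present(cdf_items, c_by_tok)
        for e in present_e:
            stats.count_e[e] = stats.count_e.get(e, 0) + 1
        for c in present_c:
            stats.count_c[c] = stats.count_c.get(c, 0) + 1
        for e in present_e:
            for c in present_c:
                stats.co[(e, c)] = stats.co.get((e, c), 0) + 1
    return stats


# ---------------------------------------------------------------------------
# FCD table and generated feature vectors
# ---------------------------------------------------------------------------

@dataclass
class FCDTable:
    """Sparse (EDF, CDF, type) -> FCD score table; zero scores are dropped."""
    smoothing_b: float = 1.0
    rows: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)

    def lookup(self, e: str, c: str, t: str = PMI_MOD) -> float:
        return self.rows.get(e, {}).get((c, t), 0.0)

    def __len__(self) -> int:
        return sum(len(r) for r in self.rows.values())

    def to_tsv(self) -> str:
        lines = [f"#b\t{self.smoothing_b}"]
        for e in sorted(self.rows):
            for (c, t), score in sorted(self.rows[e].items()):
                lines.append(f"{e}\t{c}\t{t}\t{score!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "FCDTable":
        table = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            cols = line.split("\t")
            if cols[0] == "#b":
                table.smoothing_b = float(cols[1])
            else:
                e, c, t, score = cols
                table.rows.setdefault(e, {})[(c, t)] = float(score)
        return table


def build_fcd_table(stats: CoocStats, b: float = 1.0) -> FCDTable:
    """Score every co-occurring (EDF, CDF) pair with the pmi_mod measure."""
    if b <= 0:
        raise ValueError("smoothing factor b must be positive")
    table = FCDTable(smoothing_b=b)
    for (e, c), co in stats.co.items():
        if co <= 0:
            continue
        score = fcd_score(co, stats.count_e[e], stats.count_c[c], b)
        if score != 0.0:
            table.rows.setdefault(e, {})[(c, PMI_MOD)] = score
    return table


def default_root(edf: str) -> str:
    """Map an EDF to its root concept: the family x region part of its name
    (everything before the lexical payload)."""
    return edf.split("=", 1)[0]


@dataclass
class CGFIndex:
    """The generated feature space G = R x C x T and the root(e) map."""
    roots: tuple[str, ...]
    cdfs: tuple[str, ...]
    types: tuple[str, ...] = (PMI_MOD,)
    root_of: dict[str, str] = field(default_factory=dict)

    @property
    def dimension(self) -> int:
        return len(self.roots) * len(self.cdfs) * len(self.types)


def build_cgf_index(edf_vocab: Iterable[str], cdfs: Sequence[str]) -> CGFIndex:
    """Index construction: roots are the distinct family x region concepts of
    the EDF vocabulary; the CDF axis keeps the given selection order."""
    root_of = {e: default_root(e) for e in set(edf_vocab)}
    roots = tuple(sorted(set(root_of.values())))
    return CGFIndex(roots=roots, cdfs=tuple(cdfs), root_of=dict(root_of))


def cgf_vector(instance_edfs: Iterable[str], index: CGFIndex,
               table: FCDTable) -> FeatureVector:
    """Fold an instance's EDFs into the generated feature space.

    Component (r, c, t) sums FCD_t(U, e, c) over the instance's EDFs e with
    root(e) = r; the result is linear in the EDF indicator vector.  Raises
    :class:`MappingError` for EDFs outside the root map's domain.
    """
    acc: dict[tuple[str, str, str], float] = {}
    cdf_set = set(index.cdfs)
    for e in set(instance_edfs):
        try:
            r = index.root_of[e]
        except KeyError:
            raise MappingError(f"EDF {e!r} has no root mapping") from None
        for (c, t), score in table.rows.get(e, {}).items():
            if c in cdf_set and t in index.types:
                key = (r, c, t)
                acc[key] = acc.get(key, 0.0) + score
    return {f"cgf:({r}|{c}|{t})": v for (r, c, t), v in acc.items() if v != 0.0}


# ---------------------------------------------------------------------------
# Trigger-protein features (TPF)
# ---------------------------------------------------------------------------

def pair_stats(sentences: Iterable[Sequence[str]], stems: Iterable[str],
               protein_surfaces: Iterable[str]) -> CoocStats:
    """Sentence co-occurrence of candidate stems with protein surface forms,
    the statistical substrate for TPF scoring."""
    return collect_cooccurrence(sentences, stems, protein_surfaces)


# cumulative bin edges for the thermometer encoding of TPF scores
TPF_BIN_EDGES = (0.05, 0.10, 0.15, 0.20, 0.25)


def tpf_features(sentence: Sentence, candidate: int,
                 proteins: Sequence[ProteinMention],
                 labeled_stats: CoocStats | None,
                 unlabeled_stats: CoocStats | None,
                 b: float = 1.0) -> FeatureVector:
    """Soft trigger-protein score features for a candidate token.

    The candidate's stem is paired with every in-sentence protein surface;
    the pmi_mod score of each pair is computed separately under the labeled
    and the unlabeled counts, and the maxima enter the feature space as
    real values (no threshold — low-scoring pairs stay, other features
    compensate).  Pairs never observed score 0 and are omitted.

    Each raw maximum is accompanied by cumulative "score >= edge"
    indicators (thermometer encoding), so the margin-based learner can put
    an independent weight on every score threshold instead of relying on a
    single linear coefficient for a small-magnitude real value.
    """
    if not proteins:
        return {}
    stem = sentence.tokens[candidate].stem.lower()
    fv: FeatureVector = {}
    for name, stats in (("labeled", labeled_stats), ("unlabeled", unlabeled_stats)):
        if stats is None:
            continue
        best = 0.0
        for prot in proteins:
            key = prot.text.lower()
            co = stats.co.get((stem, key), 0)
            best = max(best, _safe_fcd(co, stats.count_e.get(stem, 0),
                                       stats.count_c.get(key, 0), b))
        if best > 0.0:
            fv[f"tpf:max_{name}"] = best
            for edge in TPF_BIN_EDGES:
                if best >= edge:
                    fv[f"tpf:max_{name}>={edge:.2f}"] = 1.0
    return fv
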