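"""Feature extraction and binary classification of candidate homolog pairs.

Two heterotigs that are the two haplotype versions of one locus (a
"homolotig pair") should have near-equal lengths, near-equal sequencing
depths, high local-alignment identity over most of the shorter sequence,
and depths close to the haploid modal depth. The six-feature vector:

    length_ratio         = min(len_a, len_b) / max(len_a, len_b)
    depth_ratio          = min(dep_a, dep_b) / max(dep_a, dep_b)
    pct_identical        = identical columns / alignment columns * 100
    pct_length_alignment = alignment columns / min(len_a, len_b) * 100 (capped at 100)
    depth_prop_a         = dep_a / modal depth of all contigs
    depth_prop_b         = dep_b / modal depth of all contigs

When no depth table is available the three depth features are dropped and
the classifier runs in reduced-feature mode.

Pairs found in perfect bubbles are the positive training examples; negative
examples are seeded random contig pairs that share no scaffold-graph edge
and are not perfect-bubble partners. The learner is pluggable (logistic
regression by default; multilayer perceptron and SVM behind tags), always
wrapped in a feature scaler, with a probability output thresholded at 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .align import smith_waterman
from .bubbles import Bubble
from .formats import ContigRecord
from .graph import ContigEnd, End, ScaffoldGraph

logger = logging.getLogger(__name__)

HOMOLOG = "HOMOLOG"
NON_HOMOLOG = "NON_HOMOLOG"

FULL_FEATURES = (
    "length_ratio",
    "depth_ratio",
    "pct_identical",
    "pct_length_alignment",
    "depth_prop_a",
    "depth_prop_b",
)
REDUCED_FEATURES = ("length_ratio", "pct_identical", "pct_length_alignment")


class TrainingSetError(RuntimeError):
    """Too few perfect bubbles to train; fall back to bubbles-only scaffolds."""


def pairwise_identity(seq_a: str, seq_b: str, min_score: int = 20) -> tuple[float, int]:
    """Percent identity and column length of the best local alignment.

    BLASTn-outfmt-6 semantics: identity = identical columns over all
    alignment columns (gap columns included) x 100. Alignments scoring
    below ``min_score`` report (0.0, 0)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    score, matches, columns = smith_waterman(seq_a, seq_b)
    if score < min_score or columns == 0:
        return 0.0, 0
    return matches / columns * 100.0, columns


def depth_mode(
    depth_table: dict[str, float],
    bin_width: float = 1.0,
    contig_lengths: dict[str, int] | None = None,
    min_len: int = 100,
) -> float:
    """Modal depth: the center of the most populated histogram bin.

    Bins are centered on multiples of ``bin_width`` (bin k covers
    [k*w - w/2, k*w + w/2)); ties break toward the lower bin. When contig
    lengths are supplied, only contigs of at least ``min_len`` bases count."""
    if not depth_table:
        raise ValueError("depth table is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    counts: dict[int, int] = {}
    for cid, depth in depth_table.items():
        if contig_lengths is not None:
            if cid not in contig_lengths or contig_lengths[cid] < min_len:
                continue
        k = math.floor(depth / bin_width + 0.5)
        counts[k] = counts.get(k, 0) + 1
    if not counts:
        raise ValueError("no contigs eligible for the depth mode")
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0] * bin_width


@dataclass(frozen=True, slots=True)
class FeatureVector:
    length_ratio: float
    pct_identical: float
    pct_length_alignment: float
    depth_ratio: Optional[float] = None
    depth_prop_a: Optional[float] = None
    depth_prop_b: Optional[float] = None

    @property
    def has_depth(self) -> bool:
        return self.depth_ratio is not None

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FULL_FEATURES if self.has_depth else REDUCED_FEATURES

    def values(self) -> np.ndarray:
        if self.has_depth:
            return np.array(
                [
                    self.length_ratio,
                    self.depth_ratio,
                    self.pct_identical,
                    self.pct_length_alignment,
                    self.depth_prop_a,
                    self.depth_prop_b,
                ]
            )
        return np.array([self.length_ratio, self.pct_identical, self.pct_length_alignment])


def compute_feature_vector(
    contig_a: ContigRecord,
    contig_b: ContigRecord,
    depth_table: dict[str, float] | None = None,
    modal_depth: float | None = None,
    min_score: int = 20,
) -> FeatureVector:
    """The feature vector for one candidate pair (reduced when depths are
    unavailable for either contig)."""
    if contig_a.length == 0 or contig_b.length == 0:
        raise ValueError("zero-length contig")
    len_a, len_b = contig_a.length, contig_b.length
    length_ratio = min(len_a, len_b) / max(len_a, len_b)
    pct_ident, aln_len = pairwise_identity(contig_a.sequence, contig_b.sequence, min_score)
    pct_len_aln = min(100.0, aln_len / min(len_a, len_b) * 100.0)

    have_depth = (
        depth_table is not None
        and modal_depth is not None
        and modal_depth > 0
        and contig_a.id in depth_table
        and contig_b.id in depth_table
    )
    if not have_depth:
        return FeatureVector(length_ratio, pct_ident, pct_len_aln)
    dep_a, dep_b = depth_table[contig_a.id], depth_table[contig_b.id]
    return FeatureVector(
        length_ratio,
        pct_ident,
        pct_len_aln,
        depth_ratio=min(dep_a, dep_b) / max(dep_a, dep_b),
        depth_prop_a=dep_a / modal_depth,
        depth_prop_b=dep_b / modal_depth,
    )


@dataclass(slots=True)
class TrainingSet:
    vectors: list[FeatureVector]
    labels: list[str]
    provenance: list[tuple[str, str, str]]  # (contig_a, contig_b, source)

    @property
    def n_positive(self) -> int:
        return sum(1 for l in self.labels if l == HOMOLOG)

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    @property
    def has_depth(self) -> bool:
        return bool(self.vectors) and self.vectors[0].has_depth


def _contigs_adjacent(graph: ScaffoldGraph, a: str, b: str) -> bool:
    for end in (End.FIVE, End.THREE):
        for e in graph.edges_at(ContigEnd(a, end), include_excluded=True):
            if e.other(a).contig_id == b:
                return True
    return False


def build_training_set(
    perfect_bubbles: Sequence[Bubble],
    graph: ScaffoldGraph,
    contig_set: dict[str, ContigRecord],
    depth_table: dict[str, float] | None = None,
    modal_depth: float | None = None,
    negative_ratio: float = 1.0,
    seed: int = 0,
    min_training: int = 10,
    min_score: int = 20,
) -> TrainingSet:
    """Positives from perfect bubbles; seeded random negatives.

    Negatives are pairs of non-repeat contigs that share no scaffold-graph
    edge (at any support) and are not perfect-bubble partners; their count
    is ``negative_ratio`` times the positive count."""
    if len(perfect_bubbles) < min_training:
        raise TrainingSetError(
            f"only {len(perfect_bubbles)} perfect bubbles (< {min_training}); "
            "classification is skipped — emit bubbles-only scaffolds"
        )
    vectors: list[FeatureVector] = []
    labels: list[str] = []
    provenance: list[tuple[str, str, str]] = []
    partner_pairs = {frozenset(b.heterotigs) for b in perfect_bubbles}

    for bub in perfect_bubbles:
        fv = compute_feature_vector(
            contig_set[bub.a], contig_set[bub.b], depth_table, modal_depth, min_score
        )
        vectors.append(fv)
        labels.append(HOMOLOG)
        provenance.append((bub.a, bub.b, "perfect-bubble"))

    n_neg = int(round(negative_ratio * len(perfect_bubbles)))
    pool = sorted(set(contig_set) - graph.repeat_flags)
    rng = np.random.default_rng(seed)
    chosen: set[frozenset] = set()
    attempts = 0
    while len(chosen) < n_neg and attempts < 200 * max(n_neg, 1):
        attempts += 1
        i, j = rng.integers(0, len(pool), size=2)
        if i == j:
            continue
        a, b = sorted((pool[i], pool[j]))
        pair = frozenset((a, b))
        if pair in chosen or pair in partner_pairs:
            continue
        if _contigs_adjacent(graph, a, b):
            continue
        chosen.add(pair)
        fv = compute_feature_vector(
            contig_set[a], contig_set[b], depth_table, modal_depth, min_score
        )
        vectors.append(fv)
        labels.append(NON_HOMOLOG)
        provenance.append((a, b, "sampled-negative"))
    if len(chosen) < n_neg:
        logger.warning("sampled only %d of %d requested negatives", len(chosen), n_neg)
    return TrainingSet(vectors, labels, provenance)


@dataclass(slots=True)
class ClassifierModel:
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    threshold: float
    learner_tag: str
    training_size: int
    seed: int


_LEARNERS = ("logistic", "mlp", "svm")


def _make_learner(tag: str, seed: int):
    if tag == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if tag == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16, 8), max_iter=3000, random_state=seed)
    if tag == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    raise ValueError(f"unknown learner {tag!r}; available: {', '.join(_LEARNERS)}")


def train_classifier(
    training_set: TrainingSet,
    learner_tag: str = "logistic",
    seed: int = 0,
    threshold: float = 0.5,
) -> ClassifierModel:
    """Fit the pluggable binary classifier on the training set."""
    if len(set(training_set.labels)) < 2:
        raise ValueError("training set must contain both classes")
    X = np.vstack([fv.values() for fv in training_set.vectors])
    y = np.array([1 if l == HOMOLOG else 0 for l in training_set.labels])
    pipe = Pipeline([("scale", StandardScaler()), ("clf", _make_learner(learner_tag, seed))])
    pipe.fit(X, y)
    acc = float(pipe.score(X, y))
    logger.info(
        "trained %s on %d examples (%d pos / %d neg), training accuracy %.3f",
        learner_tag,
        len(y),
        training_set.n_positive,
        training_set.n_negative,
        acc,
    )
    names = FULL_FEATURES if training_set.has_depth else REDUCED_FEATURES
    return ClassifierModel(pipe, names, threshold, learner_tag, len(y), seed)


def classify_pair(model: ClassifierModel, fv: FeatureVector) -> tuple[bool, float]:
    """(is_homolog, probability); is_homolog iff probability >= threshold."""
    if fv.feature_names != model.feature_names:
        raise ValueError(
            f"feature set mismatch: model uses {model.feature_names}, "
            f"vector provides {fv.feature_names}"
        )
    prob = float(model.pipeline.predict_proba(fv.values().reshape(1, -1))[0, 1])
    return prob >= model.threshold, prob


def write_training_tsv(training_set: TrainingSet, path) -> None:
    """Audit dump: features plus labels, one row per training example."""
    names = FULL_FEATURES if training_set.has_depth else REDUCED_FEATURES
    with open(path, "w") as fh:
        fh.write("contig_a\tcontig_b\tsource\tlabel\t" + "\t".join(names) + "\n")
        for (a, b, src), label, fv in zip(
            training_set.provenance, training_set.labels, training_set.vectors
        ):
            vals = "\t".join(f"{v:.6g}" for v in fv.values())
            fh.write(f"{a}\t{b}\t{src}\t{label}\t{vals}\n")
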