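"""Training loop, five-fold cross-validation, metrics, ablations, and
novel-association ranking.

Known associations are the positive class; every unobserved (drug,
disease) pair is treated as a hard negative, both in the loss and in
evaluation — no negative sampling.  The loss is a weighted binary
cross-entropy over the full score matrix with held-out test entries
excluded; the positive-class weight defaults to #negatives/#positives to
counter the heavy class imbalance.  AUPR (step-wise average precision) is
the primary metric alongside rank-based AUC; thresholded metrics (RE, SP,
ACC, PRE, F1) are reported at the per-fold max-F1 threshold unless a fixed
threshold is requested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

from .autodiff import Adam, Tensor
from .data_io import AssociationMatrix, DatasetBundle
from .hetgraph import HeteroGraph, assemble_adjacency, mask_test_fold
from .model import (
    ModelConfig,
    ModelParams,
    ScoreMatrix,
    forward_tensors,
    init_params,
)
from .similarity import SimilarityMatrix, disease_similarity, drug_similarity

logger = logging.getLogger("multidda")

METRIC_NAMES = ("aupr", "auc", "recall", "precision", "specificity",
                "accuracy", "f1")


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """One rotation of the five-fold protocol over positive pairs."""

    index: int
    train_pairs: list[tuple[int, int]]
    test_pairs: list[tuple[int, int]]


def five_fold_split(a_known: AssociationMatrix, seed: int,
                    n_folds: int = 5) -> list[FoldSplit]:
    """Random partition of the known positives into near-equal test folds."""
    positives = a_known.positive_pairs()
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positives, got {len(positives)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    chunks = np.array_split(order, n_folds)
    folds = []
    for k, chunk in enumerate(chunks):
        test = [positives[i] for i in chunk]
        test_set = set(test)
        train = [p for p in positives if p not in test_set]
        folds.append(FoldSplit(k, train, test))
    return folds


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def weighted_bce_loss(scores: np.ndarray, labels: np.ndarray,
                      pos_weight: float | None = None,
                      mask=None) -> float:
    """Mean weighted binary cross-entropy over unmasked entries.

    ``mask`` lists (i, j) pairs to exclude (held-out test entries).
    ``pos_weight`` defaults to #negatives/#positives among the entries
    that remain in the sum.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels shape mismatch")
    if (scores <= 0).any() or (scores >= 1).any():
        raise ValueError("scores must lie strictly inside (0, 1)")
    keep = np.ones(scores.shape, dtype=bool)
    if mask is not None:
        for i, j in mask:
            keep[i, j] = False
    if not keep.any():
        raise ValueError("all entries masked; nothing to average")
    y = labels[keep]
    s = scores[keep]
    if pos_weight is None:
        n_pos = y.sum()
        pos_weight = (y.size - n_pos) / max(n_pos, 1.0)
    per = -(pos_weight * y * np.log(s) + (1 - y) * np.log1p(-s))
    return float(per.mean())


def _bce_from_logits_t(logits: Tensor, labels: np.ndarray,
                       keep: np.ndarray, pos_weight: float) -> Tensor:
    """Same loss as :func:`weighted_bce_loss`, differentiable and stable.

    Uses the softplus identities -log σ(z) = softplus(-z) and
    -log(1-σ(z)) = softplus(z).
    """
    y = Tensor(labels)
    m = Tensor(keep.astype(np.float64))
    per = (-logits).softplus() * y * pos_weight + logits.softplus() * (1.0 - y)
    return (per * m).sum() / float(keep.sum())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    params: ModelParams
    history: list[float]
    graph: HeteroGraph
    config: ModelConfig


def build_similarities(bundle: DatasetBundle, config: ModelConfig,
                       sim_modalities=("t", "e", "n", "p", "l")
                       ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Drug and disease similarity matrices used as graph blocks.

    The drug similarity always concatenates all available modalities
    (ablations restrict the model's branch inputs, not the graph).
    """
    from .data_io import MODALITY_CODES

    present = [m for m in sim_modalities
               if MODALITY_CODES.get(m, m) in bundle.modalities]
    sc = drug_similarity(bundle, present)
    sd = disease_similarity(bundle.dag, config.delta, bundle.disease_ids)
    return sc, sd


def train(bundle: DatasetBundle, fold: FoldSplit, config: ModelConfig,
          similarities: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
          ) -> TrainResult:
    """Full-batch Adam on the fold's training graph.

    The test fold's positives are removed from both the adjacency and the
    initial features before training, and excluded from the loss.
    ``iterations == 0`` returns the freshly initialized parameters.
    """
    if similarities is None:
        similarities = build_similarities(bundle, config)
    sc, sd = similarities
    a_train = mask_test_fold(bundle.associations, fold.test_pairs)
    graph = assemble_adjacency(sc, sd, a_train)

    modality_values = {
        name: bundle.modalities[name].values.astype(np.float64)
        for name in config.modality_names
    }
    params = init_params(config, graph.n_nodes, {
        name: bundle.modalities[name].n_features
        for name in config.modality_names
    })

    labels = a_train.values.astype(np.float64)
    keep = np.ones(labels.shape, dtype=bool)
    for i, j in fold.test_pairs:
        keep[i, j] = False
    n_pos = labels[keep].sum()
    pos_weight = (keep.sum() - n_pos) / max(n_pos, 1.0)

    rng = np.random.default_rng(config.seed + 7919 * (fold.index + 1))
    opt = Adam(params.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history: list[float] = []
    for it in range(config.iterations):
        logits, _ = forward_tensors(
            params, config, graph.normalized, graph.h0, graph.adjacency,
            modality_values, graph.n_drugs, train=True, rng=rng,
        )
        loss = _bce_from_logits_t(logits, labels, keep, pos_weight)
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at iteration {it}")
        history.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % 100 == 0:
            logger.info("fold %d iter %d loss %.6f", fold.index, it, value)
    return TrainResult(params, history, graph, config)


def predict(result: TrainResult, bundle: DatasetBundle) -> ScoreMatrix:
    """Eval-mode scores of the trained model on its training graph."""
    from .model import forward

    return forward(result.graph, bundle, result.params, result.config)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class FoldMetrics:
    aupr: float
    auc: float
    recall: float
    precision: float
    specificity: float
    accuracy: float
    f1: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class MetricsReport:
    """Per-fold metric values with mean ± sd aggregation."""

    folds: list[FoldMetrics] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def sd(self, metric: str) -> float:
        return float(np.std([getattr(f, metric) for f in self.folds], ddof=1)) \
            if len(self.folds) > 1 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m),
                "folds": [getattr(f, m) for f in self.folds]}
            for m in METRIC_NAMES
        }


def evaluate(scores, test_positives, negatives,
             threshold: str | float = "max_f1") -> FoldMetrics:
    """Metrics over held-out positives vs the negative universe.

    ``scores`` is the |C|×|D| score matrix (or a ScoreMatrix); AUC is the
    rank-based (Mann–Whitney, ties ½) statistic and AUPR the step-wise
    average precision.  ``threshold`` is either ``"max_f1"`` (per-fold
    F1-maximizing cut) or a fixed float.
    """
    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    test_positives = list(test_positives)
    negatives = list(negatives)
    if not test_positives or not negatives:
        raise ValueError("evaluate needs at least one positive and one negative")
    pos_idx = tuple(np.array(test_positives).T)
    neg_idx = tuple(np.array(negatives).T)
    y_score = np.concatenate([values[pos_idx], values[neg_idx]])
    y_true = np.concatenate([np.ones(len(test_positives)),
                             np.zeros(len(negatives))])

    auc = float(roc_auc_score(y_true, y_score))
    aupr = float(average_precision_score(y_true, y_score))

    if threshold == "max_f1":
        prec, rec, thr = precision_recall_curve(y_true, y_score)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1_curve = 2 * prec * rec / (prec + rec)
        f1_curve = np.nan_to_num(f1_curve[:-1])
        thr_value = float(thr[int(np.argmax(f1_curve))])
    else:
        thr_value = float(threshold)

    pred = y_score >= thr_value
    tp = int(np.sum(pred & (y_true == 1)))
    fp = int(np.sum(pred & (y_true == 0)))
    fn = int(np.sum(~pred & (y_true == 1)))
    tn = int(np.sum(~pred & (y_true == 0)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / len(y_true)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return FoldMetrics(aupr, auc, recall, precision, specificity, accuracy,
                       f1, thr_value)


def negative_universe(a_known: AssociationMatrix) -> list[tuple[int, int]]:
    """All (drug, disease) pairs with no known association."""
    return [tuple(p) for p in np.argwhere(a_known.values == 0)]


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


def run_cv(bundle: DatasetBundle, config: ModelConfig,
           n_folds: int = 5) -> MetricsReport:
    """Five-fold cross-validation: each positive subset held out once."""
    sims = build_similarities(bundle, config)
    folds = five_fold_split(bundle.associations, config.seed, n_folds)
    negatives = negative_universe(bundle.associations)
    report = MetricsReport()
    for fold in folds:
        result = train(bundle, fold, config, sims)
        scores = predict(result, bundle)
        report.folds.append(evaluate(scores, fold.test_pairs, negatives))
        logger.info("fold %d: AUC %.4f AUPR %.4f", fold.index,
                    report.folds[-1].auc, report.folds[-1].aupr)
    return report


def single_fold_run(bundle: DatasetBundle, config: ModelConfig,
                    fold_index: int = 0,
                    sims=None) -> FoldMetrics:
    """Train/evaluate on one rotation of the five-fold split (fast path)."""
    if sims is None:
        sims = build_similarities(bundle, config)
    fold = five_fold_split(bundle.associations, config.seed)[fold_index]
    result = train(bundle, fold, config, sims)
    scores = predict(result, bundle)
    return evaluate(scores, fold.test_pairs,
                    negative_universe(bundle.associations))


ABLATION_LABELS = ("t", "e", "p", "l")


def ablation_run(bundle: DatasetBundle, config: ModelConfig,
                 modality: str, n_folds: int = 5,
                 single_fold: bool = False) -> MetricsReport:
    """The single-modality variant: branches restricted to one modality.

    The graph (similarities, associations) is unchanged; only the branch
    inputs that update the drug node descriptors are restricted.
    """
    if modality not in ABLATION_LABELS:
        raise ValueError(
            f"ablation modality must be one of {ABLATION_LABELS}, "
            f"got {modality!r}")
    from dataclasses import replace

    variant = replace(config, modalities=(modality,))
    if single_fold:
        return MetricsReport([single_fold_run(bundle, variant)])
    return run_cv(bundle, variant, n_folds)


def ablation_table(bundle: DatasetBundle, config: ModelConfig,
                   single_fold: bool = True) -> dict[str, MetricsReport]:
    """Full model plus the four single-modality variants, one report each."""
    out = {"full": (MetricsReport([single_fold_run(bundle, config)])
                    if single_fold else run_cv(bundle, config))}
    for m in ABLATION_LABELS:
        out[m] = ablation_run(bundle, config, m, single_fold=single_fold)
    return out


def fraction_experiment(bundle: DatasetBundle, config: ModelConfig,
                        fractions, test_fraction: float = 0.2
                        ) -> dict[float, FoldMetrics]:
    """Retrain with a subsampled share of the known positives.

    A fixed held-out test set (``test_fraction`` of positives, seeded) is
    evaluated for every fraction; training retains the first ⌈f·n⌉ of a
    fixed permutation of the remaining positives, so larger fractions use
    supersets of smaller ones.
    """
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    sims = build_similarities(bundle, config)
    positives = bundle.associations.positive_pairs()
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(positives))
    n_test = max(1, int(round(test_fraction * len(positives))))
    test_pairs = [positives[i] for i in order[:n_test]]
    pool = [positives[i] for i in order[n_test:]]
    negatives = negative_universe(bundle.associations)

    out: dict[float, FoldMetrics] = {}
    for f in fractions:
        n_keep = max(1, int(np.ceil(f * len(pool))))
        retained = set(pool[:n_keep])
        dropped = [p for p in pool if p not in retained]
        # dropped positives become unknowns (0) for training, like any
        # unobserved pair; the fixed test set is masked out inside train()
        a_sub = mask_test_fold(bundle.associations, dropped)
        sub_bundle = DatasetBundle(bundle.modalities, a_sub, bundle.dag)
        fold = FoldSplit(0, sorted(retained), test_pairs)
        result = train(sub_bundle, fold, config, sims)
        scores = predict(result, sub_bundle)
        out[f] = evaluate(scores, test_pairs, negatives)
        logger.info("fraction %.2f: AUC %.4f AUPR %.4f", f, out[f].auc,
                    out[f].aupr)
    return out


# ---------------------------------------------------------------------------
# novel-association ranking
# ---------------------------------------------------------------------------


@dataclass
class PredictionRanking:
    """Unknown pairs ordered by predicted score (ties: drug, disease index)."""

    entries: list[tuple[str, str, float]]


def rank_novel(scores, a_known: AssociationMatrix,
               top_n: int = 10) -> PredictionRanking:
    """Top-scoring pairs among those with no known association."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    zero_pairs = np.argwhere(a_known.values == 0)
    if len(zero_pairs) == 0:
        warnings.warn("every pair is a known positive; ranking is empty")
        return PredictionRanking([])
    if top_n > len(zero_pairs):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(zero_pairs)} unknown pairs; "
            "truncating")
        top_n = len(zero_pairs)
    pair_scores = values[zero_pairs[:, 0], zero_pairs[:, 1]]
    order = np.lexsort((zero_pairs[:, 1], zero_pairs[:, 0], -pair_scores))
    entries = [
        (a_known.drug_ids[zero_pairs[i, 0]],
         a_known.disease_ids[zero_pairs[i, 1]],
         float(pair_scores[i]))
        for i in order[:top_n]
    ]
    return PredictionRanking(entries)


def paired_t_test(fold_values_a, fold_values_b) -> tuple[float, float]:
    """Paired t-test over matched fold metrics of two model variants."""
    t, p = stats.ttest_rel(fold_values_a, fold_values_b)
    return float(t), float(p)
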