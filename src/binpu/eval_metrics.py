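"""F1 metrics, discriminant-threshold search, lambda selection, the
positive-upweighting baseline, and the end-to-end synthetic benchmark.

The final classifier emits a probability per pair; the discriminant
threshold theta (positive iff score > theta) is chosen by exhaustively
maximizing F1 on validation data over a 0.01-step grid, ties resolved
toward the smallest theta.  The baseline mirrors the classical
unlabeled-as-negative strategy: one classifier trained on positives
(up-weighted w-fold) against the entire unlabeled pool, no bins, no
pseudo labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .backbone import Backbone
from .errors import ParameterError
from .losses import LossConfig
from .pu_core import (
    BinPUConfig,
    EntityIndex,
    PositiveSet,
    PseudoLabelSet,
    UnlabeledSet,
    run_binpu,
    stage_seed,
)
from .records import POSITIVE, InteractionPair

logger = logging.getLogger(__name__)

DEFAULT_THETA_GRID = tuple(np.round(np.arange(0, 101) / 100.0, 2))
DEFAULT_LAMBDA_GRID = (0.1, 0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class MetricsReport:
    f1: float
    precision: float
    recall: float
    threshold: Optional[float]
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "f1": self.f1, "precision": self.precision, "recall": self.recall,
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


@dataclass(frozen=True)
class ThresholdSearch:
    grid: tuple[float, ...]
    best_theta: float
    best_f1: float


def f1_score(y_true, y_pred_binary, threshold: Optional[float] = None) -> MetricsReport:
    """Confusion-matrix F1 with the zero-division convention P = R = F1 = 0."""
    y_true = np.asarray(y_true).ravel().astype(int)
    y_pred = np.asarray(y_pred_binary).ravel().astype(int)
    if y_true.shape != y_pred.shape:
        raise ParameterError("length mismatch between labels and predictions")
    if not np.isin(y_true, (0, 1)).all() or not np.isin(y_pred, (0, 1)).all():
        raise ParameterError("f1_score expects binary inputs")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return MetricsReport(f1, precision, recall, threshold, tp, fp, fn, tn)


def optimize_threshold(
    y_true, scores, grid: Sequence[float] = DEFAULT_THETA_GRID
) -> ThresholdSearch:
    """Exhaustive grid search for the theta maximizing F1 under the rule
    'positive iff score > theta'; ties go to the smallest theta."""
    grid = tuple(grid)
    if not grid:
        raise ParameterError("threshold grid must be non-empty")
    scores = np.asarray(scores, dtype=float).ravel()
    if ((scores < 0) | (scores > 1)).any():
        raise ParameterError("scores must lie in [0, 1]")
    best_theta, best_f1 = grid[0], -1.0
    for theta in grid:
        report = f1_score(y_true, (scores > theta).astype(int))
        if report.f1 > best_f1:
            best_theta, best_f1 = theta, report.f1
    return ThresholdSearch(grid=grid, best_theta=float(best_theta), best_f1=best_f1)


# ---------------------------------------------------------------------------
# split aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitBundle:
    """One train/validation/test partition: pairs, 0/1 labels and the mask
    flagging the curated (truly positive) rows for the loss."""

    pairs: tuple[InteractionPair, ...]
    labels: np.ndarray
    truly_positive_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def _split_indices(n: int, ratios: Sequence[float], rng: np.random.Generator):
    bounds = np.round(np.cumsum(ratios)[:-1] * n).astype(int)
    return np.split(rng.permutation(n), bounds)


def aggregate_split(
    pseudo_labels: PseudoLabelSet,
    positives: PositiveSet,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[SplitBundle, ...]:
    """Split positives and pseudo-labeled samples by the ratios, then union
    per partition.

    Positives and each pseudo class are split separately (stratified), so
    every partition mixes curated positives, pseudo-positives and
    pseudo-negatives in the global proportions.  Residual unlabeled pairs
    are not used for training and are excluded.
    """
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ParameterError(f"ratios must sum to 1, got {sum(ratios)}")
    rng = np.random.default_rng(seed)
    groups: list[tuple[Sequence[InteractionPair], int, bool]] = [
        (positives.pairs, 1, True),
        (pseudo_labels.psi_pos, 1, False),
        (pseudo_labels.psi_neg, 0, False),
    ]
    parts: list[list[tuple[InteractionPair, int, bool]]] = [[] for _ in ratios]
    for pairs, label, curated in groups:
        for part, idx in zip(parts, _split_indices(len(pairs), ratios, rng)):
            part.extend((pairs[i], label, curated) for i in sorted(idx.tolist()))
    bundles = []
    for part in parts:
        bundles.append(
            SplitBundle(
                pairs=tuple(p for p, _, _ in part),
                labels=np.array([lab for _, lab, _ in part], dtype=float),
                truly_positive_mask=np.array([cur for _, _, cur in part], dtype=bool),
            )
        )
    return tuple(bundles)


# ---------------------------------------------------------------------------
# lambda selection
# ---------------------------------------------------------------------------

def select_lambda(
    lambda_grid: Sequence[float],
    train: SplitBundle,
    validation: SplitBundle,
    backbone_builder: Callable[[LossConfig], Backbone],
    entities: EntityIndex,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> tuple[float, dict[float, MetricsReport]]:
    """Fit one model per candidate lambda, tune theta on validation, and
    return the lambda with the best validation F1 (ties -> smallest)."""
    lambda_grid = tuple(lambda_grid)
    if not lambda_grid:
        raise ParameterError("lambda grid must be non-empty")
    reports: dict[float, MetricsReport] = {}
    best_lambda, best_f1 = None, -1.0
    for lam in lambda_grid:
        model = backbone_builder(LossConfig(lambda_wp=lam))
        model.fit(
            entities.rows(train.pairs),
            train.labels,
            truly_positive_mask=train.truly_positive_mask,
        )
        scores = np.asarray(model.predict_proba(entities.rows(validation.pairs)))
        search = optimize_threshold(validation.labels, scores, theta_grid)
        report = f1_score(
            validation.labels,
            (scores > search.best_theta).astype(int),
            threshold=search.best_theta,
        )
        reports[lam] = report
        if report.f1 > best_f1:
            best_lambda, best_f1 = lam, report.f1
    return float(best_lambda), reports


# ---------------------------------------------------------------------------
# positive-upweighting baseline (unlabeled treated as negative)
# ---------------------------------------------------------------------------

def baseline_all_negative(
    positives: PositiveSet,
    unlabeled: UnlabeledSet,
    backbone_factory: Callable[[], Backbone],
    entities: EntityIndex,
    positive_weight: float = 10.0,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> tuple[Backbone, float, MetricsReport]:
    """Train one classifier on positives (weight w) vs. ALL unlabeled pairs
    as negatives — no bins, no pseudo labels.

    Positives and unlabeled pairs are split by ``ratios``; theta is tuned
    on the validation slice and the report computed on the test slice,
    both under the unlabeled-as-negative labeling.  Returns the fitted
    model, the tuned theta and the test report.
    """
    if positive_weight < 1:
        raise ParameterError(f"positive_weight must be >= 1, got {positive_weight}")
    rng = np.random.default_rng(seed)
    pos_parts = _split_indices(len(positives), ratios, rng)
    unl_parts = _split_indices(len(unlabeled), ratios, rng)

    def bundle(part_idx: int) -> tuple[list[InteractionPair], np.ndarray, np.ndarray]:
        pos = [positives.pairs[i] for i in sorted(pos_parts[part_idx].tolist())]
        unl = [unlabeled.pairs[i] for i in sorted(unl_parts[part_idx].tolist())]
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(unl))])
        weights = np.concatenate(
            [np.full(len(pos), positive_weight), np.ones(len(unl))]
        )
        return pos + unl, labels, weights

    train_pairs, train_labels, train_weights = bundle(0)
    model = backbone_factory()
    model.fit(
        entities.rows(train_pairs),
        train_labels,
        truly_positive_mask=train_labels == 1.0,
        sample_weight=train_weights,
    )
    val_pairs, val_labels, _ = bundle(1)
    val_scores = np.asarray(model.predict_proba(entities.rows(val_pairs)))
    theta = optimize_threshold(val_labels, val_scores, theta_grid).best_theta
    test_pairs, test_labels, _ = bundle(2)
    test_scores = np.asarray(model.predict_proba(entities.rows(test_pairs)))
    report = f1_score(test_labels, (test_scores > theta).astype(int), threshold=theta)
    return model, theta, report


# ---------------------------------------------------------------------------
# end-to-end synthetic benchmark
# ---------------------------------------------------------------------------

def make_reference_builder(
    seed: int,
    featurizer_config=None,
    train_config=None,
) -> Callable[[LossConfig], Backbone]:
    """Builder producing reference backbones with per-call seed offsets.

    Each call returns a fresh backbone whose initialization seed advances
    deterministically, so ensemble members differ in their random starts
    as well as in their bins while the whole sequence stays reproducible.

    The default featurizer uses unigram (k = n = 1) hashed counts with a
    small hash width: the synthetic renderer draws characters
    independently per position, making unigram frequencies the sufficient
    statistic of an entity's latent.
    """
    from .backbone import FeaturizerConfig, PairFeaturizer, ReferenceBackbone, TrainConfig

    if featurizer_config is None:
        featurizer_config = FeaturizerConfig(protein_k=1, smiles_n=1, hash_dim=64)
    if train_config is None:
        train_config = TrainConfig(
            learning_rate=1.0, weight_decay=1e-4, epochs=400,
            batch_size=32, hidden_units=64, seed=seed,
        )
    featurizer = PairFeaturizer(featurizer_config)
    counter = iter(range(10**9))

    def build(loss_config: LossConfig) -> Backbone:
        tc = TrainConfig(
            learning_rate=train_config.learning_rate,
            weight_decay=train_config.weight_decay,
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            hidden_units=train_config.hidden_units,
            seed=stage_seed(train_config.seed, next(counter)),
        )
        return ReferenceBackbone(
            train_config=tc, loss_config=loss_config, featurizer=featurizer
        )

    return build


def benchmark_world(
    world,
    seed: int,
    backbone_builder: Optional[Callable[[LossConfig], Backbone]] = None,
    binpu_config: BinPUConfig = BinPUConfig(K=10),
    lambda_wp: float = 1.0,
    positive_weight: float = 10.0,
    evaluate_final: bool = True,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> dict:
    """Run the full pipeline and the unlabeled-as-negative baseline on one
    synthetic world and score both against the generator's ground truth.

    The evaluation pool is the unlabeled cross product (every pair except
    the observed positives used for supervision), labeled by the world's
    true interaction matrix.  Both arms tune their discriminant threshold
    on their own validation data and are scored on the same pool, making
    the comparison paired.  K defaults to 10 here so each bin's negative
    pool stays a few times larger than the positive set at desk scale.
    Returns a flat dict of quantities: pseudo-positive precision/count,
    SCR, and (when ``evaluate_final``) the test F1 of both arms.
    """
    from .pu_core import generate_unlabeled  # local to avoid clutter above

    entities = EntityIndex(world.compounds, world.proteins)
    if backbone_builder is None:
        backbone_builder = make_reference_builder(seed)
    factory = lambda: backbone_builder(LossConfig(lambda_wp=lambda_wp))
    result = run_binpu(
        world.observed_positives,
        world.compounds,
        world.proteins,
        factory,
        seed,
        binpu_config,
    )
    truth = world.true_pair_keys()
    psi_pos_keys = [p.key for p in result.pseudo_labels.psi_pos]
    n_psi_pos = len(psi_pos_keys)
    n_psi_true = sum(1 for k in psi_pos_keys if k in truth)
    out = {
        "seed": seed,
        "n_pseudo_positive": n_psi_pos,
        "n_pseudo_negative": len(result.pseudo_labels.psi_neg),
        "pseudo_positive_true_hits": n_psi_true,
        "pseudo_positive_precision": (n_psi_true / n_psi_pos) if n_psi_pos else None,
        "scr": None if result.spy_report is None else result.spy_report.scr,
    }
    if not evaluate_final:
        return out

    # --- BIN-PU arm: final model on positives + pseudo labels -------------
    train, val, _ = aggregate_split(
        result.pseudo_labels,
        world.observed_positives,
        seed=stage_seed(seed, 10),
    )
    final = backbone_builder(LossConfig(lambda_wp=lambda_wp))
    final.fit(
        entities.rows(train.pairs),
        train.labels,
        truly_positive_mask=train.truly_positive_mask,
    )
    val_scores = np.asarray(final.predict_proba(entities.rows(val.pairs)))
    theta = optimize_threshold(val.labels, val_scores, theta_grid).best_theta

    # shared ground-truth evaluation pool: everything but observed positives
    unlabeled = generate_unlabeled(
        world.compounds, world.proteins, world.observed_positives
    )
    eval_pairs = list(unlabeled.pairs)
    eval_truth = np.array([1 if p.key in truth else 0 for p in eval_pairs])
    eval_rows = entities.rows(eval_pairs)
    binpu_scores = np.asarray(final.predict_proba(eval_rows))
    binpu_report = f1_score(
        eval_truth, (binpu_scores > theta).astype(int), threshold=theta
    )

    # --- baseline arm: all unlabeled as negative ---------------------------
    base_model, base_theta, _ = baseline_all_negative(
        world.observed_positives,
        unlabeled,
        factory,
        entities,
        positive_weight=positive_weight,
        seed=stage_seed(seed, 11),
        theta_grid=theta_grid,
    )
    base_scores = np.asarray(base_model.predict_proba(eval_rows))
    base_report = f1_score(
        eval_truth, (base_scores > base_theta).astype(int), threshold=base_theta
    )
    out.update(
        binpu_theta=theta,
        binpu_f1=binpu_report.f1,
        binpu_precision=binpu_report.precision,
        binpu_recall=binpu_report.recall,
        baseline_theta=base_theta,
        baseline_f1=base_report.f1,
        baseline_precision=base_report.precision,
        baseline_recall=base_report.recall,
        n_eval_pairs=len(eval_pairs),
        eval_prevalence=float(eval_truth.mean()),
    )
    return out
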