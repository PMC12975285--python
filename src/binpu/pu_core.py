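"""The bin-ensemble positive-unlabeled engine.

Given only known-positive compound-protein pairs, the engine

1. forms the unlabeled pool Du as the full compound x protein cross
   product minus the known positives;
2. hides a fraction of the positives as *spies* inside Du (they train as
   negatives but are known to be positive, giving a built-in yardstick);
3. randomly partitions Du into K near-equal bins; each bin, unioned with
   the remaining training positives Dp_tr, trains one classifier with the
   bin treated as negative;
4. averages the K posterior probabilities into a pseudo score Pr-bar per
   pair;
5. thresholds Pr-bar into pseudo-positives (Pr-bar > theta_u),
   pseudo-negatives (Pr-bar < theta_l) and a residual left unlabeled, and
   reports the spies capture rate SCR = N_TS / N_S, the fraction of spies
   the ensemble scores above a capture threshold.

Because each classifier sees only ~|Du|/K unlabeled pairs as negatives,
the contamination of hidden positives inside any single training set is
diluted, and averaging across bins smooths out bin-specific noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .backbone import BackboneFactory, Row
from .errors import (
    ConsistencyError,
    ContractViolationError,
    ParameterError,
    UndefinedMetricError,
)
from .records import (
    PSEUDO_NEGATIVE,
    PSEUDO_POSITIVE,
    POSITIVE,
    SPY,
    UNLABELED,
    CompoundRecord,
    InteractionPair,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]

# stage indices used to derive per-stage seeds from the master seed
_STAGE_SPLIT_SPIES = 1
_STAGE_PARTITION = 2
_STAGE_ENSEMBLE = 3

_SEED_MOD = 2**31


def stage_seed(master: int, stage_index: int) -> int:
    """Derive a per-stage seed so each stage is independently reproducible."""
    return (int(master) + stage_index) % _SEED_MOD


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositiveSet:
    """The curated truly-positive pairs Dp."""

    pairs: tuple[InteractionPair, ...]

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ConsistencyError("positive pairs must be distinct")
        for p in self.pairs:
            if p.label != POSITIVE:
                raise ConsistencyError(
                    f"pair {p.key} in a PositiveSet has label {p.label!r}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def keys(self) -> frozenset[PairKey]:
        return frozenset(p.key for p in self.pairs)


@dataclass(frozen=True)
class UnlabeledSet:
    """The unlabeled pool Du; spy rows are flagged with the spy label."""

    pairs: tuple[InteractionPair, ...]

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ConsistencyError("unlabeled pairs must be distinct")
        for p in self.pairs:
            if p.label not in (UNLABELED, SPY):
                raise ConsistencyError(
                    f"pair {p.key} in an UnlabeledSet has label {p.label!r}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def spy_keys(self) -> frozenset[PairKey]:
        return frozenset(p.key for p in self.pairs if p.label == SPY)


@dataclass(frozen=True)
class SpySplit:
    train_positives: PositiveSet
    spies: tuple[InteractionPair, ...]
    spy_fraction: float


@dataclass(frozen=True)
class BinAssignment:
    """Random K-way partition of the unlabeled pool; bins indexed 1..K."""

    K: int
    membership: dict[PairKey, int]
    pairs: tuple[InteractionPair, ...]

    def bin_members(self, k: int) -> list[InteractionPair]:
        return [p for p in self.pairs if self.membership[p.key] == k]


@dataclass(frozen=True)
class ScoreTable:
    """Per-pair ensemble mean posterior plus the raw per-bin scores."""

    mean: dict[PairKey, float]
    per_bin: dict[PairKey, tuple[tuple[int, float], ...]]
    pairs: tuple[InteractionPair, ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PseudoLabelConfig:
    """Thresholds turning ensemble scores into pseudo labels.

    In ``score`` mode theta_u / theta_l are absolute score cutoffs with
    strict inequalities; in ``percentile`` mode they are the top/bottom
    fractions (each in (0, 0.5]) of the non-spy pool taken as
    pseudo-positive / pseudo-negative.
    """

    theta_u: float = 0.8
    theta_l: float = 0.2
    mode: str = "score"

    def __post_init__(self) -> None:
        if self.mode not in ("score", "percentile"):
            raise ParameterError(f"unknown pseudo-label mode {self.mode!r}")
        if self.mode == "score":
            if not (0.0 <= self.theta_l < self.theta_u <= 1.0):
                raise ParameterError(
                    f"need 0 <= theta_l < theta_u <= 1, got "
                    f"theta_l={self.theta_l}, theta_u={self.theta_u}"
                )
        else:
            for name, frac in (("theta_u", self.theta_u), ("theta_l", self.theta_l)):
                if not (0.0 < frac <= 0.5):
                    raise ParameterError(
                        f"percentile-mode {name} must be in (0, 0.5], got {frac}"
                    )


@dataclass(frozen=True)
class PseudoLabelSet:
    psi_pos: tuple[InteractionPair, ...]
    psi_neg: tuple[InteractionPair, ...]
    residual: tuple[InteractionPair, ...]

    def __len__(self) -> int:
        return len(self.psi_pos) + len(self.psi_neg) + len(self.residual)


@dataclass(frozen=True)
class SpyReport:
    n_spies: int
    n_captured: int
    scr: float
    capture_threshold: float


@dataclass(frozen=True)
class BinPUConfig:
    """All tunables of one pseudo-labeling run."""

    K: int = 20
    spy_fraction: float = 0.2
    pseudo: PseudoLabelConfig = field(default_factory=PseudoLabelConfig)
    scr_threshold: float = 0.5
    score_scope: str = "all"  # or "held-out"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError(f"K must be >= 1, got {self.K}")
        if not (0.0 <= self.spy_fraction < 1.0):
            raise ParameterError(
                f"spy_fraction must be in [0, 1), got {self.spy_fraction}"
            )
        if self.score_scope not in ("all", "held-out"):
            raise ParameterError(f"unknown score_scope {self.score_scope!r}")


@dataclass(frozen=True)
class BinPUResult:
    pseudo_labels: PseudoLabelSet
    spy_report: Optional[SpyReport]
    scores: ScoreTable
    manifest: dict

    def __iter__(self):
        return iter((self.pseudo_labels, self.spy_report, self.scores))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

class EntityIndex:
    """id -> string lookups resolving pairs into backbone rows."""

    def __init__(
        self,
        compounds: Sequence[CompoundRecord],
        proteins: Sequence[ProteinRecord],
    ) -> None:
        self.smiles = {c.compound_id: c.smiles for c in compounds}
        self.sequence = {p.protein_id: p.sequence for p in proteins}

    def row(self, pair: InteractionPair) -> Row:
        try:
            return (self.smiles[pair.compound_id], self.sequence[pair.protein_id])
        except KeyError as exc:
            raise ConsistencyError(f"pair {pair.key} references unknown entity {exc}")

    def rows(self, pairs: Sequence[InteractionPair]) -> list[Row]:
        return [self.row(p) for p in pairs]


def generate_unlabeled(
    compounds: Sequence[CompoundRecord],
    proteins: Sequence[ProteinRecord],
    positives: PositiveSet,
) -> UnlabeledSet:
    """All cross-product pairs minus the known positives, in lexicographic
    (compound_id, protein_id) order."""
    if not compounds or not proteins:
        raise ParameterError("need at least one compound and one protein")
    cids = sorted(c.compound_id for c in compounds)
    pids = sorted(p.protein_id for p in proteins)
    if len(set(cids)) != len(cids) or len(set(pids)) != len(pids):
        raise ConsistencyError("entity ids must be unique")
    known = positives.keys
    for key in known:
        if key[0] not in set(cids) or key[1] not in set(pids):
            raise ConsistencyError(
                f"positive pair {key} references an unknown entity"
            )
    pairs = tuple(
        InteractionPair(cid, pid, label=UNLABELED)
        for cid in cids
        for pid in pids
        if (cid, pid) not in known
    )
    return UnlabeledSet(pairs)


def split_spies(positives: PositiveSet, spy_fraction: float, seed: int) -> SpySplit:
    """Hold out round(fraction * |Dp|) positives as spies, uniformly at random."""
    if not (0.0 <= spy_fraction < 1.0):
        raise ParameterError(f"spy_fraction must be in [0, 1), got {spy_fraction}")
    n = len(positives)
    n_spies = int(round(spy_fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    spy_idx = set(idx[:n_spies].tolist())
    spies = tuple(
        positives.pairs[i].with_label(SPY) for i in sorted(spy_idx)
    )
    train = tuple(p for i, p in enumerate(positives.pairs) if i not in spy_idx)
    return SpySplit(PositiveSet(train), spies, spy_fraction)


def inject_spies(
    unlabeled: UnlabeledSet, spies: Sequence[InteractionPair]
) -> UnlabeledSet:
    """Add the spy pairs to the unlabeled pool, keeping their spy flag.

    The flag is bookkeeping only: bin training serializes every member of
    the pool as a negative, spies included.
    """
    existing = {p.key for p in unlabeled.pairs}
    overlap = [s.key for s in spies if s.key in existing]
    if overlap:
        raise ConsistencyError(f"spies overlap the unlabeled pool: {overlap[:3]}")
    flagged = tuple(s.with_label(SPY) for s in spies)
    return UnlabeledSet(unlabeled.pairs + flagged)


def partition_bins(unlabeled: UnlabeledSet, K: int, seed: int) -> BinAssignment:
    """Uniform random partition of the pool into K bins of near-equal size."""
    n = len(unlabeled)
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    if K > n:
        raise ParameterError(f"K={K} exceeds the pool size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # the first (n mod K) bins get one extra member
    base, extra = divmod(n, K)
    membership: dict[PairKey, int] = {}
    pos = 0
    for k in range(1, K + 1):
        size = base + (1 if k <= extra else 0)
        for i in order[pos : pos + size]:
            membership[unlabeled.pairs[i].key] = k
        pos += size
    return BinAssignment(K=K, membership=membership, pairs=unlabeled.pairs)


def build_bin_training_set(
    bin_members: Sequence[InteractionPair], train_positives: PositiveSet
) -> tuple[list[InteractionPair], np.ndarray]:
    """One bin's training table D_k = Dp_tr (label 1) + bin members (label 0).

    The *entire* training-positive set enters every bin; the bin's
    unlabeled members (spies included) are treated as negatives.
    """
    bin_keys = {p.key for p in bin_members}
    overlap = bin_keys & train_positives.keys
    if overlap:
        raise ConsistencyError(
            f"bin members overlap the training positives: {sorted(overlap)[:3]}"
        )
    rows = list(train_positives.pairs) + list(bin_members)
    labels = np.concatenate(
        [np.ones(len(train_positives)), np.zeros(len(bin_members))]
    )
    return rows, labels


def score_ensemble(
    bins: BinAssignment,
    train_positives: PositiveSet,
    backbone_factory: BackboneFactory,
    entities: EntityIndex,
    seed: int,
    score_scope: str = "all",
) -> ScoreTable:
    """Train one backbone per bin and average posteriors into Pr-bar.

    Under ``score_scope="all"`` every bin's model scores the whole pool,
    so each pair collects K scores.  Under ``"held-out"`` a model never
    scores its own bin's members (its training negatives), leaving K-1
    scores per pair.
    """
    if score_scope not in ("all", "held-out"):
        raise ParameterError(f"unknown score_scope {score_scope!r}")
    pool = bins.pairs
    pool_rows = entities.rows(pool)
    per_bin: dict[PairKey, list[tuple[int, float]]] = {p.key: [] for p in pool}
    for k in range(1, bins.K + 1):
        members = bins.bin_members(k)
        train_pairs, labels = build_bin_training_set(members, train_positives)
        model = backbone_factory()
        mask = labels == 1.0
        model.fit(
            entities.rows(train_pairs),
            labels,
            truly_positive_mask=mask,
        )
        scores = np.asarray(model.predict_proba(pool_rows), dtype=float)
        if ((scores < 0) | (scores > 1)).any() or np.isnan(scores).any():
            raise ContractViolationError(
                f"bin {k}: backbone produced scores outside [0, 1]"
            )
        member_keys = {p.key for p in members}
        for pair, s in zip(pool, scores):
            if score_scope == "held-out" and pair.key in member_keys:
                continue
            per_bin[pair.key].append((k, float(s)))
        logger.debug("bin %d/%d scored (%d training rows)", k, bins.K, len(train_pairs))
    mean = {}
    for key, entries in per_bin.items():
        if not entries:
            raise ConsistencyError(f"pair {key} collected no scores")
        mean[key] = float(np.mean([s for _, s in entries]))
    return ScoreTable(
        mean=mean,
        per_bin={k: tuple(v) for k, v in per_bin.items()},
        pairs=pool,
    )


def assign_pseudo_labels(
    scores: ScoreTable, config: PseudoLabelConfig
) -> PseudoLabelSet:
    """Partition the scored non-spy pairs into psi_pos / psi_neg / residual.

    Score mode uses strict inequalities (Pr-bar > theta_u, < theta_l);
    percentile mode takes the top/bottom fractions of the non-spy pool,
    breaking score ties by the lexicographic pair order.  Spies are never
    emitted.
    """
    non_spy = [p for p in scores.pairs if p.label != SPY]
    pos: list[InteractionPair] = []
    neg: list[InteractionPair] = []
    res: list[InteractionPair] = []
    if config.mode == "score":
        for p in non_spy:
            s = scores.mean[p.key]
            scored = p.with_score(s)
            if s > config.theta_u:
                pos.append(scored.with_label(PSEUDO_POSITIVE))
            elif s < config.theta_l:
                neg.append(scored.with_label(PSEUDO_NEGATIVE))
            else:
                res.append(scored)
    else:
        ranked = sorted(non_spy, key=lambda p: (scores.mean[p.key], p.key))
        n = len(ranked)
        n_pos = int(config.theta_u * n)
        n_neg = int(config.theta_l * n)
        neg_set = ranked[:n_neg]
        pos_set = ranked[n - n_pos :] if n_pos else []
        mid = ranked[n_neg : n - n_pos] if n_pos else ranked[n_neg:]
        pos = [p.with_score(scores.mean[p.key]).with_label(PSEUDO_POSITIVE) for p in pos_set]
        neg = [p.with_score(scores.mean[p.key]).with_label(PSEUDO_NEGATIVE) for p in neg_set]
        res = [p.with_score(scores.mean[p.key]) for p in mid]
    return PseudoLabelSet(tuple(pos), tuple(neg), tuple(res))


def compute_scr(
    scores: ScoreTable,
    spies: Sequence[InteractionPair],
    capture_threshold: float = 0.5,
) -> SpyReport:
    """Spies capture rate: the fraction of spies with Pr-bar above the
    capture threshold (strict inequality)."""
    if not spies:
        raise UndefinedMetricError("SCR is undefined with zero spies")
    missing = [s.key for s in spies if s.key not in scores.mean]
    if missing:
        raise ConsistencyError(f"unscored spies: {missing[:3]}")
    n_captured = sum(
        1 for s in spies if scores.mean[s.key] > capture_threshold
    )
    return SpyReport(
        n_spies=len(spies),
        n_captured=n_captured,
        scr=n_captured / len(spies),
        capture_threshold=capture_threshold,
    )


def run_binpu(
    positives: PositiveSet,
    compounds: Sequence[CompoundRecord],
    proteins: Sequence[ProteinRecord],
    backbone_factory: BackboneFactory,
    seed: int,
    config: BinPUConfig = BinPUConfig(),
) -> BinPUResult:
    """Run the full pseudo-labeling pipeline and return labels, the spy
    report (None when spy_fraction is 0) and the score table.

    Stage seeds are derived from the master seed, so a fixed seed gives
    identical outputs end to end.
    """
    entities = EntityIndex(compounds, proteins)
    unlabeled = generate_unlabeled(compounds, proteins, positives)
    logger.info("unlabeled pool: %d pairs", len(unlabeled))

    split = split_spies(
        positives, config.spy_fraction, stage_seed(seed, _STAGE_SPLIT_SPIES)
    )
    logger.info(
        "spy split: %d training positives, %d spies",
        len(split.train_positives), len(split.spies),
    )
    pool = inject_spies(unlabeled, split.spies)
    bins = partition_bins(pool, config.K, stage_seed(seed, _STAGE_PARTITION))
    logger.info("partitioned %d pairs into %d bins", len(pool), bins.K)

    scores = score_ensemble(
        bins,
        split.train_positives,
        backbone_factory,
        entities,
        stage_seed(seed, _STAGE_ENSEMBLE),
        score_scope=config.score_scope,
    )
    spy_report = (
        compute_scr(scores, split.spies, config.scr_threshold)
        if split.spies
        else None
    )
    if spy_report is not None:
        logger.info(
            "SCR = %.3f (%d/%d spies above %.2f)",
            spy_report.scr, spy_report.n_captured,
            spy_report.n_spies, spy_report.capture_threshold,
        )
    pseudo = assign_pseudo_labels(scores, config.pseudo)
    logger.info(
        "pseudo labels: %d positive, %d negative, %d residual",
        len(pseudo.psi_pos), len(pseudo.psi_neg), len(pseudo.residual),
    )
    manifest = {
        "seed": seed,
        "K": config.K,
        "spy_fraction": config.spy_fraction,
        "theta_u": config.pseudo.theta_u,
        "theta_l": config.pseudo.theta_l,
        "mode": config.pseudo.mode,
        "score_scope": config.score_scope,
        "scr_threshold": config.scr_threshold,
        "n_compounds": len(compounds),
        "n_proteins": len(proteins),
        "n_positives": len(positives),
        "n_unlabeled": len(unlabeled),
        "n_spies": len(split.spies),
        "n_pool": len(pool),
        "n_pseudo_positive": len(pseudo.psi_pos),
        "n_pseudo_negative": len(pseudo.psi_neg),
        "n_residual": len(pseudo.residual),
        "scr": None if spy_report is None else spy_report.scr,
    }
    return BinPUResult(pseudo, spy_report, scores, manifest)
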