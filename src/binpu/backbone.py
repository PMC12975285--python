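"""Pluggable classifier contract and the reference backbone.

The bin-ensemble framework is backbone-agnostic: any object exposing
``fit(rows, labels, ...)`` and ``predict_proba(rows) -> probabilities``
can score compound-protein pairs inside bins.  Rows are ``(smiles,
sequence)`` string tuples, so deep encoders can be plugged in without
touching the pipeline.

The reference backbone shipped here is deliberately cheap: overlapping
protein k-mers and SMILES character n-grams are signed-hashed into
fixed-width count vectors (feature hashing a la Weinberger), the two
vectors are L2-normalized and concatenated, and a single-hidden-layer
feedforward network is trained on the composite loss with plain
mini-batch gradient descent and decoupled weight decay.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import (
    ContractViolationError,
    DegenerateTrainingError,
    FeaturizationError,
    NotFittedError,
    ParameterError,
)
from .losses import LossConfig, composite_loss, loss_gradient

Row = tuple[str, str]  # (smiles, sequence)


@runtime_checkable
class Backbone(Protocol):
    """Structural contract for any pluggable CPI classifier f(.)."""

    def fit(
        self,
        rows: Sequence[Row],
        labels: Sequence[int],
        truly_positive_mask: Optional[Sequence[bool]] = None,
        sample_weight: Optional[Sequence[float]] = None,
    ) -> "Backbone": ...

    def predict_proba(self, rows: Sequence[Row]) -> np.ndarray: ...


BackboneFactory = Callable[[], Backbone]


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeaturizerConfig:
    protein_k: int = 3
    smiles_n: int = 3
    hash_dim: int = 1024
    hash_seed: int = 17

    def __post_init__(self) -> None:
        if self.protein_k < 1 or self.smiles_n < 1:
            raise ParameterError("k-mer / n-gram lengths must be >= 1")
        if self.hash_dim < 16:
            raise ParameterError("hash_dim must be >= 16")


def _hash_token(token: str, seed: int) -> tuple[int, int]:
    """Stable (bucket-source, sign) pair for a token under a seed."""
    digest = hashlib.blake2b(
        token.encode(), key=str(seed).encode(), digest_size=8
    ).digest()
    value = int.from_bytes(digest, "little")
    return value >> 1, 1 - 2 * (value & 1)


def _hashed_grams(text: str, length: int, dim: int, seed: int, namespace: str) -> np.ndarray:
    if len(text) < length:
        raise FeaturizationError(
            f"{namespace} string of length {len(text)} is shorter than {length}"
        )
    vec = np.zeros(dim)
    for i in range(len(text) - length + 1):
        bucket, sign = _hash_token(namespace + ":" + text[i : i + length], seed)
        vec[bucket % dim] += sign
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def featurize_protein(sequence: str, config: FeaturizerConfig = FeaturizerConfig()) -> np.ndarray:
    """Signed-hashed, L2-normalized overlapping k-mer counts of a sequence."""
    return _hashed_grams(sequence, config.protein_k, config.hash_dim, config.hash_seed, "prot")


def featurize_compound(smiles: str, config: FeaturizerConfig = FeaturizerConfig()) -> np.ndarray:
    """Signed-hashed, L2-normalized overlapping character n-grams of a SMILES."""
    if not smiles.strip():
        raise FeaturizationError("empty SMILES")
    return _hashed_grams(smiles, config.smiles_n, config.hash_dim, config.hash_seed, "smi")


def hash_collision_rate(tokens: Sequence[str], config: FeaturizerConfig = FeaturizerConfig()) -> float:
    """Fraction of distinct tokens sharing a bucket with another token."""
    buckets: dict[int, int] = {}
    for tok in set(tokens):
        b, _ = _hash_token(tok, config.hash_seed)
        buckets[b % config.hash_dim] = buckets.get(b % config.hash_dim, 0) + 1
    n = len(set(tokens))
    if n == 0:
        return 0.0
    collided = sum(c for c in buckets.values() if c > 1)
    return collided / n


class PairFeaturizer:
    """Concatenated protein+compound hashed features with per-entity caching."""

    def __init__(self, config: FeaturizerConfig = FeaturizerConfig()) -> None:
        self.config = config
        self._prot_cache: dict[str, np.ndarray] = {}
        self._comp_cache: dict[str, np.ndarray] = {}

    @property
    def dim(self) -> int:
        return 2 * self.config.hash_dim

    def transform(self, rows: Sequence[Row]) -> np.ndarray:
        out = np.empty((len(rows), self.dim))
        for i, (smiles, sequence) in enumerate(rows):
            comp = self._comp_cache.get(smiles)
            if comp is None:
                comp = featurize_compound(smiles, self.config)
                self._comp_cache[smiles] = comp
            prot = self._prot_cache.get(sequence)
            if prot is None:
                prot = featurize_protein(sequence, self.config)
                self._prot_cache[sequence] = prot
            out[i, : self.config.hash_dim] = comp
            out[i, self.config.hash_dim :] = prot
        return out


# ---------------------------------------------------------------------------
# reference backbone
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the reference backbone's gradient-descent fit."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 200
    batch_size: int = 32
    hidden_units: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay <= 0:
            raise ParameterError("learning_rate and weight_decay must be > 0")
        if self.epochs < 1 or self.batch_size < 1 or self.hidden_units < 1:
            raise ParameterError("epochs, batch_size and hidden_units must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ReferenceBackbone:
    """Single-hidden-layer feedforward classifier on hashed pair features.

    Trained by mini-batch gradient descent on the composite loss
    (BCE + lambda * weighted-positive term), with decoupled weight decay
    applied to the weight matrices.  The per-epoch mean training loss is
    recorded in ``loss_curve_``.
    """

    def __init__(
        self,
        featurizer_config: FeaturizerConfig = FeaturizerConfig(),
        train_config: TrainConfig = TrainConfig(),
        loss_config: LossConfig = LossConfig(),
        featurizer: Optional[PairFeaturizer] = None,
    ) -> None:
        self.featurizer = featurizer or PairFeaturizer(featurizer_config)
        self.train_config = train_config
        self.loss_config = loss_config
        self._params: Optional[dict[str, np.ndarray]] = None
        self.loss_curve_: list[float] = []

    # -- training ----------------------------------------------------------

    def fit(
        self,
        rows: Sequence[Row],
        labels: Sequence[int],
        truly_positive_mask: Optional[Sequence[bool]] = None,
        sample_weight: Optional[Sequence[float]] = None,
    ) -> "ReferenceBackbone":
        y = np.asarray(labels, dtype=float).ravel()
        if len(rows) != y.size:
            raise ParameterError("rows and labels length mismatch")
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateTrainingError(
                "training data contains a single class; need >= 1 positive "
                "and >= 1 negative row"
            )
        mask = (
            np.zeros(y.size, dtype=bool)
            if truly_positive_mask is None
            else np.asarray(truly_positive_mask, dtype=bool).ravel()
        )
        weight = (
            None if sample_weight is None else np.asarray(sample_weight, dtype=float).ravel()
        )
        X = self.featurizer.transform(rows)
        tc = self.train_config
        rng = np.random.default_rng(tc.seed)
        d, h = X.shape[1], tc.hidden_units
        params = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h)),
            "b1": np.zeros(h),
            "w2": rng.normal(0.0, 1.0 / np.sqrt(h), size=h),
            "b2": np.zeros(1),
        }
        self.loss_curve_ = []
        n = X.shape[0]
        for _ in range(tc.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                Xb, yb, mb = X[idx], y[idx], mask[idx]
                wb = None if weight is None else weight[idx]
                hid = np.tanh(Xb @ params["W1"] + params["b1"])
                yhat = _sigmoid(hid @ params["w2"] + params["b2"][0])
                breakdown = composite_loss(yb, yhat, mb, self.loss_config, sample_weight=wb)
                epoch_loss += breakdown.total * idx.size
                dL_dyhat = loss_gradient(yb, yhat, mb, self.loss_config, sample_weight=wb)
                dz2 = dL_dyhat * yhat * (1.0 - yhat)
                gw2 = hid.T @ dz2
                gb2 = dz2.sum()
                dhid = np.outer(dz2, params["w2"]) * (1.0 - hid**2)
                gW1 = Xb.T @ dhid
                gb1 = dhid.sum(axis=0)
                lr = tc.learning_rate
                params["w2"] -= lr * (gw2 + tc.weight_decay * params["w2"])
                params["b2"] -= lr * gb2
                params["W1"] -= lr * (gW1 + tc.weight_decay * params["W1"])
                params["b1"] -= lr * gb1
            self.loss_curve_.append(epoch_loss / n)
        self._params = params
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, rows: Sequence[Row]) -> np.ndarray:
        if self._params is None:
            raise NotFittedError("backbone has not been fitted")
        X = self.featurizer.transform(rows)
        hid = np.tanh(X @ self._params["W1"] + self._params["b1"])
        return _sigmoid(hid @ self._params["w2"] + self._params["b2"][0])

    # -- persistence -------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path: str) -> None:
        """Serialize weights + manifest as a flat .npz with a version stamp."""
        if self._params is None:
            raise NotFittedError("cannot save an unfitted backbone")
        fc, tc = self.featurizer.config, self.train_config
        np.savez(
            path,
            format_version=np.array([self.FORMAT_VERSION]),
            manifest=np.array(
                [
                    fc.protein_k, fc.smiles_n, fc.hash_dim, fc.hash_seed,
                    tc.hidden_units, tc.seed,
                ]
            ),
            **self._params,
        )

    @classmethod
    def load(cls, path: str) -> "ReferenceBackbone":
        data = np.load(path)
        version = int(data["format_version"][0])
        if version != cls.FORMAT_VERSION:
            raise ParameterError(f"unsupported model format version {version}")
        pk, sn, hd, hs, hu, seed = (int(v) for v in data["manifest"])
        model = cls(
            featurizer_config=FeaturizerConfig(pk, sn, hd, hs),
            train_config=TrainConfig(hidden_units=hu, seed=seed),
        )
        params = {k: data[k] for k in ("W1", "b1", "w2", "b2")}
        if params["W1"].shape != (2 * hd, hu):
            raise ParameterError("weight shapes inconsistent with manifest")
        model._params = params
        return model


# ---------------------------------------------------------------------------
# deterministic stubs (useful for pipeline tests and brute-force oracles)
# ---------------------------------------------------------------------------

class ConstantBackbone:
    """Ignores training and scores every row with a fixed constant."""

    def __init__(self, value: float = 0.5) -> None:
        self.value = value

    def fit(self, rows, labels, truly_positive_mask=None, sample_weight=None):
        return self

    def predict_proba(self, rows) -> np.ndarray:
        return np.full(len(rows), self.value)


class RuleBackbone:
    """Scores each (smiles, sequence) row with a user-supplied function."""

    def __init__(self, rule: Callable[[str, str], float]) -> None:
        self.rule = rule

    def fit(self, rows, labels, truly_positive_mask=None, sample_weight=None):
        return self

    def predict_proba(self, rows) -> np.ndarray:
        return np.array([float(self.rule(s, q)) for s, q in rows])


# ---------------------------------------------------------------------------
# contract conformance
# ---------------------------------------------------------------------------

def check_backbone_contract(
    factory: BackboneFactory,
    rows: Sequence[Row],
    labels: Sequence[int],
) -> dict[str, bool]:
    """Validate any backbone implementation against the f(.) contract.

    Checks: probabilities in [0, 1]; predict_proba deterministic after
    fit; row independence (permuting inputs permutes outputs); fresh
    instances from the factory are independent objects.  Raises
    :class:`ContractViolationError` on the first failure, otherwise
    returns the per-check record.
    """
    model = factory().fit(rows, labels)
    scores = np.asarray(model.predict_proba(rows), dtype=float)
    if scores.shape != (len(rows),):
        raise ContractViolationError("predict_proba must return one score per row")
    if ((scores < 0) | (scores > 1)).any():
        raise ContractViolationError("scores outside [0, 1]")
    if not np.array_equal(scores, np.asarray(model.predict_proba(rows), dtype=float)):
        raise ContractViolationError("predict_proba is not deterministic after fit")
    perm = list(range(len(rows)))[::-1]
    permuted = np.asarray(model.predict_proba([rows[i] for i in perm]), dtype=float)
    if not np.allclose(permuted, scores[perm]):
        raise ContractViolationError("rows are not scored independently")
    if factory() is model:
        raise ContractViolationError("factory must return fresh instances")
    return {
        "range": True,
        "deterministic": True,
        "row_independent": True,
        "fresh_instances": True,
    }
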