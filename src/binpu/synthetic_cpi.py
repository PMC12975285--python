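"""Synthetic compound-protein worlds with known ground truth.

A world draws a latent factor vector for every protein and compound from
a standard spherical normal.  The propensity of pair (c, p) to interact
is logistic(a * <z_c, z_p> + b): the signal strength ``a`` scales how
strongly aligned latents drive interaction, and the bias ``b`` is
calibrated so the prevalence of true positives matches ``positive_rate``.
True labels are the thresholded propensities by default (propensity >
0.5), or Bernoulli draws when ``stochastic_labels`` is set — required
when a = 0, where thresholding cannot produce an intermediate
prevalence.

Entities are then *rendered* into strings: each protein's residues are
drawn position-wise from a softmax over a fixed random projection of its
latent, so hashed k-mer counts of the rendered sequence carry a
recoverable trace of the latent; compounds are rendered the same way
over a 12-character SMILES-like alphabet.  The rendered strings are
syntactically plausible, not chemically valid — the pipeline treats them
as opaque tokens.

Only a fraction of the true positives is revealed as labeled positives
(``observed_fraction``), reproducing the positive-unlabeled setting: the
rest hide inside the unlabeled cross product.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass


import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import io_formats
from .errors import CalibrationError, ParameterError
from .pu_core import PositiveSet
from .records import CompoundRecord, InteractionPair, ProteinRecord

PROTEIN_RENDER_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SMILES_RENDER_ALPHABET = "CNOcno=#12()"

_BIAS_TOL = 1e-4


@dataclass(frozen=True)
class WorldConfig:
    """Shape and signal of one synthetic world.

    Defaults describe a desk-scale strong-signal world: 50 proteins x 40
    compounds, 10% true-interaction prevalence, 30% of true positives
    revealed as labels.
    """

    n_proteins: int = 50
    n_compounds: int = 40
    latent_dim: int = 2
    signal_strength: float = 5.0
    positive_rate: float = 0.1
    observed_fraction: float = 0.3
    sequence_length: int = 600
    smiles_length: int = 100
    stochastic_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_compounds < 1:
            raise ParameterError("need at least one protein and one compound")
        if self.latent_dim < 1:
            raise ParameterError("latent_dim must be >= 1")
        if self.signal_strength < 0:
            raise ParameterError("signal_strength must be >= 0")
        if not (0.0 < self.positive_rate < 1.0):
            raise ParameterError("positive_rate must be in (0, 1)")
        if not (0.0 < self.observed_fraction <= 1.0):
            raise ParameterError("observed_fraction must be in (0, 1]")
        if self.sequence_length < 1 or self.smiles_length < 1:
            raise ParameterError("rendered string lengths must be >= 1")


@dataclass(frozen=True)
class SyntheticWorld:
    config: WorldConfig
    compounds: tuple[CompoundRecord, ...]
    proteins: tuple[ProteinRecord, ...]
    compound_latents: np.ndarray  # (n_compounds, d)
    protein_latents: np.ndarray  # (n_proteins, d)
    propensity: np.ndarray  # (n_compounds, n_proteins)
    true_labels: np.ndarray  # bool, (n_compounds, n_proteins)
    observed_positives: PositiveSet
    bias: float

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def true_pair_keys(self) -> set[tuple[str, str]]:
        cids, pids = self.compound_ids, self.protein_ids
        ci, pi = np.nonzero(self.true_labels)
        return {(cids[i], pids[j]) for i, j in zip(ci, pi)}


def _calibrate_bias(scores: np.ndarray, rate: float, stochastic: bool) -> float:
    """Bias b such that the world's prevalence matches ``rate``.

    Stochastic labels: solve mean(expit(scores + b)) = rate by bisection
    to within 1e-4.  Deterministic labels: place b so that exactly
    round(rate * n) pairs have propensity > 0.5.
    """
    flat = scores.ravel()
    n = flat.size
    if stochastic:
        def gap(b: float) -> float:
            return float(expit(flat + b).mean()) - rate

        lo, hi = -50.0, 50.0
        if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - defensive
            raise CalibrationError("target prevalence unreachable by bias shift")
        return float(brentq(gap, lo, hi, xtol=_BIAS_TOL))
    if np.ptp(flat) == 0.0:
        raise CalibrationError(
            "deterministic labels need score spread; with signal_strength=0 "
            "every propensity is identical, so no bias attains the target "
            "prevalence — use stochastic_labels=True"
        )
    m = int(round(rate * n))
    if m < 1 or m >= n:
        raise CalibrationError(
            f"positive_rate={rate} rounds to {m} positives out of {n}"
        )
    ordered = np.sort(flat)[::-1]
    # propensity > 0.5  <=>  score + b > 0; split between ranks m and m+1
    return float(-(ordered[m - 1] + ordered[m]) / 2.0)


def render_string(
    latent: np.ndarray,
    projection: np.ndarray,
    alphabet: str,
    length: int,
    rng: np.random.Generator,
) -> str:
    """Draw a string position-wise from softmax(projection @ latent)."""
    logits = projection @ latent
    logits = logits - logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    idx = rng.choice(len(alphabet), size=length, p=probs)
    return "".join(alphabet[i] for i in idx)


def render_entities(
    protein_latents: np.ndarray,
    compound_latents: np.ndarray,
    config: WorldConfig,
) -> tuple[tuple[ProteinRecord, ...], tuple[CompoundRecord, ...]]:
    """Render latents into protein sequences and SMILES-like strings.

    Projection matrices and the rendering stream derive from the world
    seed, so rendering is deterministic given the latents and config.
    """
    rng = np.random.default_rng((config.seed, 1))
    d = config.latent_dim
    proj_prot = rng.normal(size=(len(PROTEIN_RENDER_ALPHABET), d))
    proj_comp = rng.normal(size=(len(SMILES_RENDER_ALPHABET), d))
    width_p = len(str(protein_latents.shape[0]))
    width_c = len(str(compound_latents.shape[0]))
    proteins = tuple(
        ProteinRecord(
            f"p{i + 1:0{width_p}d}",
            render_string(
                protein_latents[i], proj_prot, PROTEIN_RENDER_ALPHABET,
                config.sequence_length, rng,
            ),
        )
        for i in range(protein_latents.shape[0])
    )
    compounds = tuple(
        CompoundRecord(
            f"c{i + 1:0{width_c}d}",
            render_string(
                compound_latents[i], proj_comp, SMILES_RENDER_ALPHABET,
                config.smiles_length, rng,
            ),
        )
        for i in range(compound_latents.shape[0])
    )
    return proteins, compounds


def generate_world(config: WorldConfig = WorldConfig()) -> SyntheticWorld:
    """Sample a complete world: latents, truth, rendered entities and the
    observed (labeled) positives."""
    rng = np.random.default_rng((config.seed, 0))
    zp = rng.normal(size=(config.n_proteins, config.latent_dim))
    zc = rng.normal(size=(config.n_compounds, config.latent_dim))
    scores = config.signal_strength * (zc @ zp.T)
    bias = _calibrate_bias(scores, config.positive_rate, config.stochastic_labels)
    propensity = expit(scores + bias)
    if config.stochastic_labels:
        truth = rng.random(propensity.shape) < propensity
    else:
        truth = propensity > 0.5
    proteins, compounds = render_entities(zp, zc, config)

    ci, pi = np.nonzero(truth)
    n_true = ci.size
    if n_true == 0:
        raise CalibrationError("world contains no true positives")
    n_obs = int(round(config.observed_fraction * n_true))
    n_obs = max(n_obs, 1)
    pick = rng.permutation(n_true)[:n_obs]
    observed = PositiveSet(
        tuple(
            InteractionPair(
                compounds[ci[t]].compound_id, proteins[pi[t]].protein_id
            )
            for t in sorted(pick.tolist())
        )
    )
    return SyntheticWorld(
        config=config,
        compounds=compounds,
        proteins=proteins,
        compound_latents=zc,
        protein_latents=zp,
        propensity=propensity,
        true_labels=truth,
        observed_positives=observed,
        bias=bias,
    )


def world_to_files(world: SyntheticWorld, directory: str | os.PathLike) -> dict[str, str]:
    """Write interactions.tsv, proteins.fasta, compounds.smi, truth.tsv and
    world_manifest.json; only observed positives appear as labeled rows."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        name: os.path.join(directory, name)
        for name in (
            "interactions.tsv", "proteins.fasta", "compounds.smi",
            "truth.tsv", "world_manifest.json",
        )
    }
    smiles = {c.compound_id: c.smiles for c in world.compounds}
    seqs = {p.protein_id: p.sequence for p in world.proteins}
    with open(paths["interactions.tsv"], "w") as fh:
        fh.write("compound_id\tsmiles\tprotein_id\tsequence\tlabel\n")
        for pair in world.observed_positives.pairs:
            fh.write(
                f"{pair.compound_id}\t{smiles[pair.compound_id]}\t"
                f"{pair.protein_id}\t{seqs[pair.protein_id]}\tpositive\n"
            )
    with open(paths["proteins.fasta"], "w") as fh:
        for p in world.proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    with open(paths["compounds.smi"], "w") as fh:
        for c in world.compounds:
            fh.write(f"{c.smiles} {c.compound_id}\n")
    with open(paths["truth.tsv"], "w") as fh:
        fh.write("compound_id\tprotein_id\tlabel\n")
        for i, cid in enumerate(world.compound_ids):
            for j, pid in enumerate(world.protein_ids):
                fh.write(f"{cid}\t{pid}\t{int(world.true_labels[i, j])}\n")
    manifest = dict(asdict(world.config))
    manifest.update(
        bias=world.bias,
        n_true_positives=int(world.true_labels.sum()),
        n_observed_positives=len(world.observed_positives),
    )
    io_formats.write_json_report(manifest, paths["world_manifest.json"])
    return paths


def read_truth_table(path: str | os.PathLike) -> dict[tuple[str, str], int]:
    """Read a truth.tsv back into a pair -> {0, 1} map (evaluation only)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "protein_id": str})
    return {
        (row.compound_id, row.protein_id): int(row.label)
        for row in df.itertuples()
    }
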