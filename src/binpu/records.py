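"""Domain records: compounds, proteins and interaction pairs.

A compound is an opaque identifier plus a SMILES string; a protein is an
identifier plus an amino-acid sequence.  An interaction pair links one of
each and carries a label from :data:`LABELS` and, once scored, the
ensemble posterior.  SMILES are treated as opaque tokens throughout — no
chemistry engine is required — while sequences are restricted to the
twenty standard residues plus ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

from .errors import FormatError

# canonical label vocabulary
POSITIVE = "positive"
UNLABELED = "unlabeled"
SPY = "spy"
PSEUDO_POSITIVE = "pseudo_positive"
PSEUDO_NEGATIVE = "pseudo_negative"

LABELS = frozenset({POSITIVE, UNLABELED, SPY, PSEUDO_POSITIVE, PSEUDO_NEGATIVE})

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class CompoundRecord:
    """A compound identified by an opaque id and a raw SMILES string."""

    compound_id: str
    smiles: str

    def __post_init__(self) -> None:
        smiles = self.smiles.strip()
        if not smiles:
            raise FormatError(f"compound {self.compound_id!r}: empty SMILES")
        object.__setattr__(self, "smiles", smiles)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by an opaque id and an amino-acid sequence.

    The sequence is upper-cased on construction.  Characters outside the
    20-letter alphabet plus ``X`` are reported through a warning but the
    record is kept: silently dropping data is worse than a noisy read.
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        if not seq:
            raise FormatError(f"protein {self.protein_id!r}: empty sequence")
        bad = sorted(set(seq) - PROTEIN_ALPHABET)
        if bad:
            warnings.warn(
                f"protein {self.protein_id!r}: characters outside the "
                f"amino-acid alphabet: {''.join(bad)}",
                stacklevel=2,
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class InteractionPair:
    """One (compound, protein) pair with a label and an optional score."""

    compound_id: str
    protein_id: str
    label: str = POSITIVE
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise FormatError(
                f"pair ({self.compound_id}, {self.protein_id}): "
                f"unknown label {self.label!r}"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise FormatError(
                f"pair ({self.compound_id}, {self.protein_id}): "
                f"score {self.score} outside [0, 1]"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.protein_id)

    def with_label(self, label: str) -> "InteractionPair":
        return replace(self, label=label)

    def with_score(self, score: float) -> "InteractionPair":
        return replace(self, score=float(score))


def check_smiles(smiles: str) -> bool:
    """Optional SMILES sanity check via RDKit, if installed.

    Returns True when the string parses (or RDKit is unavailable, in which
    case the check is a no-op).  Emits a warning for unparsable strings but
    never filters — the pipeline treats SMILES as opaque tokens.
    """
    try:
        from rdkit import Chem  # type: ignore
        from rdkit import RDLogger  # type: ignore
    except ImportError:  # pragma: no cover - rdkit optional
        return True
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        warnings.warn(f"SMILES does not parse: {smiles!r}", stacklevel=2)
        return False
    return True
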