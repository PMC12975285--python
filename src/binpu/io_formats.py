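"""Readers and writers for interaction tables, FASTA, .smi and pair tables.

The interaction table is a CSV/TSV with columns ``compound_id``, ``smiles``,
``protein_id``, ``sequence`` and an optional ``label``; rows without a label
column are taken as known positives.  Entities are deduplicated by *exact*
string equality of the SMILES / sequence (canonicalization, e.g. through a
chemistry toolkit, is assumed to have happened upstream): the first id seen
for a given string becomes the canonical id, and pair references are
remapped onto it.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConflictError, FormatError
from .records import (
    POSITIVE,
    CompoundRecord,
    InteractionPair,
    ProteinRecord,
)

_REQUIRED_COLUMNS = ("compound_id", "smiles", "protein_id", "sequence")

SCORE_DECIMALS = 6


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise FormatError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")


def infer_dialect(path: str | os.PathLike) -> str:
    """Guess csv/tsv from the file extension; default to tsv."""
    ext = os.path.splitext(str(path))[1].lower()
    return "csv" if ext == ".csv" else "tsv"


def _dedup_compounds(rows: Iterable[tuple[str, str]]) -> tuple[list[CompoundRecord], dict[str, str]]:
    """Deduplicate (id, smiles) rows by exact SMILES; return canonical-id map."""
    by_smiles: dict[str, str] = {}
    id_to_smiles: dict[str, str] = {}
    canonical: dict[str, str] = {}
    out: list[CompoundRecord] = []
    for cid, smiles in rows:
        smiles = smiles.strip()
        if cid in id_to_smiles and id_to_smiles[cid] != smiles:
            raise ConflictError(
                f"compound id {cid!r} maps to two different SMILES strings"
            )
        id_to_smiles[cid] = smiles
        if smiles in by_smiles:
            canonical[cid] = by_smiles[smiles]
        else:
            by_smiles[smiles] = cid
            canonical[cid] = cid
            out.append(CompoundRecord(cid, smiles))
    return out, canonical


def _dedup_proteins(rows: Iterable[tuple[str, str]]) -> tuple[list[ProteinRecord], dict[str, str]]:
    by_seq: dict[str, str] = {}
    id_to_seq: dict[str, str] = {}
    canonical: dict[str, str] = {}
    out: list[ProteinRecord] = []
    for pid, seq in rows:
        seq = seq.strip().upper()
        if pid in id_to_seq and id_to_seq[pid] != seq:
            raise ConflictError(
                f"protein id {pid!r} maps to two different sequences"
            )
        id_to_seq[pid] = seq
        if seq in by_seq:
            canonical[pid] = by_seq[seq]
        else:
            by_seq[seq] = pid
            canonical[pid] = pid
            out.append(ProteinRecord(pid, seq))
    return out, canonical


def read_interactions(
    path: str | os.PathLike, dialect: Optional[str] = None
) -> tuple[list[CompoundRecord], list[ProteinRecord], list[InteractionPair]]:
    """Read an interaction table and return deduplicated entities plus pairs.

    A missing ``label`` column labels every row ``positive``.  Duplicate
    (compound, protein) rows with the same label collapse to one pair;
    with different labels they raise :class:`ConflictError`.
    """
    if dialect is None:
        dialect = infer_dialect(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"interaction table not found: {path}")
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    has_label = "label" in df.columns

    compounds, cmap = _dedup_compounds(
        zip(df["compound_id"], df["smiles"])
    ) if len(df) else ([], {})
    proteins, pmap = _dedup_proteins(
        zip(df["protein_id"], df["sequence"])
    ) if len(df) else ([], {})

    pairs: list[InteractionPair] = []
    seen: dict[tuple[str, str], str] = {}
    for _, row in df.iterrows():
        label = row["label"].strip() if has_label and row["label"].strip() else POSITIVE
        cid = cmap[row["compound_id"]]
        pid = pmap[row["protein_id"]]
        key = (cid, pid)
        if key in seen:
            if seen[key] != label:
                raise ConflictError(
                    f"pair {key} appears with conflicting labels "
                    f"{seen[key]!r} and {label!r}"
                )
            continue
        seen[key] = label
        score = None
        if "score" in df.columns and row["score"].strip():
            score = float(row["score"])
        pairs.append(InteractionPair(cid, pid, label=label, score=score))
    return compounds, proteins, pairs


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a FASTA file into protein records, deduplicated by sequence.

    Record ids are the first whitespace-delimited header token; wrapped
    sequence lines are concatenated and upper-cased.
    """
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: content before the first '>' header")
                break
        handle.seek(0)
        raw = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    for pid, seq in raw:
        if not seq.strip():
            raise FormatError(f"{path}: record {pid!r} has an empty sequence")
    records, _ = _dedup_proteins(raw)
    return records


def read_smiles_file(path: str | os.PathLike) -> list[CompoundRecord]:
    """Read a .smi file: one ``SMILES[<whitespace>ID]`` per line.

    A missing id is synthesized as ``C{line}`` from the 1-based line
    number.  Records are deduplicated by exact SMILES.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split()
            smiles = fields[0].strip()
            if not smiles:
                raise FormatError(f"{path}:{lineno}: blank SMILES field")
            cid = fields[1] if len(fields) > 1 else f"C{lineno}"
            rows.append((cid, smiles))
    records, _ = _dedup_compounds(rows)
    return records


def write_pair_table(
    pairs: Sequence[InteractionPair],
    path: str | os.PathLike,
    dialect: Optional[str] = None,
) -> None:
    """Write pairs as a table with columns compound_id, protein_id, label, score.

    Scores are serialized to 6 decimal places; a missing score is an empty
    field.  ``write_pair_table`` followed by :func:`read_pair_table` is the
    identity on (ids, label, score@6dp).
    """
    if dialect is None:
        dialect = infer_dialect(path)
    sep = _sep(dialect)
    with open(path, "w") as handle:
        handle.write(sep.join(["compound_id", "protein_id", "label", "score"]) + "\n")
        for p in pairs:
            score = "" if p.score is None else f"{p.score:.{SCORE_DECIMALS}f}"
            handle.write(sep.join([p.compound_id, p.protein_id, p.label, score]) + "\n")


def read_pair_table(
    path: str | os.PathLike, dialect: Optional[str] = None
) -> list[InteractionPair]:
    """Read a table written by :func:`write_pair_table`."""
    if dialect is None:
        dialect = infer_dialect(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in ("compound_id", "protein_id", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    pairs = []
    for _, row in df.iterrows():
        score = float(row["score"]) if "score" in df.columns and row["score"].strip() else None
        pairs.append(
            InteractionPair(row["compound_id"], row["protein_id"], label=row["label"], score=score)
        )
    return pairs


def write_json_report(report: dict, path: str | os.PathLike) -> None:
    """Write a flat metrics/manifest dict as indented JSON."""
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=float)
        handle.write("\n")
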