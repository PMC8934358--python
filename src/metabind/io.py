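"""Readers/writers for the external representations the pipeline touches.

All tabular inputs are delimited text (tab or comma, auto-detected from the
header line).  IDs are opaque strings; every downstream stage indexes
positionally against the ordered ID lists held by :class:`AffinityDataset`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Orientation",
    "AffinityDataset",
    "SimilarityMatrix",
    "SequenceRecord",
    "load_affinity_table",
    "write_affinity_table",
    "load_fasta",
    "load_smiles_table",
    "load_similarity_matrix",
    "write_similarity_matrix",
]

_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Orientation(enum.Enum):
    """Whether a larger raw affinity value means a stronger binder.

    pKd-style scales are HIGHER_IS_STRONGER; raw Kd (nM) and raw KIBA
    scores are LOWER_IS_STRONGER.
    """

    HIGHER_IS_STRONGER = "higher_is_stronger"
    LOWER_IS_STRONGER = "lower_is_stronger"


@dataclass
class AffinityDataset:
    """Drug x target affinity matrix with an observed-entry mask.

    Parameters
    ----------
    drug_ids, target_ids
        Ordered, duplicate-free identifier lists.
    affinities
        ``(n_drugs, n_targets)`` float array; entries where ``observed`` is
        False are ignored everywhere downstream (never imputed).
    observed
        Boolean mask, same shape as ``affinities``.
    orientation
        Scale direction of the raw values.
    unit_label
        Free-text label, e.g. ``"pKd"`` or ``"KIBA score"``.
    """

    drug_ids: list[str]
    target_ids: list[str]
    affinities: np.ndarray
    observed: np.ndarray
    orientation: Orientation = Orientation.HIGHER_IS_STRONGER
    unit_label: str = ""

    def __post_init__(self) -> None:
        self.affinities = np.asarray(self.affinities, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n, m = len(self.drug_ids), len(self.target_ids)
        if len(set(self.drug_ids)) != n:
            raise ValueError("duplicate drug IDs")
        if len(set(self.target_ids)) != m:
            raise ValueError("duplicate target IDs")
        if self.affinities.shape != (n, m):
            raise ValueError(
                f"affinity matrix shape {self.affinities.shape} != ({n}, {m})"
            )
        if self.observed.shape != (n, m):
            raise ValueError("observed mask shape mismatch")
        if not np.all(np.isfinite(self.affinities[self.observed])):
            raise ValueError("non-finite value at an observed entry")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def observed_pairs(self) -> np.ndarray:
        """(N, 2) array of (drug_index, target_index) for observed entries."""
        return np.argwhere(self.observed)

    def labels(self, pairs: np.ndarray) -> np.ndarray:
        pairs = np.asarray(pairs)
        return self.affinities[pairs[:, 0], pairs[:, 1]]


@dataclass
class SimilarityMatrix:
    """Square symmetric pairwise-score matrix keyed by an ordered ID list."""

    entity_ids: list[str]
    values: np.ndarray
    _sym_tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.entity_ids)
        if self.values.shape != (k, k):
            raise ValueError(f"similarity matrix must be {k}x{k}, got {self.values.shape}")
        if len(set(self.entity_ids)) != k:
            raise ValueError("duplicate entity IDs")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > self._sym_tol:
            raise ValueError(f"similarity matrix asymmetric (max |S - S.T| = {asym:g})")
        # symmetrize away sub-tolerance float noise
        self.values = (self.values + self.values.T) / 2.0


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence: amino-acid string or SMILES string."""

    id: str
    sequence: str

    def validate_protein(self) -> None:
        bad = set(self.sequence) - _PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non amino-acid characters {sorted(bad)}"
            )


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def load_affinity_table(
    path: str | Path,
    orientation: Orientation = Orientation.HIGHER_IS_STRONGER,
    missing_token: str = "NaN",
    unit_label: str = "",
) -> AffinityDataset:
    """Load a labelled drug (rows) x target (columns) affinity matrix.

    Cells equal to ``missing_token`` (or empty) are masked out; any other
    non-numeric cell is a hard error naming the offending cell.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty affinity table")
    drug_ids = [str(i) for i in df.index]
    target_ids = [str(c) for c in df.columns]
    if len(set(drug_ids)) != len(drug_ids):
        raise ValueError(f"{path}: duplicate drug IDs")
    if len(set(target_ids)) != len(target_ids):
        raise ValueError(f"{path}: duplicate target IDs")
    raw = df.to_numpy()
    values = np.zeros(raw.shape, dtype=float)
    observed = np.ones(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell == missing_token or cell == "":
                observed[i, j] = False
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell at drug {drug_ids[i]!r}, "
                    f"target {target_ids[j]!r}: {cell!r}"
                ) from exc
    return AffinityDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        affinities=values,
        observed=observed,
        orientation=orientation,
        unit_label=unit_label,
    )


def write_affinity_table(
    dataset: AffinityDataset, path: str | Path, missing_token: str = "NaN", sep: str = "\t"
) -> None:
    """Write the matrix back out; masked cells become ``missing_token``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(sep.join([""] + dataset.target_ids) + "\n")
        for i, did in enumerate(dataset.drug_ids):
            cells = [
                repr(float(dataset.affinities[i, j])) if dataset.observed[i, j] else missing_token
                for j in range(dataset.n_targets)
            ]
            fh.write(sep.join([did] + cells) + "\n")


def load_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into ordered records (sequences uppercased)."""
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(SequenceRecord(header, "".join(chunks)))
                header = line[1:].split()[0]
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                chunks.append(line.upper().replace(" ", ""))
    if header is not None:
        records.append(SequenceRecord(header, "".join(chunks)))
    for rec in records:
        if not rec.sequence:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def load_smiles_table(path: str | Path) -> list[SequenceRecord]:
    """Load a two-column delimited ID -> SMILES table, order preserved.

    SMILES are kept verbatim (no canonicalization).  A quoted field may
    contain the delimiter.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        for ln, row in enumerate(reader, 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns (ID, SMILES)")
            rid, smiles = row[0].strip(), row[1].strip()
            if ln == 1 and smiles.upper() in {"SMILES", "SMILE"}:
                continue  # header row
            if rid in seen:
                raise ValueError(f"{path}: duplicate drug ID {rid!r}")
            if not smiles:
                raise ValueError(f"{path}:{ln}: empty SMILES for {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, smiles))
    if not records:
        raise ValueError(f"{path}: no SMILES records")
    return records


def write_smiles_table(records: Sequence[SequenceRecord], path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["drug_id", "SMILES"])
        for rec in records:
            writer.writerow([rec.id, rec.sequence])


def load_similarity_matrix(path: str | Path, sym_tol: float = 1e-9) -> SimilarityMatrix:
    """Load a square labelled similarity matrix; asymmetry beyond tolerance errors."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is {df.shape[0]}x{df.shape[1]}, not square")
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row labels and column labels disagree")
    return SimilarityMatrix(entity_ids=ids, values=df.to_numpy(dtype=float), _sym_tol=sym_tol)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids)
    df.to_csv(path, sep=sep)


def pair_id(drug_id: str, target_id: str) -> str:
    """Canonical pair key used in exported feature tables."""
    return f"{drug_id}|{target_id}"
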