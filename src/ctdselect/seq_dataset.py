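"""Sequence datasets and the labeled feature-table interchange format.

This module handles the plumbing around the descriptors: reading protein
sequences from FASTA, assembling a labeled feature matrix from a positive
and a negative sequence set, and round-tripping that matrix through CSV.

Internally the positive class is always labeled 1 and the negative class 0.
Some published feature tables instead mark positives 0 and negatives -1;
:func:`write_csv` can emit that convention via ``label_style="zero_minusone"``
and :func:`read_csv` maps it back on import.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: One-letter codes that occur in real FASTA files but are not canonical
#: residues: ambiguity codes (B, J, Z, X), the rare translated residues
#: selenocysteine (U) and pyrrolysine (O).
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")

RESIDUE_POLICIES = ("strict", "drop", "map_to_x_then_drop")

LABEL_STYLES = {
    # internal -> exported
    "standard": {1: 1, 0: 0},
    "zero_minusone": {1: 0, 0: -1},
}
#: Alias for the 0/-1 export convention used in some published tables.
LABEL_STYLES["paper"] = LABEL_STYLES["zero_minusone"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class ResidueError(ValueError):
    """Raised when a sequence contains letters outside the 20-letter alphabet."""


class FeatureTableError(ValueError):
    """Raised when a feature matrix violates its structural contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: identifier plus residue string.

    Residues must be uppercase letters from the 20-letter canonical
    alphabet; apply :func:`sanitize_residues` first for raw input.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ResidueError(f"sequence {self.id!r}: empty after sanitization")
        bad = sorted(set(self.residues) - _AA_SET)
        if bad:
            raise ResidueError(
                f"sequence {self.id!r}: non-canonical residue(s) {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def sanitize_residues(raw: str, policy: str = "drop", seq_id: str = "?") -> str:
    """Uppercase a residue string and apply the nonstandard-residue policy.

    Parameters
    ----------
    raw:
        Residue string as read from file; may be mixed case and contain
        whitespace (stripped) or nonstandard one-letter codes.
    policy:
        ``"strict"`` raises on any non-canonical letter; ``"drop"`` removes
        such letters; ``"map_to_x_then_drop"`` first maps ambiguity codes to
        X and then drops X along with anything else non-canonical (the net
        residue content equals ``"drop"``, but the intermediate X-form is
        the convention some toolchains log).
    """
    if policy not in RESIDUE_POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; choose from {RESIDUE_POLICIES}")
    seq = "".join(raw.split()).upper()
    if policy == "strict":
        bad = sorted(set(seq) - _AA_SET)
        if bad:
            raise ResidueError(
                f"sequence {seq_id!r}: non-canonical residue(s) {''.join(bad)!r} "
                "(policy=strict)"
            )
        return seq
    if policy == "map_to_x_then_drop":
        seq = "".join("X" if c in NONSTANDARD_RESIDUES else c for c in seq)
    return "".join(c for c in seq if c in _AA_SET)


def read_fasta(path: str | Path, residue_policy: str = "drop") -> list[ProteinSequence]:
    """Read all records of a FASTA file, in file order.

    Residues are uppercased and the nonstandard-residue ``residue_policy``
    is applied (see :func:`sanitize_residues`). A record whose sequence is
    empty — in the file, or after dropping nonstandard letters — is a
    parse error naming the record index.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    for i, rec in enumerate(records):
        if not rec.id:
            raise FastaParseError(f"{path}: record {i}: empty header")
        raw = str(rec.seq)
        if not raw:
            raise FastaParseError(f"{path}: record {i} ({rec.id!r}): empty sequence")
        residues = sanitize_residues(raw, residue_policy, seq_id=rec.id)
        if not residues:
            raise FastaParseError(
                f"{path}: record {i} ({rec.id!r}): no canonical residues remain"
            )
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> Path:
    """Write sequences to ``path``, one unwrapped line per record."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")
    return path


@dataclass
class FeatureMatrix:
    """Named feature columns x labeled samples.

    ``data`` holds one row per sample (index = sample ids, columns = unique
    feature names); ``labels`` is an aligned int series with 1 for the
    positive class and 0 for the negative class. Both classes must be
    present.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise FeatureTableError("feature matrix has no samples")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FeatureTableError(f"duplicated feature names: {dups}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise FeatureTableError("feature values must be numeric")
        if len(self.labels) != len(self.data):
            raise FeatureTableError("labels and data row counts differ")
        self.labels = self.labels.astype(int)
        self.labels.index = self.data.index
        observed = set(self.labels.unique())
        if observed != {0, 1}:
            raise FeatureTableError(
                f"labels must be exactly {{0, 1}} with both classes present; got {sorted(observed)}"
            )

    # -- convenience views -------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select(self, features: Sequence[str]) -> "FeatureMatrix":
        """Restrict to the given feature columns, preserving sample order."""
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise FeatureTableError(f"unknown feature name(s): {missing}")
        return FeatureMatrix(self.data.loc[:, list(features)].copy(), self.labels.copy())


def build_feature_table(
    pos: Sequence[ProteinSequence],
    neg: Sequence[ProteinSequence],
    extractor: Callable[[ProteinSequence], pd.Series],
) -> FeatureMatrix:
    """Extract features for both classes and stack them into one matrix.

    Rows are positives (label 1) in input order followed by negatives
    (label 0) in input order. ``extractor`` maps a sequence to a named
    numeric vector (a :class:`pandas.Series`); all vectors must share the
    same index.
    """
    if not pos or not neg:
        raise FeatureTableError("both the positive and the negative set must be non-empty")
    overlap = {s.residues for s in pos} & {s.residues for s in neg}
    if overlap:
        warnings.warn(
            f"{len(overlap)} identical sequence(s) appear in both classes; "
            "they are kept with their respective labels",
            stacklevel=2,
        )
    rows: list[pd.Series] = []
    ids: list[str] = []
    names: list[str] | None = None
    for seq in list(pos) + list(neg):
        vec = extractor(seq)
        if names is None:
            names = list(vec.index)
        elif list(vec.index) != names:
            raise FeatureTableError(
                f"extractor returned inconsistent feature names for {seq.id!r}"
            )
        rows.append(vec.astype(float))
        ids.append(seq.id)
    data = pd.DataFrame(rows, index=ids)
    labels = pd.Series([1] * len(pos) + [0] * len(neg), index=ids)
    return FeatureMatrix(data, labels)


def write_csv(matrix: FeatureMatrix, path: str | Path, label_style: str = "standard") -> Path:
    """Write a feature matrix as ``id,label,<feature...>`` CSV (UTF-8).

    ``label_style`` selects the exported label coding: ``"standard"``
    writes 1/0, ``"zero_minusone"`` (alias ``"paper"``) writes 0 for the
    positive class and -1 for the negative class. Values are written at
    full repr precision so the round trip is exact.
    """
    if label_style not in LABEL_STYLES:
        raise ValueError(f"unknown label style {label_style!r}; choose from {sorted(LABEL_STYLES)}")
    if matrix.n_samples == 0:  # pragma: no cover - FeatureMatrix already forbids this
        raise FeatureTableError("refusing to write an empty feature matrix")
    path = Path(path)
    mapping = LABEL_STYLES[label_style]
    out = matrix.data.copy()
    out.insert(0, "label", matrix.labels.map(mapping))
    out.index.name = "id"
    out.to_csv(path, float_format=None)
    return path


def read_csv(path: str | Path, label_style: str = "auto") -> FeatureMatrix:
    """Read a ``id,label,<feature...>`` CSV back into a :class:`FeatureMatrix`.

    With ``label_style="auto"`` the exported coding is inferred from the
    label values: ``{0, 1}`` means standard 1-positive coding and
    ``{0, -1}`` means the 0-positive / -1-negative coding.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    cols = list(df.columns)
    if len(cols) < 2 or cols[0] != "id" or cols[1] != "label":
        raise FeatureTableError(
            f"{path}: expected header starting with 'id,label', got {cols[:2]}"
        )
    df = df.set_index("id")
    raw_labels = df.pop("label")
    observed = set(pd.unique(raw_labels))
    if label_style == "auto":
        if observed <= {0, 1}:
            label_style = "standard"
        elif observed <= {0, -1}:
            label_style = "zero_minusone"
        else:
            raise FeatureTableError(
                f"{path}: cannot infer label coding from values {sorted(observed)}"
            )
    if label_style not in LABEL_STYLES:
        raise ValueError(f"unknown label style {label_style!r}")
    inverse = {v: k for k, v in LABEL_STYLES[label_style].items()}
    unknown = observed - set(inverse)
    if unknown:
        raise FeatureTableError(
            f"{path}: label value(s) {sorted(unknown)} invalid for style {label_style!r}"
        )
    labels = raw_labels.map(inverse)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row_id = df.index[bad][0]
            raise FeatureTableError(
                f"{path}: non-numeric value {df.loc[row_id, col]!r} "
                f"in row {row_id!r}, column {col!r}"
            )
        df[col] = coerced
    return FeatureMatrix(df, labels)
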