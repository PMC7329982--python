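"""Composition/Transition/Distribution (CTD) protein descriptors.

CTD turns a variable-length protein sequence into a fixed-length numeric
vector. Each physicochemical scale partitions the 20 amino acids into three
groups; the sequence is rewritten as a string over {1,2,3} and three kinds
of statistics are read off that index string:

* **Composition** — for each group e, 100 * n_e / N, the percentage of
  residues falling in the group (n_e occurrences, sequence length N).
* **Transition** — for each unordered group pair {a,b}, a != b,
  100 * (n_ab + n_ba) / (N - 1), the percentage of adjacent residue pairs
  that switch between the two groups.
* **Distribution** — for each group, the positions (1-based, as a
  percentage of N) at which the group's occurrences sit: either every
  occurrence (``all_positions``) or the classic five quantile landmarks
  (first, 25%, 50%, 75%, 100% of the group's occurrences).

Grouping tables ship as plain-text data: ``core7`` (seven scales, 21
composition features) and ``extended13`` (thirteen scales, 39 composition
features).

Percentages are kept at full float precision. :func:`truncate1` floors to
one decimal and exists only to reproduce human-readable reference values,
which conventionally truncate rather than round (e.g. 2/19 -> 10.5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_dataset import AMINO_ACIDS, ProteinSequence

_AA_SET = frozenset(AMINO_ACIDS)

#: Unordered heterogeneous group pairs, in canonical order.
TRANSITION_PAIRS = ((1, 2), (1, 3), (2, 3))

#: Quantile landmarks of the five-point distribution descriptor.
FIVE_POINT_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)
#: Four-point variant omitting the 75% landmark.
FOUR_POINT_QUANTILES = (0.0, 0.25, 0.50, 1.0)


class GroupingError(ValueError):
    """Raised when a grouping table is not a valid 3-partition of the alphabet."""


def truncate1(value: float) -> float:
    """Floor a percentage to one decimal place (36.84 -> 36.8, 21.05 -> 21.0)."""
    return math.floor(value * 10.0) / 10.0


@dataclass(frozen=True)
class PropertyGrouping:
    """One physicochemical scale's partition of the 20 amino acids into 3 groups."""

    name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        if not self.name:
            raise GroupingError("property name must be non-empty")
        if len(self.groups) != 3:
            raise GroupingError(f"{self.name}: expected exactly 3 groups")
        union: set[str] = set()
        for k, g in enumerate(self.groups, start=1):
            if not g:
                raise GroupingError(f"{self.name}: group {k} is empty")
            clash = union & set(g)
            if clash:
                raise GroupingError(
                    f"{self.name}: residue(s) {''.join(sorted(clash))!r} in more than one group"
                )
            union |= set(g)
        if union != _AA_SET:
            missing = "".join(sorted(_AA_SET - union))
            extra = "".join(sorted(union - _AA_SET))
            raise GroupingError(
                f"{self.name}: groups must cover the 20-letter alphabet exactly"
                + (f"; missing {missing!r}" if missing else "")
                + (f"; unknown {extra!r}" if extra else "")
            )
        object.__setattr__(
            self,
            "_index",
            {res: k for k, g in enumerate(self.groups, start=1) for res in g},
        )

    def group_of(self, residue: str) -> int:
        """Group number (1, 2 or 3) of a canonical residue."""
        try:
            return self._index[residue]  # type: ignore[attr-defined]
        except KeyError:
            raise GroupingError(
                f"{self.name}: residue {residue!r} not assigned to any group"
            ) from None


@dataclass(frozen=True)
class GroupingTable:
    """An ordered collection of uniquely named :class:`PropertyGrouping` scales."""

    name: str
    groupings: tuple[PropertyGrouping, ...]

    def __post_init__(self) -> None:
        if not self.groupings:
            raise GroupingError(f"table {self.name!r} is empty")
        names = [g.name for g in self.groupings]
        if len(set(names)) != len(names):
            raise GroupingError(f"table {self.name!r}: duplicate property names")

    def __iter__(self) -> Iterator[PropertyGrouping]:
        return iter(self.groupings)

    def __len__(self) -> int:
        return len(self.groupings)

    def __getitem__(self, key: int | str) -> PropertyGrouping:
        if isinstance(key, str):
            for g in self.groupings:
                if g.name == key:
                    return g
            raise KeyError(key)
        return self.groupings[key]

    @property
    def property_names(self) -> list[str]:
        return [g.name for g in self.groupings]


def _parse_grouping_lines(lines: Sequence[str], table_name: str) -> GroupingTable:
    groupings: list[PropertyGrouping] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise GroupingError(
                f"table {table_name!r}, line {lineno}: expected "
                f"'name<TAB>group1<TAB>group2<TAB>group3', got {line!r}"
            )
        name, g1, g2, g3 = parts
        groupings.append(
            PropertyGrouping(
                name=name,
                groups=(
                    frozenset(g1.upper()),
                    frozenset(g2.upper()),
                    frozenset(g3.upper()),
                ),
            )
        )
    return GroupingTable(name=table_name, groupings=tuple(groupings))


def load_grouping_table(which: str | Path = "core7") -> GroupingTable:
    """Load a grouping table: the bundled ``core7``/``extended13`` or a custom file.

    Custom files use the same plain-text format as the bundled tables: one
    scale per line, ``name<TAB>group1<TAB>group2<TAB>group3``, ``#`` comments.
    """
    if which in ("core7", "extended13"):
        text = resources.files("ctdselect.data").joinpath(f"{which}.tsv").read_text()
        return _parse_grouping_lines(text.splitlines(), str(which))
    path = Path(which)
    if not path.exists():
        raise FileNotFoundError(
            f"unknown grouping table {which!r}: not 'core7', 'extended13' or an existing file"
        )
    return _parse_grouping_lines(path.read_text().splitlines(), path.stem)


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence rewritten as group indices {1,2,3} under one scale."""

    indices: str
    source_property: str = "custom"

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("encoded sequence must be non-empty")
        bad = set(self.indices) - {"1", "2", "3"}
        if bad:
            raise ValueError(f"encoded sequence contains non-index symbols {sorted(bad)}")

    @property
    def N(self) -> int:
        return len(self.indices)

    def count(self, group: int) -> int:
        """n_e: occurrences of group ``group`` in the encoding."""
        return self.indices.count(str(group))

    def positions(self, group: int) -> list[int]:
        """1-based positions of the occurrences of ``group``, ascending."""
        sym = str(group)
        return [i + 1 for i, c in enumerate(self.indices) if c == sym]


def encode_sequence(seq: ProteinSequence, grouping: PropertyGrouping) -> EncodedSequence:
    """Rewrite a protein sequence as its group-index string under one scale."""
    return EncodedSequence(
        indices="".join(str(grouping.group_of(r)) for r in seq.residues),
        source_property=grouping.name,
    )


def composition(enc: EncodedSequence) -> np.ndarray:
    """Percentage of residues in groups 1..3; entries sum to 100 exactly (pre-rounding)."""
    n = enc.N
    return np.array([100.0 * enc.count(g) / n for g in (1, 2, 3)])


def transition(enc: EncodedSequence) -> np.ndarray:
    """Percentage of adjacent pairs switching groups, for pairs (1,2), (1,3), (2,3).

    Undefined for a single-residue encoding (no adjacent pairs).
    """
    n = enc.N
    if n < 2:
        raise ValueError("transition is undefined for a length-1 sequence (N-1 = 0 pairs)")
    counts = {pair: 0 for pair in TRANSITION_PAIRS}
    for a, b in zip(enc.indices, enc.indices[1:]):
        if a != b:
            key = tuple(sorted((int(a), int(b))))
            counts[key] += 1
    return np.array([100.0 * counts[p] / (n - 1) for p in TRANSITION_PAIRS])


def _occurrence_landmarks(k: int, quantiles: Sequence[float]) -> list[int]:
    # occurrence number for quantile q: max(1, round-half-up(q * k))
    return [max(1, math.floor(q * k + 0.5)) for q in quantiles]


def distribution(
    enc: EncodedSequence,
    mode: str = "all_positions",
    quantiles: Sequence[float] = FIVE_POINT_QUANTILES,
) -> dict[int, list[float]]:
    """Positional distribution of each group, as percentages of the length.

    ``all_positions`` lists every occurrence position p as 100*p/N
    (strictly increasing; empty list for an absent group). ``five_point``
    reduces each group to landmark occurrences — for a group with k >= 1
    occurrences, occurrence number ``max(1, round_half_up(q*k))`` for each
    quantile q (default first/25/50/75/100%) — and reports those positions;
    an absent group yields all zeros.
    """
    if mode not in ("all_positions", "five_point"):
        raise ValueError(f"unknown distribution mode {mode!r}")
    n = enc.N
    out: dict[int, list[float]] = {}
    for g in (1, 2, 3):
        pos = enc.positions(g)
        if mode == "all_positions":
            out[g] = [100.0 * p / n for p in pos]
        else:
            if not pos:
                out[g] = [0.0] * len(quantiles)
            else:
                out[g] = [
                    100.0 * pos[idx - 1] / n
                    for idx in _occurrence_landmarks(len(pos), quantiles)
                ]
    return out


@dataclass(frozen=True)
class CtdResult:
    """Full C/T/D readout of one encoded sequence (percent scale)."""

    composition: np.ndarray  # groups 1..3
    transition: np.ndarray  # pairs (1,2), (1,3), (2,3)
    distribution: Mapping[int, list[float]]


def ctd(enc: EncodedSequence, distribution_mode: str = "all_positions") -> CtdResult:
    """Compute composition, transition and distribution for one encoding."""
    return CtdResult(
        composition=composition(enc),
        transition=transition(enc),
        distribution=distribution(enc, mode=distribution_mode),
    )


def ctdc_vector(seq: ProteinSequence, table: GroupingTable) -> pd.Series:
    """Composition features for every scale of ``table``, property-major.

    Feature names are ``<property>.G<k>``; the vector length is
    ``3 * len(table)`` (21 for ``core7``, 39 for ``extended13``).
    """
    names: list[str] = []
    values: list[float] = []
    for grouping in table:
        comp = composition(encode_sequence(seq, grouping))
        for k in (1, 2, 3):
            names.append(f"{grouping.name}.G{k}")
            values.append(comp[k - 1])
    return pd.Series(values, index=names)


def ctd_vector(
    seq: ProteinSequence,
    table: GroupingTable,
    descriptors: str = "C",
    quantiles: Sequence[float] = FIVE_POINT_QUANTILES,
) -> pd.Series:
    """Concatenated descriptor vector with the chosen components.

    ``descriptors`` is one of ``"C"``, ``"CT"``, ``"CTD"``: composition
    only (3 features per scale), plus transitions (3 more), plus the
    five-point distribution (3 groups x len(quantiles) more). Property-major
    ordering with C, T, D blocks consecutive within each scale.
    """
    if descriptors not in ("C", "CT", "CTD"):
        raise ValueError(f"descriptors must be 'C', 'CT' or 'CTD', got {descriptors!r}")
    names: list[str] = []
    values: list[float] = []
    for grouping in table:
        enc = encode_sequence(seq, grouping)
        comp = composition(enc)
        for k in (1, 2, 3):
            names.append(f"{grouping.name}.G{k}")
            values.append(comp[k - 1])
        if "T" in descriptors:
            tr = transition(enc)
            for (a, b), v in zip(TRANSITION_PAIRS, tr):
                names.append(f"{grouping.name}.T.G{a}G{b}")
                values.append(v)
        if "D" in descriptors:
            dist = distribution(enc, mode="five_point", quantiles=quantiles)
            for k in (1, 2, 3):
                for q, v in zip(quantiles, dist[k]):
                    names.append(f"{grouping.name}.D.G{k}.Q{int(round(q * 100)):03d}")
                    values.append(v)
    return pd.Series(values, index=names)


def ctdc_extractor(table: GroupingTable, descriptors: str = "C"):
    """Return an extractor closure suitable for ``build_feature_table``."""

    def _extract(seq: ProteinSequence) -> pd.Series:
        if descriptors == "C":
            return ctdc_vector(seq, table)
        return ctd_vector(seq, table, descriptors=descriptors)

    return _extract
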