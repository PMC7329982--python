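"""Synthetic labeled protein-sequence datasets with controllable compositional bias.

The generator draws residues i.i.d. from a per-class 20-letter weight
vector, which is exactly the kind of signal a composition descriptor can
carry. The built-in separable dataset shifts probability mass ``bias``
toward the hydrophobic residues (M, F, I, L, C, W, V) in the positive
class and toward the polar residues (N, Q, D, E, K, R) in the negative
class; ``bias = 0`` makes the two classes identically distributed
(uniform over the alphabet), giving a clean no-signal null.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_dataset import AMINO_ACIDS, ProteinSequence, write_fasta

#: Hydrophobicity-scale groups that define the bias axis.
POLAR_RESIDUES = frozenset("NQDEKR")
HYDROPHOBIC_RESIDUES = frozenset("MFILCWV")

#: Default sequence-length range, roughly the span of globular protein domains.
DEFAULT_LENGTH_RANGE = (100, 400)


@dataclass(frozen=True)
class ClassModel:
    """An i.i.d. residue model for one class: weights + length range."""

    label: int
    residue_weights: tuple[float, ...]  # aligned to AMINO_ACIDS, sums to 1
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        w = np.asarray(self.residue_weights, dtype=float)
        if len(w) != len(AMINO_ACIDS):
            raise ValueError(f"need {len(AMINO_ACIDS)} residue weights, got {len(w)}")
        if np.any(w < 0):
            raise ValueError("residue weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"residue weights must sum to 1 (got {w.sum()!r})")
        lo, hi = self.length_range
        if not (10 <= lo <= hi):
            raise ValueError("length range must satisfy 10 <= min <= max")

    def mass_on(self, residues: Sequence[str]) -> float:
        """Total probability mass the model puts on a residue set."""
        idx = [AMINO_ACIDS.index(r) for r in residues]
        return float(np.sum(np.asarray(self.residue_weights)[idx]))


def generate_sequences(model: ClassModel, n: int, seed: int) -> list[ProteinSequence]:
    """Draw ``n`` i.i.d. sequences from a class model; deterministic per seed.

    Lengths are uniform on the model's range; ids encode the class and the
    record index (e.g. ``pos_00003``).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    weights = np.asarray(model.residue_weights)
    tag = "pos" if model.label == 1 else "neg"
    lo, hi = model.length_range
    out: list[ProteinSequence] = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(alphabet, size=length, p=weights))
        out.append(ProteinSequence(id=f"{tag}_{i:05d}", residues=residues))
    return out


def biased_weights(bias: float, enriched: Sequence[str]) -> tuple[float, ...]:
    """Uniform weights with probability mass ``bias`` moved onto ``enriched``.

    Every residue keeps ``(1 - bias)/20``; the moved mass is spread evenly
    over the enriched set. ``bias = 0`` returns the uniform vector.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    enriched_set = set(enriched)
    n = len(AMINO_ACIDS)
    base = (1.0 - bias) / n
    extra = bias / len(enriched_set)
    return tuple(base + (extra if aa in enriched_set else 0.0) for aa in AMINO_ACIDS)


def separable_class_models(
    bias: float, length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
) -> tuple[ClassModel, ClassModel]:
    """(positive, negative) models: hydrophobic- vs polar-enriched by ``bias``."""
    pos = ClassModel(
        label=1,
        residue_weights=biased_weights(bias, sorted(HYDROPHOBIC_RESIDUES)),
        length_range=length_range,
    )
    neg = ClassModel(
        label=0,
        residue_weights=biased_weights(bias, sorted(POLAR_RESIDUES)),
        length_range=length_range,
    )
    return pos, neg


def make_separable_dataset(
    bias: float,
    n_per_class: int,
    seed: int,
    out_dir: str | Path,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> tuple[Path, Path]:
    """Write ``positives.fasta`` / ``negatives.fasta`` plus a parameter manifest.

    Independent per-class streams are spawned from the seed, so the two
    files are individually reproducible. Returns the two FASTA paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos_model, neg_model = separable_class_models(bias, length_range)
    pos_seed, neg_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    )
    pos_path = write_fasta(
        generate_sequences(pos_model, n_per_class, pos_seed), out_dir / "positives.fasta"
    )
    neg_path = write_fasta(
        generate_sequences(neg_model, n_per_class, neg_seed), out_dir / "negatives.fasta"
    )
    manifest = {
        "bias": bias,
        "n_per_class": n_per_class,
        "seed": seed,
        "length_range": list(length_range),
        "positive_enriched": "".join(sorted(HYDROPHOBIC_RESIDUES)),
        "negative_enriched": "".join(sorted(POLAR_RESIDUES)),
        "positive_weights": list(pos_model.residue_weights),
        "negative_weights": list(neg_model.residue_weights),
        "files": {"positives": pos_path.name, "negatives": neg_path.name},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return pos_path, neg_path
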