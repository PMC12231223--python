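"""Uncorrected pairwise p-distance on aligned nucleotide sequences.

Conspecificity of barcode (COI) samples is commonly checked by the
proportion of differing sites between aligned sequences, without any
substitution-model correction.  This module reads an aligned FASTA,
computes the p-distance for every pair with per-pair accounting of
comparable sites, and reports the maximum divergence as a percentage.

Sites containing a gap in either sequence are always excluded.  Ambiguity
codes follow one of two policies: ``pairwise_delete`` (the conventional
default for uncorrected distances) also excludes any site with a
non-ACGT code in either sequence; ``mismatch_if_incompatible`` keeps such
sites and counts a mismatch only when the two codes' IUPAC base sets are
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .data import GeckodietError
from .composition import round_half_away

__all__ = [
    "AlignmentError",
    "AlignedSequences",
    "DistanceMatrix",
    "read_alignment",
    "p_distance",
    "distance_matrix",
    "max_divergence",
    "IUPAC_SETS",
]


class AlignmentError(GeckodietError):
    """Invalid alignment: ragged lengths, illegal characters, or too few records."""


#: IUPAC nucleotide codes mapped to the sets of bases they may represent.
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_ALPHABET = set(IUPAC_SETS) | {"-"}
_UNAMBIGUOUS = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class AlignedSequences:
    """An alignment as ordered (id, sequence) pairs of equal length."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 2:
            raise AlignmentError("alignment needs at least 2 sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        for rid, seq in self.records:
            for pos, ch in enumerate(seq):
                if ch not in _ALPHABET:
                    raise AlignmentError(
                        f"sequence {rid!r}: illegal character {ch!r} at column "
                        f"{pos + 1}"
                    )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(rid)


def read_alignment(path: str | Path) -> AlignedSequences:
    """Read an aligned FASTA; uppercases and maps U (RNA) to T."""
    records = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 FASTA records, got {len(records)}")
    return AlignedSequences(tuple(records))


def p_distance(
    seq_a: str, seq_b: str, ambiguity_policy: str = "pairwise_delete"
) -> tuple[float, int]:
    """Proportion of differing sites between two equal-length sequences.

    Returns ``(proportion, comparable_sites)``.  Gap columns are always
    excluded; under ``pairwise_delete`` so is any column with an ambiguity
    code, while ``mismatch_if_incompatible`` scores ambiguous columns as
    mismatches only when the codes share no possible base.
    """
    if ambiguity_policy not in ("pairwise_delete", "mismatch_if_incompatible"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise AlignmentError("sequences differ in length")
    comparable = 0
    mismatches = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        if ca in _UNAMBIGUOUS and cb in _UNAMBIGUOUS:
            comparable += 1
            if ca != cb:
                mismatches += 1
        elif ambiguity_policy == "mismatch_if_incompatible":
            comparable += 1
            if not (IUPAC_SETS[ca] & IUPAC_SETS[cb]):
                mismatches += 1
        # pairwise_delete: ambiguous column excluded
    if comparable == 0:
        raise AlignmentError("no comparable sites between sequences")
    return mismatches / comparable, comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    ids: tuple[str, ...]
    distances: np.ndarray       # proportions in [0, 1], zero diagonal
    comparable_sites: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=list(self.ids),
                            columns=list(self.ids))

    def tidy(self) -> pd.DataFrame:
        """Long form: one row per unordered pair (id_a, id_b, p_distance, sites)."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append((self.ids[i], self.ids[j],
                             float(self.distances[i, j]),
                             int(self.comparable_sites[i, j])))
        return pd.DataFrame(rows, columns=["id_a", "id_b", "p_distance",
                                           "comparable_sites"])

    def to_phylip(self) -> str:
        """PHYLIP-style square matrix as text."""
        lines = [f"{len(self.ids)}"]
        for i, rid in enumerate(self.ids):
            vals = " ".join(f"{d:.6f}" for d in self.distances[i])
            lines.append(f"{rid:<10s} {vals}")
        return "\n".join(lines) + "\n"


def distance_matrix(
    alignment: AlignedSequences, ambiguity_policy: str = "pairwise_delete"
) -> DistanceMatrix:
    """All-pairs p-distance matrix for an alignment."""
    n = len(alignment.records)
    d = np.zeros((n, n))
    sites = np.full((n, n), alignment.alignment_length, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            prop, comp = p_distance(alignment.records[i][1],
                                    alignment.records[j][1], ambiguity_policy)
            d[i, j] = d[j, i] = prop
            sites[i, j] = sites[j, i] = comp
    return DistanceMatrix(ids=alignment.ids, distances=d, comparable_sites=sites)


def max_divergence(
    alignment: AlignedSequences, ambiguity_policy: str = "pairwise_delete"
) -> tuple[float, tuple[str, str]]:
    """Maximum off-diagonal p-distance as a percent (2 decimals), with its pair.

    Ties resolve to the first pair in row-major order.
    """
    dm = distance_matrix(alignment, ambiguity_policy)
    n = len(dm.ids)
    best = (-1.0, ("", ""))
    for i in range(n):
        for j in range(i + 1, n):
            if dm.distances[i, j] > best[0]:
                best = (float(dm.distances[i, j]), (dm.ids[i], dm.ids[j]))
    return round_half_away(100.0 * best[0], 2), best[1]
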