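"""Sequence containers for taxon-pair population samples.

A *taxon pair* is one species sampled on both sides of a biogeographic
barrier: two population samples of aligned homologous sequences plus locus
metadata (alignment length, a locus-type mutation-rate multiplier).  All
statistics and simulations in this package operate on these objects.

Sequences are stored as ``int8`` matrices with the encoding
A=0, C=1, G=2, T=3, N=4, gap(-)=5.  Codes >= 4 are treated as missing and
excluded pairwise by the statistics.  Lowercase input is accepted and U is
mapped to T; IUPAC ambiguity codes other than N are rejected with their
location, so every downstream statistic is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaxonPair",
    "SequenceError",
    "encode_sequence",
    "encode_alignment",
    "decode_sequence",
    "MISSING_CODE",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_DECODE = "ACGTN-"
#: first code treated as missing data (N or gap)
MISSING_CODE = 4


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad symbol, ragged alignment)."""


def encode_sequence(seq: str, where: str = "") -> np.ndarray:
    """Encode one DNA string to int8 codes; U→T, case-insensitive."""
    s = seq.upper().replace("U", "T")
    out = np.empty(len(s), dtype=np.int8)
    for i, ch in enumerate(s):
        code = _CODE.get(ch)
        if code is None:
            loc = f" in {where}" if where else ""
            raise SequenceError(
                f"unsupported symbol {ch!r} at position {i + 1}{loc}; "
                "only A/C/G/T/U/N/- are accepted"
            )
        out[i] = code
    return out


def encode_alignment(seqs, where: str = "") -> np.ndarray:
    """Encode a list of equal-length strings (or pass through an int8 matrix)."""
    if isinstance(seqs, np.ndarray):
        arr = np.asarray(seqs, dtype=np.int8)
        if arr.ndim != 2:
            raise SequenceError(f"alignment array must be 2-D{': ' + where if where else ''}")
        return arr
    encoded = [encode_sequence(s, where=f"{where} sequence {i + 1}" if where else f"sequence {i + 1}")
               for i, s in enumerate(seqs)]
    lengths = {len(e) for e in encoded}
    if len(lengths) > 1:
        raise SequenceError(
            f"ragged alignment{' in ' + where if where else ''}: lengths {sorted(lengths)}"
        )
    if not encoded:
        return np.empty((0, 0), dtype=np.int8)
    return np.vstack(encoded)


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_DECODE[c] for c in np.asarray(codes, dtype=np.int8))


@dataclass
class TaxonPair:
    """One taxon pair: two population samples flanking a barrier.

    Parameters
    ----------
    pair_id, barrier_id
        Free-form labels (species and barrier names in a real study).
    pop1, pop2
        Aligned sequences per population; lists of strings or int8 matrices.
    rate_multiplier
        Locus mutation-rate scaling relative to the slow reference loci
        (mtDNA = 20, cpDNA/ITS = 1 in the default manifest convention).
    locus_type
        Optional label ("mtDNA", "cpDNA", "ITS", ...) carried through output.
    """

    pair_id: str
    barrier_id: str
    pop1: np.ndarray
    pop2: np.ndarray
    rate_multiplier: float = 1.0
    locus_type: str = ""
    seq_ids_1: list = field(default_factory=list)
    seq_ids_2: list = field(default_factory=list)

    def __post_init__(self):
        self.pop1 = encode_alignment(self.pop1, where=f"pair {self.pair_id} pop1")
        self.pop2 = encode_alignment(self.pop2, where=f"pair {self.pair_id} pop2")
        if self.pop1.shape[1] != self.pop2.shape[1]:
            raise SequenceError(
                f"pair {self.pair_id}: population alignments differ in length "
                f"({self.pop1.shape[1]} vs {self.pop2.shape[1]})"
            )
        if self.rate_multiplier <= 0:
            raise ValueError(f"pair {self.pair_id}: rate_multiplier must be > 0")
        if self.n1 < 2 or self.n2 < 2:
            warnings.warn(
                f"pair {self.pair_id}: sample sizes {self.n1}/{self.n2}; "
                "within-population statistics undefined for sides with < 2 sequences",
                stacklevel=2,
            )

    @property
    def n1(self) -> int:
        return self.pop1.shape[0]

    @property
    def n2(self) -> int:
        return self.pop2.shape[0]

    @property
    def length(self) -> int:
        return self.pop1.shape[1]

    # alias used throughout formulas
    @property
    def L(self) -> int:  # noqa: N802
        return self.pop1.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TaxonPair({self.pair_id!r}, barrier={self.barrier_id!r}, "
            f"n1={self.n1}, n2={self.n2}, L={self.L}, rho={self.rate_multiplier:g})"
        )
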