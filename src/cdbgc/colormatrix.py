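"""The color matrix in SPSS order.

Each union k-mer gets a rank: the number of k-mer windows strictly before its
window when simplitigs are scanned in record order, left to right.  The color
matrix lists the per-k-mer color vectors in that rank order.  Color vectors are
C-bit integers with color 0 as the most significant bit, so sorting vectors
numerically sorts them as the bitstrings read left-to-right.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Tuple

from .cdbg_io import CdbgInput, union_with_classes
from .spss import Spss, SpssError, _canon

__all__ = ["RankLookupError", "KmerRank", "ColorMatrix", "build_rank_index",
           "build_color_matrix", "vector_bits", "iter_ranked_kmers",
           "write_matrix_tsv"]


class RankLookupError(KeyError):
    """Queried k-mer is not part of the SPSS."""


def vector_bits(v: int, C: int) -> str:
    """Render a color vector as its C-char bitstring (color 0 leftmost)."""
    return format(v, f"0{C}b")


@dataclass
class KmerRank:
    """Bijection canonical k-mer -> rank in [0, |union|)."""

    ranks: Dict[str, int]

    def rank(self, kmer: str) -> int:
        try:
            return self.ranks[kmer]
        except KeyError:
            raise RankLookupError(f"k-mer {kmer!r} not present in the SPSS") from None

    def __len__(self) -> int:
        return len(self.ranks)


@dataclass
class ColorMatrix:
    """Per-k-mer color vectors in rank order."""

    rows: List[int]
    C: int

    def row_bits(self, r: int) -> str:
        return vector_bits(self.rows[r], self.C)


def iter_ranked_kmers(S: Spss) -> Iterator[str]:
    """Canonical k-mers of *S* in rank order (window canonicalized)."""
    k = S.k
    for s in S.simplitigs:
        for i in range(len(s) - k + 1):
            yield _canon(s[i : i + k])


def build_rank_index(S: Spss) -> KmerRank:
    """Rank every k-mer of the SPSS by (simplitig index, window offset)."""
    ranks: Dict[str, int] = {}
    for r, km in enumerate(iter_ranked_kmers(S)):
        if km in ranks:
            raise SpssError(f"k-mer {km!r} appears twice in the SPSS")
        ranks[km] = r
    return KmerRank(ranks)


def build_color_matrix(S: Spss, E: CdbgInput) -> ColorMatrix:
    """Color matrix of *E* in the k-mer order induced by *S*.

    *S* must be an SPSS of exactly the union k-mer set of *E*; any k-mer on
    one side only is reported by name.
    """
    mapping = union_with_classes(E)
    index = build_rank_index(S)
    rows = [0] * len(index)
    for km, r in index.ranks.items():
        v = mapping.get(km)
        if v is None:
            raise SpssError(f"SPSS contains k-mer {km!r} absent from the input")
        rows[r] = v
    if len(mapping) != len(index):
        missing = next(iter(set(mapping) - set(index.ranks)))
        raise SpssError(f"input k-mer {missing!r} is not covered by the SPSS")
    return ColorMatrix(rows, E.C)


def write_matrix_tsv(S: Spss, matrix: ColorMatrix, path) -> None:
    """Debug/interchange dump: one ``<kmer>\\t<bitstring>`` line per rank."""
    with open(path, "w") as fh:
        for km, v in zip(iter_ranked_kmers(S), matrix.rows):
            fh.write(f"{km}\t{vector_bits(v, matrix.C)}\n")
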