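"""Global class table: Huffman IDs for color classes and their serialization.

The M distinct color vectors of the matrix get prefix-free *global IDs* via
canonical Huffman coding over their k-mer frequencies, so frequent classes get
short IDs.  On disk the table is three artifacts:

* ``delta`` — the classes sorted ascending as C-bit integers; the first written
  verbatim in C bits, each later one as the ascending list of color indices
  where it differs from its predecessor, each index in ceil(log2 C) bits;
* ``boundary`` — a bitvector of the same length with a 1 wherever a class's
  encoding begins;
* the frequency list, aligned with the sorted order, stored as ASCII decimals.

Frequencies alone regenerate the exact same Huffman codes at decompression
time, so the codes themselves are never stored.  Determinism: frequency ties
merge smaller class values first, and codewords are assigned canonically
(shorter first, then by class value).
"""
from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .colormatrix import ColorMatrix

__all__ = ["ClassTableError", "GlobalClassTable", "GlobalTableSerialization",
           "class_frequencies", "assign_global_ids", "serialize_global_table",
           "deserialize_global_table", "index_width", "HuffmanDecoder"]


class ClassTableError(ValueError):
    """Inconsistent class-table serialization."""


def index_width(C: int) -> int:
    """Bits per color index in delta encoding: ceil(log2 C), floored at 1."""
    return max(1, (C - 1).bit_length())


def class_frequencies(matrix: ColorMatrix) -> Dict[int, int]:
    """Count the k-mers carrying each distinct color vector."""
    if not matrix.rows:
        raise ClassTableError("empty color matrix")
    return dict(Counter(matrix.rows))


def _huffman_lengths(freqs: Dict[int, int]) -> Dict[int, int]:
    """Optimal prefix code lengths; deterministic under frequency ties.

    Heap entries are (frequency, smallest class value in subtree, symbols);
    class values are distinct so the ordering is total.
    """
    if len(freqs) == 1:
        return {next(iter(freqs)): 0}
    heap: List[Tuple[int, int, Dict[int, int]]] = [
        (f, cls, {cls: 0}) for cls, f in freqs.items()
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        f1, m1, d1 = heapq.heappop(heap)
        f2, m2, d2 = heapq.heappop(heap)
        merged = {s: d + 1 for s, d in d1.items()}
        merged.update({s: d + 1 for s, d in d2.items()})
        heapq.heappush(heap, (f1 + f2, min(m1, m2), merged))
    return heap[0][2]


@dataclass
class GlobalClassTable:
    """Sorted class list, Huffman codes (global IDs) and class frequencies."""

    classes: List[int]          # ascending numeric (= bitstring) order
    codes: Dict[int, str]       # class value -> codeword; '' iff M == 1
    freqs: Dict[int, int]

    @property
    def M(self) -> int:
        return len(self.classes)

    def decoder(self) -> "HuffmanDecoder":
        return HuffmanDecoder(self)


class HuffmanDecoder:
    """Stream decoder for global IDs (prefix-free lookup)."""

    def __init__(self, table: GlobalClassTable):
        self._single = table.classes[0] if table.M == 1 else None
        self._by_code = {code: cls for cls, code in table.codes.items()}
        self._max_len = max((len(c) for c in table.codes.values()), default=0)

    def read(self, bits: str, pos: int) -> Tuple[int, int]:
        """Decode one global ID starting at *pos*; return (class, new pos)."""
        if self._single is not None:
            return self._single, pos
        end = pos
        limit = min(len(bits), pos + self._max_len)
        while end < limit:
            end += 1
            cls = self._by_code.get(bits[pos:end])
            if cls is not None:
                return cls, end
        raise ClassTableError("bit stream exhausted while decoding a global ID")


def assign_global_ids(freqs: Dict[int, int]) -> GlobalClassTable:
    """Build the canonical Huffman table for a class-frequency map.

    With a single class the codeword is empty (zero bits): a store-ID encoding
    then costs only its type bit.
    """
    if not freqs:
        raise ClassTableError("no color classes")
    lengths = _huffman_lengths(freqs)
    ordered = sorted(lengths, key=lambda cls: (lengths[cls], cls))
    codes: Dict[int, str] = {}
    code = 0
    prev_len = lengths[ordered[0]]
    for pos, cls in enumerate(ordered):
        L = lengths[cls]
        if pos:
            code = (code + 1) << (L - prev_len)
        codes[cls] = format(code, f"0{L}b") if L else ""
        prev_len = L
    return GlobalClassTable(sorted(freqs), codes, dict(freqs))


@dataclass
class GlobalTableSerialization:
    """On-disk form of the table: delta bits, boundary bits, frequency list."""

    delta: str
    boundary: str
    freq_list: List[int]


def serialize_global_table(t: GlobalClassTable, C: int) -> GlobalTableSerialization:
    delta_parts: List[str] = []
    boundary_parts: List[str] = []
    w = index_width(C)
    prev = None
    for cls in t.classes:
        if prev is None:
            part = format(cls, f"0{C}b")
        else:
            diff = prev ^ cls
            part = "".join(
                format(i, f"0{w}b") for i in range(C) if diff >> (C - 1 - i) & 1
            )
        delta_parts.append(part)
        boundary_parts.append("1" + "0" * (len(part) - 1))
        prev = cls
    return GlobalTableSerialization(
        "".join(delta_parts),
        "".join(boundary_parts),
        [t.freqs[cls] for cls in t.classes],
    )


def deserialize_global_table(s: GlobalTableSerialization, C: int) -> GlobalClassTable:
    """Rebuild the table (classes and byte-identical Huffman codes) from disk."""
    if len(s.delta) != len(s.boundary):
        raise ClassTableError(
            f"delta/boundary length mismatch: {len(s.delta)} vs {len(s.boundary)}"
        )
    if not s.boundary or s.boundary[0] != "1":
        raise ClassTableError("boundary bitvector must start with 1")
    starts = [i for i, b in enumerate(s.boundary) if b == "1"]
    if len(starts) != len(s.freq_list):
        raise ClassTableError(
            f"{len(starts)} classes in boundary but {len(s.freq_list)} frequencies"
        )
    w = index_width(C)
    classes: List[int] = []
    bounds = starts + [len(s.delta)]
    for j in range(len(starts)):
        seg = s.delta[bounds[j] : bounds[j + 1]]
        if j == 0:
            if len(seg) != C:
                raise ClassTableError(f"first class occupies {len(seg)} bits, expected C={C}")
            classes.append(int(seg, 2))
        else:
            if len(seg) % w:
                raise ClassTableError(f"class {j}: delta segment of {len(seg)} bits not a multiple of {w}")
            v = classes[-1]
            flips = set()
            for o in range(0, len(seg), w):
                i = int(seg[o : o + w], 2)
                if i >= C or i in flips:
                    raise ClassTableError(f"class {j}: bad difference index {i}")
                flips.add(i)
                v ^= 1 << (C - 1 - i)
            classes.append(v)
    if any(a >= b for a, b in zip(classes, classes[1:])):
        raise ClassTableError("reconstructed classes are not strictly ascending")
    return assign_global_ids(dict(zip(classes, s.freq_list)))
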