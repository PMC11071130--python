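"""Per-simplitig encoding of the class sequence into the m bitvector.

Scanning a simplitig left to right, each k-mer is emitted with one of four
encodings, selected by fixed rules given the per-simplitig parameters
``maxDif`` (0..2) and ``useLocalID``:

* **Skip** — interior k-mer whose class equals both neighbours: nothing is
  appended.
* **Small class difference** — Hamming distance h to the previous k-mer's
  vector satisfies 0 < h <= maxDif: type ``10``, one extra bit distinguishing
  h=1/h=2 when maxDif==2, then the h differing color indices, each in
  ceil(log2 C) bits.
* **End of run** — class equals the previous k-mer's and the run ends here
  (different successor, or last k-mer): type ``11`` (just ``1`` when
  maxDif==0, where only two encodings exist), then the run length in
  quotient/remainder form: runLen = number of consecutive same-class
  predecessors, q = runLen // runDivisor in unary (q ones, then a zero),
  r = runLen % runDivisor in exactly log2(runDivisor) bits.
* **Store class ID** — every other case, in particular the first k-mer:
  type ``0``, then the class's global (Huffman) ID, or its local ID in
  ceil(log2 l) fixed bits when useLocalID is set.

A decoder needs only the simplitig's k-mer count (recovered from simplitig
lengths), the global table, and the local table if present; at a run marker it
emits runLen k-mers — the skipped interior plus the run closer, the opener
having been emitted by its own store/diff encoding.

The six (maxDif, useLocalID) combinations are all evaluated per simplitig and
the cheapest kept (ties: smaller maxDif, then no local table); cost is
3 metadata bits + |m| + the serialized local table, if any.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .classtable import ClassTableError, GlobalClassTable, HuffmanDecoder, index_width

__all__ = ["CodecError", "SimplitigMeta", "LocalClassTable", "MVector",
           "EncodingChoice", "encode_run_length", "decode_run_length",
           "diff_indices", "encode_simplitig", "decode_simplitig",
           "choose_encoding", "local_table_bits", "encode_local_table",
           "decode_local_table", "local_len_width"]


class CodecError(ValueError):
    """Corrupt or inconsistent m-vector / local-table bits."""


@dataclass(frozen=True)
class SimplitigMeta:
    """Per-simplitig mode: maxDif in {0,1,2} and the local-ID flag."""

    max_dif: int
    use_local_id: bool

    def __post_init__(self) -> None:
        if self.max_dif not in (0, 1, 2):
            raise ValueError(f"maxDif must be 0, 1 or 2, got {self.max_dif}")

    def to_bits(self) -> str:
        # bit 2 = useLocalID, bits 1..0 = maxDif (11 reserved)
        return ("1" if self.use_local_id else "0") + format(self.max_dif, "02b")

    @classmethod
    def from_bits(cls, bits: str) -> "SimplitigMeta":
        if len(bits) != 3:
            raise CodecError(f"metadata must be 3 bits, got {len(bits)}")
        max_dif = int(bits[1:], 2)
        if max_dif == 3:
            raise CodecError("metadata maxDif value 3 is reserved")
        return cls(max_dif, bits[0] == "1")


@dataclass
class LocalClassTable:
    """Distinct classes of one simplitig, in first-appearance order.

    Local ID i refers to entries[i]; IDs are fixed-width ceil(log2 l) bits
    (zero bits when l == 1).
    """

    entries: List[int]

    @property
    def ell(self) -> int:
        return len(self.entries)

    @property
    def id_width(self) -> int:
        return (self.ell - 1).bit_length()


@dataclass
class MVector:
    """The encoded bit sequence of one simplitig's class sequence."""

    bits: str
    n_kmers: int


def encode_run_length(run_len: int, run_divisor: int) -> str:
    """Quotient in unary (ones, then a zero), remainder in log2(divisor) bits."""
    if run_divisor < 2 or run_divisor & (run_divisor - 1):
        raise ValueError(f"runDivisor must be a power of two >= 2, got {run_divisor}")
    q, r = divmod(run_len, run_divisor)
    width = run_divisor.bit_length() - 1
    return "1" * q + "0" + format(r, f"0{width}b")


def decode_run_length(bits: str, pos: int, run_divisor: int) -> Tuple[int, int]:
    """Inverse of :func:`encode_run_length`; returns (runLen, new position)."""
    if run_divisor < 2 or run_divisor & (run_divisor - 1):
        raise ValueError(f"runDivisor must be a power of two >= 2, got {run_divisor}")
    q = 0
    n = len(bits)
    while pos < n and bits[pos] == "1":
        q += 1
        pos += 1
    if pos >= n:
        raise CodecError("bit stream exhausted inside a unary quotient")
    pos += 1  # the terminating zero
    width = run_divisor.bit_length() - 1
    if pos + width > n:
        raise CodecError("bit stream exhausted inside a run remainder")
    r = int(bits[pos : pos + width], 2)
    return q * run_divisor + r, pos + width


def diff_indices(prev: int, cur: int, C: int) -> List[int]:
    """Ascending 0-based color indices where two vectors differ (color 0 = MSB)."""
    x = prev ^ cur
    return [i for i in range(C) if x >> (C - 1 - i) & 1]


def local_len_width(M: int) -> int:
    """Bits used to store l-1 on disk: ceil(log2 M), floored at 1."""
    return max(1, (M - 1).bit_length())


def local_table_bits(local: LocalClassTable, table: GlobalClassTable) -> int:
    """Serialized size of a local table: the l-1 field plus the l global IDs."""
    return local_len_width(table.M) + sum(len(table.codes[c]) for c in local.entries)


def encode_local_table(local: LocalClassTable, table: GlobalClassTable) -> str:
    return format(local.ell - 1, f"0{local_len_width(table.M)}b") + "".join(
        table.codes[c] for c in local.entries
    )


def decode_local_table(bits: str, pos: int, table: GlobalClassTable) -> Tuple[LocalClassTable, int]:
    w = local_len_width(table.M)
    if pos + w > len(bits):
        raise CodecError("bit stream exhausted inside a local-table length field")
    ell = int(bits[pos : pos + w], 2) + 1
    pos += w
    dec = table.decoder()
    entries: List[int] = []
    for _ in range(ell):
        cls, pos = dec.read(bits, pos)
        entries.append(cls)
    if len(set(entries)) != ell:
        raise CodecError("local table entries are not distinct")
    return LocalClassTable(entries), pos


def _first_appearance_order(class_seq: List[int]) -> List[int]:
    seen: Dict[int, None] = {}
    for c in class_seq:
        seen.setdefault(c)
    return list(seen)


def encode_simplitig(
    class_seq: List[int],
    meta: SimplitigMeta,
    table: GlobalClassTable,
    run_divisor: int = 16,
    C: Optional[int] = None,
) -> Tuple[MVector, Optional[LocalClassTable]]:
    """Encode one simplitig's class sequence under a fixed mode.

    *C* defaults to the bit width implied by the largest class in the table;
    passing it explicitly is required whenever the leading color(s) could be
    absent from every class.
    """
    if not class_seq:
        raise CodecError("empty class sequence")
    if C is None:
        C = max(table.classes).bit_length() or 1
    for c in class_seq:
        if c not in table.codes:
            raise CodecError(f"class {c} missing from the global table")

    local: Optional[LocalClassTable] = None
    if meta.use_local_id:
        local = LocalClassTable(_first_appearance_order(class_seq))
        lw = local.id_width
        local_ids = {c: i for i, c in enumerate(local.entries)}

        def id_bits(c: int) -> str:
            return format(local_ids[c], f"0{lw}b") if lw else ""
    else:
        codes = table.codes

        def id_bits(c: int) -> str:
            return codes[c]

    wC = index_width(C)
    run_type = "11" if meta.max_dif else "1"
    n = len(class_seq)
    parts: List[str] = []
    run_count = 0  # consecutive predecessors sharing the current class
    for i, cls in enumerate(class_seq):
        if i == 0:
            parts.append("0" + id_bits(cls))
            run_count = 0
            continue
        prev = class_seq[i - 1]
        if cls == prev:
            run_count += 1
            if i + 1 < n and class_seq[i + 1] == cls:
                continue  # Skip
            parts.append(run_type + encode_run_length(run_count, run_divisor))
            continue
        run_count = 0
        h = (prev ^ cls).bit_count()
        if 0 < h <= meta.max_dif:
            t = "10"
            if meta.max_dif == 2:
                t += "1" if h == 2 else "0"
            parts.append(t + "".join(format(j, f"0{wC}b") for j in diff_indices(prev, cls, C)))
        else:
            parts.append("0" + id_bits(cls))
    return MVector("".join(parts), n), local


def decode_simplitig(
    bits: str,
    pos: int,
    meta: SimplitigMeta,
    table: GlobalClassTable,
    local: Optional[LocalClassTable],
    n_kmers: int,
    C: int,
    run_divisor: int = 16,
) -> Tuple[List[int], int]:
    """Decode exactly *n_kmers* classes from *bits* starting at *pos*.

    Exact inverse of :func:`encode_simplitig`; returns the class list and the
    cursor position one past the simplitig's last bit.
    """
    if meta.use_local_id:
        if local is None:
            raise CodecError("metadata demands a local table but none was given")
        lw = local.id_width
        entries = local.entries

        def read_id(p: int) -> Tuple[int, int]:
            if lw == 0:
                return entries[0], p
            if p + lw > len(bits):
                raise CodecError("bit stream exhausted inside a local ID")
            idx = int(bits[p : p + lw], 2)
            if idx >= len(entries):
                raise CodecError(f"local ID {idx} out of range (l={len(entries)})")
            return entries[idx], p + lw
    else:
        dec = table.decoder()

        def read_id(p: int) -> Tuple[int, int]:
            try:
                return dec.read(bits, p)
            except ClassTableError as e:
                raise CodecError(str(e)) from None

    wC = index_width(C)
    out: List[int] = []
    n = len(bits)
    while len(out) < n_kmers:
        if pos >= n:
            raise CodecError("bit stream exhausted before the class sequence completed")
        if bits[pos] == "0":  # Store class ID
            cls, pos = read_id(pos + 1)
            out.append(cls)
            continue
        if meta.max_dif == 0:
            kind = "run"
            pos += 1
        else:
            if pos + 1 >= n:
                raise CodecError("bit stream exhausted inside a type field")
            kind = "run" if bits[pos + 1] == "1" else "diff"
            pos += 2
        if kind == "diff":
            if not out:
                raise CodecError("difference encoding before any class was established")
            h = 1
            if meta.max_dif == 2:
                if pos >= n:
                    raise CodecError("bit stream exhausted inside an h flag")
                h = 2 if bits[pos] == "1" else 1
                pos += 1
            v = out[-1]
            for _ in range(h):
                if pos + wC > n:
                    raise CodecError("bit stream exhausted inside a difference index")
                j = int(bits[pos : pos + wC], 2)
                if j >= C:
                    raise CodecError(f"difference index {j} out of range (C={C})")
                v ^= 1 << (C - 1 - j)
                pos += wC
            out.append(v)
        else:  # End of run
            if not out:
                raise CodecError("run marker before any class was established")
            run_len, pos = decode_run_length(bits, pos, run_divisor)
            if run_len == 0:
                raise CodecError("run marker with runLen 0")
            out.extend([out[-1]] * run_len)
    if len(out) != n_kmers:
        raise CodecError(
            f"decoded {len(out)} k-mers where the simplitig holds {n_kmers}"
        )
    return out, pos


@dataclass
class EncodingChoice:
    """Winner of the six-way per-simplitig mode search."""

    meta: SimplitigMeta
    m: MVector
    local: Optional[LocalClassTable]
    total_bits: int


def choose_encoding(
    class_seq: List[int],
    table: GlobalClassTable,
    run_divisor: int = 16,
    C: Optional[int] = None,
) -> EncodingChoice:
    """Try all six (maxDif, useLocalID) modes and keep the cheapest encoding.

    Cost of a candidate = 3 metadata bits + |m| + its serialized local table
    (if any).  Ties go to the smaller maxDif, then to useLocalID=False, which
    the iteration order realizes with a strict comparison.
    """
    best: Optional[EncodingChoice] = None
    for max_dif in (0, 1, 2):
        for use_local in (False, True):
            meta = SimplitigMeta(max_dif, use_local)
            m, local = encode_simplitig(class_seq, meta, table, run_divisor, C)
            cost = 3 + len(m.bits)
            if local is not None:
                cost += local_table_bits(local, table)
            if best is None or cost < best.total_bits:
                best = EncodingChoice(meta, m, local, cost)
    assert best is not None
    return best
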