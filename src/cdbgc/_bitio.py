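"""Bit-string packing helpers.

Bit sequences are plain Python strings over {'0','1'}; they are packed into
bytes MSB-first within each byte and zero-padded to a byte boundary, which is
the convention used by every bit-carrying archive section.
"""
from __future__ import annotations


def pack_bits(bits: str) -> bytes:
    """Pack a '0'/'1' string into bytes, MSB-first, zero-padded on the right."""
    if not bits:
        return b""
    nbytes = (len(bits) + 7) // 8
    value = int(bits, 2) << (nbytes * 8 - len(bits))
    return value.to_bytes(nbytes, "big")


def unpack_bits(data: bytes, nbits: int) -> str:
    """Inverse of :func:`pack_bits`; *nbits* selects the meaningful prefix."""
    if nbits == 0:
        return ""
    total = len(data) * 8
    if nbits > total:
        raise ValueError(f"requested {nbits} bits from {total}-bit buffer")
    return format(int.from_bytes(data, "big"), f"0{total}b")[:nbits]
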