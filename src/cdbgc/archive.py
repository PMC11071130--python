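"""Self-describing binary container and the end-to-end compress/decompress.

Layout (all integers little-endian):

    magic "CDBC" | version u8 | k u32 | C u32 | M u32 | runDivisor u32 |
    n_simplitigs u32 | n_kmers u64 |
    7 x section directory entry: codec u8, raw_len u64, stored_len u64,
      crc32(raw) u32 |
    7 x section payload, in directory order.

Sections, in order: SPSSDATA (the simplitig FASTA text), DELTA and BOUNDARY
(global-table delta coding), FREQS (ASCII class frequencies, one per line),
META (3 bits per simplitig), LOCAL (concatenated local tables of the
simplitigs that use one), MBITS (concatenated m vectors).  Bit-carrying
sections store a u64 bit count followed by the MSB-first packed bits.  Every
section is post-compressed with DEFLATE when that is smaller than the raw
payload (codec 1), and stored raw otherwise (codec 0).

The archive is deterministic: identical input and parameters give identical
bytes.  Decompression restores the simplitigs and the exact k-mer to
color-vector mapping; nothing here supports queries on the compressed file.
"""
from __future__ import annotations

import io
import struct
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

from Bio import SeqIO

from . import mcodec
from ._bitio import pack_bits, unpack_bits
from .cdbg_io import CdbgInput, union_with_classes
from .classtable import (GlobalTableSerialization, assign_global_ids,
                         class_frequencies, deserialize_global_table,
                         serialize_global_table)
from .colormatrix import (ColorMatrix, build_color_matrix, iter_ranked_kmers,
                          vector_bits, write_matrix_tsv)
from .spss import Spss, build_simplitigs, write_spss

__all__ = ["ArchiveError", "ArchiveFormatError", "SECTIONS", "pack_section",
           "unpack_section", "build_archive_bytes", "compress", "read_archive",
           "decompress", "verify_roundtrip", "archive_stats",
           "CompressionReport", "DecompressResult", "RoundtripReport",
           "ArchiveStats"]

MAGIC = b"CDBC"
VERSION = 1
SECTIONS = ("SPSSDATA", "DELTA", "BOUNDARY", "FREQS", "META", "LOCAL", "MBITS")
_BIT_SECTIONS = {"DELTA", "BOUNDARY", "META", "LOCAL", "MBITS"}

_HEADER = struct.Struct("<4sBIIIIIQ")
_DIRENT = struct.Struct("<BQQI")

CODEC_RAW = 0
CODEC_DEFLATE = 1


class ArchiveError(ValueError):
    """Archive-level failure (pipeline input, verification)."""


class ArchiveFormatError(ArchiveError):
    """Malformed, truncated or corrupt archive file."""


def pack_section(raw: bytes, codec: int) -> bytes:
    if codec == CODEC_RAW:
        return raw
    if codec == CODEC_DEFLATE:
        return zlib.compress(raw, 9)
    raise ArchiveFormatError(f"unknown codec id {codec}")


def unpack_section(stored: bytes, codec: int) -> bytes:
    if codec == CODEC_RAW:
        return stored
    if codec == CODEC_DEFLATE:
        try:
            return zlib.decompress(stored)
        except zlib.error as e:
            raise ArchiveFormatError(f"DEFLATE section corrupt: {e}") from None
    raise ArchiveFormatError(f"unknown codec id {codec}")


def _best_codec(raw: bytes) -> Tuple[int, bytes]:
    packed = zlib.compress(raw, 9)
    if len(packed) < len(raw):
        return CODEC_DEFLATE, packed
    return CODEC_RAW, raw


def _bit_payload(bits: str) -> bytes:
    return struct.pack("<Q", len(bits)) + pack_bits(bits)


def _payload_bits(raw: bytes, name: str) -> str:
    if len(raw) < 8:
        raise ArchiveFormatError(f"section {name}: missing bit-count prefix")
    (nbits,) = struct.unpack_from("<Q", raw)
    body = raw[8:]
    if (nbits + 7) // 8 != len(body):
        raise ArchiveFormatError(
            f"section {name}: {nbits} bits do not fit {len(body)} payload bytes"
        )
    return unpack_bits(body, nbits)


@dataclass
class CompressionReport:
    """What one compression run produced, before and after byte compression."""

    k: int
    C: int
    M: int
    run_divisor: int
    n_simplitigs: int
    n_kmers: int
    archive_bytes: int
    section_raw_bytes: Dict[str, int]
    section_stored_bytes: Dict[str, int]
    color_payload_bits: int       # MBITS+META+LOCAL+DELTA+BOUNDARY+FREQS, raw
    mode_counts: Dict[Tuple[int, bool], int]

    @property
    def naive_matrix_bits(self) -> int:
        """Cost of the uncompressed color matrix: C bits per union k-mer."""
        return self.C * self.n_kmers


def build_archive_bytes(E: CdbgInput, run_divisor: int = 16) -> Tuple[bytes, CompressionReport]:
    """Run the whole pipeline in memory; returns archive bytes and a report."""
    mapping = union_with_classes(E)
    if not mapping:
        raise ArchiveError("input holds no k-mers")
    S = build_simplitigs(set(mapping), E.k)
    matrix = build_color_matrix(S, E)
    table = assign_global_ids(class_frequencies(matrix))
    ser = serialize_global_table(table, E.C)

    meta_parts: List[str] = []
    local_parts: List[str] = []
    m_parts: List[str] = []
    mode_counts: Dict[Tuple[int, bool], int] = {}
    offset = 0
    for s in S.simplitigs:
        n = len(s) - E.k + 1
        choice = mcodec.choose_encoding(
            matrix.rows[offset : offset + n], table, run_divisor, E.C
        )
        offset += n
        meta_parts.append(choice.meta.to_bits())
        if choice.local is not None:
            local_parts.append(mcodec.encode_local_table(choice.local, table))
        m_parts.append(choice.m.bits)
        key = (choice.meta.max_dif, choice.meta.use_local_id)
        mode_counts[key] = mode_counts.get(key, 0) + 1

    fasta_buf = io.StringIO()
    write_spss_text(S, fasta_buf)
    freq_text = "".join(f"{f}\n" for f in ser.freq_list)
    raw = {
        "SPSSDATA": fasta_buf.getvalue().encode(),
        "DELTA": _bit_payload(ser.delta),
        "BOUNDARY": _bit_payload(ser.boundary),
        "FREQS": freq_text.encode(),
        "META": _bit_payload("".join(meta_parts)),
        "LOCAL": _bit_payload("".join(local_parts)),
        "MBITS": _bit_payload("".join(m_parts)),
    }

    dirents = []
    payloads = []
    for name in SECTIONS:
        codec, stored = _best_codec(raw[name])
        dirents.append(_DIRENT.pack(codec, len(raw[name]), len(stored), zlib.crc32(raw[name])))
        payloads.append(stored)
    header = _HEADER.pack(
        MAGIC, VERSION, E.k, E.C, table.M, run_divisor, len(S.simplitigs), S.n_kmers
    )
    blob = header + b"".join(dirents) + b"".join(payloads)

    color_bits = (
        sum(len(p) for p in m_parts)
        + 3 * len(S.simplitigs)
        + sum(len(p) for p in local_parts)
        + len(ser.delta)
        + len(ser.boundary)
        + 8 * len(raw["FREQS"])
    )
    report = CompressionReport(
        k=E.k, C=E.C, M=table.M, run_divisor=run_divisor,
        n_simplitigs=len(S.simplitigs), n_kmers=S.n_kmers,
        archive_bytes=len(blob),
        section_raw_bytes={n: len(raw[n]) for n in SECTIONS},
        section_stored_bytes={n: len(p) for n, p in zip(SECTIONS, payloads)},
        color_payload_bits=color_bits,
        mode_counts=mode_counts,
    )
    return blob, report


def write_spss_text(S: Spss, handle) -> None:
    """FASTA text of an Spss into a text handle (wrap-free records)."""
    for i, s in enumerate(S.simplitigs):
        handle.write(f">simplitig_{i}\n{s}\n")


def compress(E: CdbgInput, out_path, run_divisor: int = 16) -> CompressionReport:
    """Compress a colored de Bruijn graph to an archive file."""
    blob, report = build_archive_bytes(E, run_divisor)
    with open(out_path, "wb") as fh:
        fh.write(blob)
    return report


@dataclass
class RawArchive:
    """Parsed container: header fields plus decoded raw section payloads."""

    k: int
    C: int
    M: int
    run_divisor: int
    n_simplitigs: int
    n_kmers: int
    codecs: Dict[str, int]
    raw: Dict[str, bytes]
    stored_bytes: Dict[str, int]


def read_archive(path) -> RawArchive:
    """Read and validate the container (magic, version, CRCs, framing)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _HEADER.size + 7 * _DIRENT.size:
        raise ArchiveFormatError("archive truncated inside the header")
    magic, version, k, C, M, run_divisor, n_simplitigs, n_kmers = _HEADER.unpack_from(data)
    if magic != MAGIC:
        raise ArchiveFormatError(f"bad magic {magic!r}")
    if version != VERSION:
        raise ArchiveFormatError(f"unsupported format version {version}")
    pos = _HEADER.size
    entries = []
    for name in SECTIONS:
        codec, raw_len, stored_len, crc = _DIRENT.unpack_from(data, pos)
        pos += _DIRENT.size
        entries.append((name, codec, raw_len, stored_len, crc))
    raw: Dict[str, bytes] = {}
    codecs: Dict[str, int] = {}
    stored_sizes: Dict[str, int] = {}
    for name, codec, raw_len, stored_len, crc in entries:
        stored = data[pos : pos + stored_len]
        if len(stored) != stored_len:
            raise ArchiveFormatError(f"archive truncated inside section {name}")
        pos += stored_len
        payload = unpack_section(stored, codec)
        if len(payload) != raw_len:
            raise ArchiveFormatError(
                f"section {name}: raw length {len(payload)} != recorded {raw_len}"
            )
        if zlib.crc32(payload) != crc:
            raise ArchiveFormatError(f"section {name}: CRC mismatch")
        raw[name] = payload
        codecs[name] = codec
        stored_sizes[name] = stored_len
    if pos != len(data):
        raise ArchiveFormatError(f"{len(data) - pos} trailing bytes after the last section")
    return RawArchive(k, C, M, run_divisor, n_simplitigs, n_kmers,
                      codecs, raw, stored_sizes)


@dataclass
class DecompressResult:
    """Recovered SPSS and color matrix; streams k-mers in rank order."""

    spss: Spss
    matrix: ColorMatrix

    def iter_kmers(self) -> Iterator[Tuple[str, int]]:
        return zip(iter_ranked_kmers(self.spss), self.matrix.rows)

    def mapping(self) -> Dict[str, int]:
        return dict(self.iter_kmers())

    def write_spss(self, path) -> None:
        write_spss(self.spss, path)

    def write_matrix(self, path) -> None:
        write_matrix_tsv(self.spss, self.matrix, path)


def decompress(path) -> DecompressResult:
    """Restore the simplitigs and the exact k-mer -> color-vector mapping."""
    arc = read_archive(path)

    fasta = arc.raw["SPSSDATA"].decode()
    sims: List[str] = []
    for rec in SeqIO.parse(io.StringIO(fasta), "fasta"):
        s = str(rec.seq).upper()
        if len(s) < arc.k:
            raise ArchiveFormatError(f"simplitig {rec.id!r} shorter than k={arc.k}")
        sims.append(s)
    S = Spss(sims, arc.k)
    if len(sims) != arc.n_simplitigs:
        raise ArchiveFormatError(
            f"{len(sims)} simplitigs stored, header claims {arc.n_simplitigs}"
        )
    if S.n_kmers != arc.n_kmers:
        raise ArchiveFormatError(
            f"{S.n_kmers} k-mer windows, header claims {arc.n_kmers}"
        )

    ser = GlobalTableSerialization(
        _payload_bits(arc.raw["DELTA"], "DELTA"),
        _payload_bits(arc.raw["BOUNDARY"], "BOUNDARY"),
        [int(line) for line in arc.raw["FREQS"].decode().split()],
    )
    table = deserialize_global_table(ser, arc.C)
    if table.M != arc.M:
        raise ArchiveFormatError(f"table holds {table.M} classes, header claims {arc.M}")

    meta_bits = _payload_bits(arc.raw["META"], "META")
    if len(meta_bits) != 3 * arc.n_simplitigs:
        raise ArchiveFormatError("META section length does not match simplitig count")
    metas = [
        mcodec.SimplitigMeta.from_bits(meta_bits[3 * i : 3 * i + 3])
        for i in range(arc.n_simplitigs)
    ]

    local_bits = _payload_bits(arc.raw["LOCAL"], "LOCAL")
    m_bits = _payload_bits(arc.raw["MBITS"], "MBITS")
    rows: List[int] = []
    lpos = mpos = 0
    try:
        for s, meta in zip(sims, metas):
            local = None
            if meta.use_local_id:
                local, lpos = mcodec.decode_local_table(local_bits, lpos, table)
            seq, mpos = mcodec.decode_simplitig(
                m_bits, mpos, meta, table, local,
                len(s) - arc.k + 1, arc.C, arc.run_divisor,
            )
            rows.extend(seq)
    except mcodec.CodecError as e:
        raise ArchiveFormatError(f"m-vector decode failed: {e}") from None
    if mpos != len(m_bits):
        raise ArchiveFormatError(f"{len(m_bits) - mpos} unconsumed bits in MBITS")
    if lpos != len(local_bits):
        raise ArchiveFormatError(f"{len(local_bits) - lpos} unconsumed bits in LOCAL")
    return DecompressResult(S, ColorMatrix(rows, arc.C))


@dataclass
class RoundtripReport:
    """Comparison of an archive against the input it should encode."""

    n_compared: int
    missing: List[str] = field(default_factory=list)   # in input, not in archive
    extra: List[str] = field(default_factory=list)     # in archive, not in input
    first_divergence: Optional[Tuple[str, str, str]] = None  # kmer, want, got

    @property
    def ok(self) -> bool:
        return not (self.missing or self.extra or self.first_divergence)


def verify_roundtrip(E: CdbgInput, path) -> RoundtripReport:
    """Check that the archive restores exactly the union mapping of *E*."""
    want = union_with_classes(E)
    got = decompress(path).mapping()
    report = RoundtripReport(n_compared=len(want))
    report.missing = sorted(set(want) - set(got))[:20]
    report.extra = sorted(set(got) - set(want))[:20]
    for km in sorted(set(want) & set(got)):
        if want[km] != got[km]:
            report.first_divergence = (
                km, vector_bits(want[km], E.C), vector_bits(got[km], E.C)
            )
            break
    return report


@dataclass
class ArchiveStats:
    """Per-section and per-mode breakdown of an existing archive."""

    k: int
    C: int
    M: int
    run_divisor: int
    n_simplitigs: int
    n_kmers: int
    section_raw_bytes: Dict[str, int]
    section_stored_bytes: Dict[str, int]
    codecs: Dict[str, int]
    mode_counts: Dict[Tuple[int, bool], int]

    @property
    def total_stored_bytes(self) -> int:
        return sum(self.section_stored_bytes.values())


def archive_stats(path) -> ArchiveStats:
    arc = read_archive(path)
    meta_bits = _payload_bits(arc.raw["META"], "META")
    mode_counts: Dict[Tuple[int, bool], int] = {}
    for i in range(arc.n_simplitigs):
        meta = mcodec.SimplitigMeta.from_bits(meta_bits[3 * i : 3 * i + 3])
        key = (meta.max_dif, meta.use_local_id)
        mode_counts[key] = mode_counts.get(key, 0) + 1
    return ArchiveStats(
        k=arc.k, C=arc.C, M=arc.M, run_divisor=arc.run_divisor,
        n_simplitigs=arc.n_simplitigs, n_kmers=arc.n_kmers,
        section_raw_bytes={n: len(arc.raw[n]) for n in SECTIONS},
        section_stored_bytes=dict(arc.stored_bytes),
        codecs=dict(arc.codecs),
        mode_counts=mode_counts,
    )
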