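"""cdbgc — lossless disk compression for colored de Bruijn graphs.

A colored de Bruijn graph is a family of canonical k-mer sets, one per color
(sample, genome, experiment).  cdbgc stores it as a spectrum-preserving string
set of the union k-mers plus a compressed color matrix: Huffman-coded global
class IDs, a delta-coded class table, optional per-simplitig local class
tables, and a per-simplitig bitvector built from four k-mer encodings chosen
by a six-way mode search.  Decompression restores the exact k-mer to
color-class mapping.
"""
from .archive import (archive_stats, compress, decompress, verify_roundtrip)
from .cdbg_io import (CdbgInput, ColorKmerSet, canonicalize, count_color,
                      extract_kmers, load_cdbg, union_with_classes)
from .classtable import (assign_global_ids, class_frequencies,
                         deserialize_global_table, serialize_global_table)
from .colormatrix import build_color_matrix, build_rank_index
from .mcodec import (choose_encoding, decode_run_length, decode_simplitig,
                     diff_indices, encode_run_length, encode_simplitig)
from .spss import Spss, build_simplitigs, read_spss, validate_spss, write_spss
from .synthio import SyntheticCdbgSpec, generate_cdbg, sharing_stats

__version__ = "1.0.0"

__all__ = [
    "CdbgInput", "ColorKmerSet", "Spss", "SyntheticCdbgSpec",
    "archive_stats", "assign_global_ids", "build_color_matrix",
    "build_rank_index", "build_simplitigs", "canonicalize",
    "choose_encoding", "class_frequencies", "compress", "count_color",
    "decode_run_length", "decode_simplitig", "decompress",
    "deserialize_global_table", "diff_indices", "encode_run_length",
    "encode_simplitig", "extract_kmers", "generate_cdbg", "load_cdbg",
    "read_spss", "serialize_global_table", "sharing_stats",
    "union_with_classes", "validate_spss", "verify_roundtrip", "write_spss",
]
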