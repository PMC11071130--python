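"""Reading colored k-mer sets.

A colored de Bruijn graph is a family ``E = {E_0, ..., E_{C-1}}`` of canonical
k-mer sets, one per color.  Colors are loaded from FASTA files (k-mers counted
in-process with an abundance threshold ``a``) or from plain-text ``.kmers``
lists (one k-mer per line, taken verbatim after canonicalization).  A manifest
file assigns files to colors: one line per color, whitespace-separated paths,
the 0-based line number being the color index.

The union view maps every k-mer of ``E`` to its *color vector*: a C-bit value
whose bit for color ``i`` is set iff the k-mer belongs to ``E_i``.  Color 0 is
the leftmost, most-significant bit throughout the package.
"""
from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Set, Tuple

from Bio import SeqIO

__all__ = [
    "InputError",
    "ColorKmerSet",
    "CdbgInput",
    "revcomp",
    "canonicalize",
    "extract_kmers",
    "count_color",
    "read_kmer_list",
    "load_cdbg",
    "union_with_classes",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class InputError(ValueError):
    """Malformed sequence input, k-mer list or manifest."""


def revcomp(s: str) -> str:
    """Reverse complement of an ACGT string."""
    return s.translate(_COMPLEMENT)[::-1]


def canonicalize(s: str) -> str:
    """Return the canonical form of a k-mer.

    The canonical form is the lexicographically smaller of the k-mer and its
    reverse complement, so both strands of a DNA word share one representative.
    Lowercase input is accepted; any non-ACGT character is rejected with its
    position.
    """
    s = s.upper()
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise InputError(f"non-ACGT character {ch!r} at position {i}")
    rc = revcomp(s)
    return s if s <= rc else rc


def extract_kmers(seq: str, k: int) -> List[str]:
    """Canonical k-mers of every valid length-k window of *seq*, in order.

    Windows containing a non-ACGT character (ambiguity codes such as N) are
    skipped rather than raising; multiplicities are preserved.  A sequence
    shorter than k yields an empty list.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    seq = seq.upper()
    out: List[str] = []
    valid_run = 0
    for i, ch in enumerate(seq):
        valid_run = valid_run + 1 if ch in _VALID else 0
        if valid_run >= k:
            w = seq[i - k + 1 : i + 1]
            rc = revcomp(w)
            out.append(w if w <= rc else rc)
    return out


@dataclass
class ColorKmerSet:
    """The canonical k-mer set of one color."""

    color_index: int
    kmers: Set[str] = field(default_factory=set)


@dataclass
class CdbgInput:
    """A colored de Bruijn graph: C ordered colors over a common k."""

    k: int
    C: int
    colors: List[ColorKmerSet]
    abundance: int = 1

    def __post_init__(self) -> None:
        if self.C != len(self.colors):
            raise InputError(f"C={self.C} but {len(self.colors)} color sets given")
        for i, cs in enumerate(self.colors):
            if cs.color_index != i:
                raise InputError(f"color set {i} carries index {cs.color_index}")
            for km in cs.kmers:
                if len(km) != self.k:
                    raise InputError(
                        f"color {i}: k-mer {km!r} has length {len(km)}, expected {self.k}"
                    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fasta(path) -> Iterator[Tuple[str, str]]:
    """Yield (record id, sequence) pairs; reject files that are not FASTA."""
    path = Path(path)
    with _open_text(path) as fh:
        ch = fh.read(1)
        while ch and ch.isspace():
            ch = fh.read(1)
        if ch != ">":
            raise InputError(f"{path}: not a FASTA file (no '>' header found)")
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def count_color(fasta_paths: Sequence, k: int, a: int, color_index: int = 0) -> ColorKmerSet:
    """Count canonical k-mers across FASTA files; keep those seen >= *a* times.

    Counts accumulate over all listed files (listing a file twice doubles its
    contribution).  With ``a == 1`` and no valid k-mer the result is simply
    empty, not an error.
    """
    if a < 1:
        raise ValueError(f"abundance threshold must be >= 1, got {a}")
    counts: Counter = Counter()
    for p in fasta_paths:
        for _rid, seq in _iter_fasta(p):
            counts.update(extract_kmers(seq, k))
    return ColorKmerSet(color_index, {km for km, n in counts.items() if n >= a})


def read_kmer_list(path, k: int) -> Set[str]:
    """Read a ``.kmers`` file: one k-mer per line, canonicalized on read."""
    out: Set[str] = set()
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if len(s) != k:
                raise InputError(f"{path}:{lineno}: k-mer length {len(s)} != k={k}")
            out.add(canonicalize(s))
    return out


def load_cdbg(manifest, k: int, a: int = 1) -> CdbgInput:
    """Load a colored de Bruijn graph from a color manifest.

    Each non-blank manifest line defines one color (0-based line order) and
    lists its input files, whitespace-separated, resolved relative to the
    manifest's directory.  ``.kmers`` files are read verbatim as sets; all
    other files are FASTA and go through abundance counting.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise InputError(f"{manifest}: empty manifest (no color lines)")
    base = manifest.parent
    colors: List[ColorKmerSet] = []
    for i, files in enumerate(lines):
        counts: Counter = Counter()
        verbatim: Set[str] = set()
        for f in files:
            p = base / f
            if not p.exists():
                raise InputError(f"{manifest}: color {i}: missing file {p}")
            if p.name.endswith(".kmers"):
                verbatim |= read_kmer_list(p, k)
            else:
                for _rid, seq in _iter_fasta(p):
                    counts.update(extract_kmers(seq, k))
        kmers = {km for km, n in counts.items() if n >= a} | verbatim
        colors.append(ColorKmerSet(i, kmers))
    return CdbgInput(k=k, C=len(colors), colors=colors, abundance=a)


def union_with_classes(E: CdbgInput) -> Dict[str, int]:
    """Map every union k-mer to its color vector (C-bit int, color 0 = MSB)."""
    C = E.C
    mapping: Dict[str, int] = {}
    get = mapping.get
    for cs in E.colors:
        bit = 1 << (C - 1 - cs.color_index)
        for km in cs.kmers:
            mapping[km] = get(km, 0) | bit
    return mapping
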