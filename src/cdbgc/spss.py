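"""Spectrum-preserving string sets (simplitigs).

An SPSS of a canonical k-mer set K is a list of strings, each at least k long,
whose length-k windows canonicalize to exactly the members of K, each appearing
exactly once across the whole set.  The record order of the SPSS fixes the
global k-mer order used by the color matrix, so construction must be
deterministic.

Construction is greedy: repeatedly seed a simplitig with the lexicographically
smallest unused canonical k-mer, then extend to the right and afterwards to the
left, at each step appending the smallest base in A<C<G<T order whose new
window canonicalizes to an unused member of K.  Membership is always tested on
the canonical form, so a k-mer may sit in a simplitig in either orientation.
Any valid SPSS is acceptable downstream; greediness only affects size, not
correctness.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Set

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cdbg_io import _COMPLEMENT, extract_kmers

__all__ = ["SpssError", "Spss", "SpssValidation", "build_simplitigs",
           "validate_spss", "write_spss", "read_spss"]


class SpssError(ValueError):
    """Invalid SPSS content or file."""


@dataclass
class Spss:
    """An ordered spectrum-preserving string set."""

    simplitigs: List[str]
    k: int

    @property
    def n_kmers(self) -> int:
        """Number of k-mer windows, == |K| for a valid SPSS."""
        return sum(len(s) - self.k + 1 for s in self.simplitigs)

    @property
    def n_chars(self) -> int:
        return sum(len(s) for s in self.simplitigs)


def _canon(w: str) -> str:
    rc = w.translate(_COMPLEMENT)[::-1]
    return w if w <= rc else rc


def build_simplitigs(kmers: Set[str], k: int) -> Spss:
    """Greedy deterministic SPSS construction of a canonical k-mer set.

    Empty input yields an empty Spss.  The output always satisfies
    :func:`validate_spss` against the input set.
    """
    used: Set[str] = set()
    sims: List[str] = []
    for seed in sorted(kmers):
        if seed in used:
            continue
        used.add(seed)
        # left_rev holds the left extension chars, most recently prepended last
        left_rev: List[str] = []
        right: List[str] = list(seed)
        while True:  # extend right
            suffix = "".join(right[-(k - 1):])
            for c in "ACGT":
                cw = _canon(suffix + c)
                if cw in kmers and cw not in used:
                    right.append(c)
                    used.add(cw)
                    break
            else:
                break
        while True:  # extend left
            need = k - 1
            if len(left_rev) >= need:
                prefix = "".join(reversed(left_rev[-need:]))
            else:
                prefix = "".join(reversed(left_rev)) + "".join(right[: need - len(left_rev)])
            for c in "ACGT":
                cw = _canon(c + prefix)
                if cw in kmers and cw not in used:
                    left_rev.append(c)
                    used.add(cw)
                    break
            else:
                break
        sims.append("".join(reversed(left_rev)) + "".join(right))
    return Spss(sims, k)


@dataclass
class SpssValidation:
    """Outcome of checking an Spss against a reference k-mer set."""

    missing: List[str] = field(default_factory=list)
    duplicated: List[str] = field(default_factory=list)
    foreign: List[str] = field(default_factory=list)
    malformed: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.duplicated or self.foreign or self.malformed)


def validate_spss(S: Spss, kmers: Set[str]) -> SpssValidation:
    """Check the SPSS invariants: exact, duplicate-free coverage of *kmers*.

    The report lists missing k-mers (in *kmers* but absent from the windows),
    duplicated ones (covered more than once), foreign ones (covered but not in
    *kmers*) and malformed simplitigs (shorter than k or non-ACGT windows).
    """
    seen: Counter = Counter()
    rep = SpssValidation()
    for idx, s in enumerate(S.simplitigs):
        if len(s) < S.k:
            rep.malformed.append(f"simplitig_{idx}: length {len(s)} < k={S.k}")
            continue
        wins = extract_kmers(s, S.k)
        if len(wins) != len(s) - S.k + 1:
            rep.malformed.append(f"simplitig_{idx}: non-ACGT character")
        seen.update(wins)
    rep.missing = sorted(set(kmers) - set(seen))
    rep.foreign = sorted(set(seen) - set(kmers))
    rep.duplicated = sorted(km for km, n in seen.items() if n > 1)
    return rep


def write_spss(S: Spss, path) -> None:
    """Write the SPSS as FASTA, records headed ``>simplitig_<index>``."""
    records = [
        SeqRecord(Seq(s), id=f"simplitig_{i}", description="")
        for i, s in enumerate(S.simplitigs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_spss(path, k: int) -> Spss:
    """Read an SPSS FASTA; record order is preserved (it defines k-mer rank)."""
    sims: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if len(s) < k:
            raise SpssError(f"{path}: record {rec.id!r} shorter than k={k}")
        sims.append(s)
    return Spss(sims, k)
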