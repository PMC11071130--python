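"""Synthetic colored de Bruijn graphs with controlled k-mer sharing.

The generator emulates a small pan-genome: ``n_backbones`` random DNA
backbones are shared across colors; each color drops a backbone with
probability ``dropout`` and substitutes bases of the retained ones
independently at rate ``mutation_rate``.  Low mutation and dropout give high
k-mer sharing and long monochrome runs along simplitigs (the regime where the
codec shines); high mutation pushes k-mers toward single-color classes.

Ground truth is obtained by re-counting canonical k-mers over the emitted
sequences themselves, never by tracking which bases mutated, so a mutated
k-mer that collides with an existing one is classified exactly as a reader
would classify it.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .cdbg_io import extract_kmers
from .spss import build_simplitigs, _canon

__all__ = ["SyntheticCdbgSpec", "GeneratedCdbg", "SharingStats",
           "generate_cdbg", "sharing_stats"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticCdbgSpec:
    """Parameters of one synthetic colored de Bruijn graph."""

    C: int
    n_backbones: int
    backbone_len: int
    mutation_rate: float
    dropout: float
    k: int
    abundance: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.backbone_len < self.k:
            raise ValueError(
                f"backbone_len {self.backbone_len} shorter than k={self.k}"
            )
        for name in ("mutation_rate", "dropout"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class GeneratedCdbg:
    """Generator output: file layout plus exact ground truth."""

    spec: SyntheticCdbgSpec
    manifest: Path
    fasta_paths: List[Path]
    truth: Dict[str, int]          # canonical k-mer -> color vector (color 0 = MSB)
    color_seqs: List[List[str]]    # per color, the emitted records


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases (never to themselves) at the given per-base rate."""
    if rate == 0.0:
        return codes
    hits = rng.random(codes.size) < rate
    if not hits.any():
        return codes
    out = codes.copy()
    out[hits] = (out[hits] + rng.integers(1, 4, hits.sum())) % 4
    return out


def generate_cdbg(spec: SyntheticCdbgSpec, out_dir) -> GeneratedCdbg:
    """Write per-color FASTA, a manifest and a truth TSV under *out_dir*.

    Deterministic for a given spec (including seed).  A color that ends up
    with no k-mers at all (e.g. dropout=1) is rejected: an all-zero color
    column cannot occur in a colored de Bruijn graph.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    backbones = [
        rng.integers(0, 4, spec.backbone_len, dtype=np.uint8)
        for _ in range(spec.n_backbones)
    ]
    color_seqs: List[List[str]] = []
    for _c in range(spec.C):
        records: List[str] = []
        for bb in backbones:
            if rng.random() < spec.dropout:
                continue
            codes = _mutate(bb, spec.mutation_rate, rng)
            records.append(_BASES[codes].tobytes().decode())
        color_seqs.append(records)

    truth: Dict[str, int] = {}
    for c, records in enumerate(color_seqs):
        bit = 1 << (spec.C - 1 - c)
        kmers = set()
        for seq in records:
            kmers.update(extract_kmers(seq, spec.k))
        if not kmers:
            raise ValueError(f"color {c} received no k-mers (dropout too high?)")
        for km in kmers:
            truth[km] = truth.get(km, 0) | bit

    fasta_paths: List[Path] = []
    for c, records in enumerate(color_seqs):
        p = out_dir / f"color_{c}.fa"
        with open(p, "w") as fh:
            for j, seq in enumerate(records):
                fh.write(f">backbone_{j}\n{seq}\n")
        fasta_paths.append(p)
    manifest = out_dir / "manifest.txt"
    with open(manifest, "w") as fh:
        for p in fasta_paths:
            fh.write(p.name + "\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        for km in sorted(truth):
            fh.write(f"{km}\t{format(truth[km], f'0{spec.C}b')}\n")
    return GeneratedCdbg(spec, manifest, fasta_paths, truth, color_seqs)


@dataclass
class SharingStats:
    """Summary of a k-mer -> color-vector mapping."""

    single_color_fraction: float
    n_classes: int
    mean_run_length: float


def sharing_stats(mapping: Dict[str, int], k: Optional[int] = None) -> SharingStats:
    """Exact sharing statistics of a ground-truth (or decompressed) mapping.

    The mean run length is measured along the package's own reference SPSS of
    the mapping's k-mer set; *k* defaults to the k-mer length observed.
    """
    if not mapping:
        raise ValueError("empty mapping")
    if k is None:
        k = len(next(iter(mapping)))
    single = sum(1 for v in mapping.values() if v.bit_count() == 1)
    spss = build_simplitigs(set(mapping), k)
    runs: List[int] = []
    for s in spss.simplitigs:
        cur = None
        for i in range(len(s) - k + 1):
            v = mapping[_canon(s[i : i + k])]
            if v == cur:
                runs[-1] += 1
            else:
                runs.append(1)
                cur = v
    return SharingStats(
        single_color_fraction=single / len(mapping),
        n_classes=len(set(mapping.values())),
        mean_run_length=sum(runs) / len(runs),
    )
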