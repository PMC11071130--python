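# cdbgc — lossless disk compression for colored de Bruijn graphs

A *colored de Bruijn graph* (cdBG) is a family `E = {E_0, …, E_{C−1}}` of
canonical k-mer sets, one per *color* — a sample, a genome assembly, a
sequencing experiment. Equivalently it is the union k-mer set
`Ē = ∪ᵢ Eᵢ` together with, for each k-mer `x`, its *color class*
`{i : x ∈ Eᵢ}`, written as a C-bit *color vector*. Pan-genome collections,
metagenome cohorts and RNA-seq compendia are routinely reduced to this form,
and storing or shipping the resulting matrices is a real cost: the naive
representation spends `C` bits per k-mer regardless of how redundant the
colors are.

`cdbgc` compresses a cdBG to disk — no queries on the compressed file, just a
small archive and exact reconstruction. It exploits two regularities:

1. **k-mers shared across colors** — the number of *distinct* color classes
   `M` is usually far smaller than `2^C`, so classes can be dictionary-coded;
2. **locality along simplitigs** — consecutive k-mers of a
   *spectrum-preserving string set* (SPSS) overwhelmingly carry the same or a
   nearly identical class, so most rows of the color matrix can be encoded as
   runs or small Hamming differences instead of class IDs.

## The scheme

* **SPSS.** The union k-mers are assembled into *simplitigs*: strings whose
  length-k windows canonicalize to every union k-mer exactly once. The record
  order fixes the global k-mer rank, and the color matrix is emitted in that
  order.
* **Global class table.** Each distinct class gets a Huffman codeword
  (*global ID*) from its k-mer frequency. On disk the sorted classes are
  delta-coded: the first vector verbatim in `C` bits, each next one as the
  `hᵢ` color indices where it differs from its predecessor (`⌈log₂C⌉` bits
  each), plus a boundary bitvector marking where classes start and the
  frequency list — enough to regenerate identical codes at decompression.
* **m vector.** Each simplitig's class sequence is scanned left to right and
  every k-mer is emitted as one of four encodings: **skip** (equal to both
  neighbours — zero bits), **small class difference** (Hamming distance
  `h ≤ maxDif` to the predecessor: type `10`, then the differing indices),
  **end of run** (type `11`, or `1` when `maxDif = 0`; the run length is
  split as `runLen = q·runDivisor + r` with `q` in unary and `r` in
  `log₂ runDivisor` binary bits), or **store class ID** (type `0`, then the
  global — or local — ID).
* **Local class tables.** A simplitig touching only `ℓ` distinct classes may
  instead index them with fixed-width `⌈log₂ℓ⌉`-bit *local IDs*, at the price
  of storing the ℓ global IDs once.
* **Mode search.** All six combinations of `maxDif ∈ {0,1,2}` ×
  `useLocalID ∈ {False,True}` are encoded per simplitig and the cheapest kept,
  recorded in 3 metadata bits.

Every section (simplitig FASTA, Δ, boundary, frequencies, metadata, local
tables, m) lands in a self-describing binary container with per-section
DEFLATE and CRC32. Identical input yields byte-identical archives.

## Worked example

Three colors, `k = 5`:

```
E_0 = {TCAAA, CAAAA, AAAAT}
E_1 = {TCAAA, CAAAA, AAAAT, AAATT, CAAAG, AAATC, AATCG}
E_2 = {TCAAA, CAAAA, AAAAT, AAATT, CAAAG}
```

```python
from cdbgc import CdbgInput, ColorKmerSet, build_simplitigs, union_with_classes
from cdbgc import compress, decompress

E = CdbgInput(k=5, C=3, colors=[
    ColorKmerSet(0, {"TCAAA", "CAAAA", "AAAAT"}),
    ColorKmerSet(1, {"TCAAA", "CAAAA", "AAAAT", "AAATT", "CAAAG", "AAATC", "AATCG"}),
    ColorKmerSet(2, {"TCAAA", "CAAAA", "AAAAT", "AAATT", "CAAAG"}),
])
mapping = union_with_classes(E)
print(len(mapping), len(set(mapping.values())))   # 7 3
print(build_simplitigs(set(mapping), 5).simplitigs)
# ['TCAAAATCG', 'AAATT', 'CAAAG']
report = compress(E, "toy.cdbgc")
print(report.M, report.n_kmers)                   # 3 7
print(decompress("toy.cdbgc").mapping() == mapping)  # True
```

The union holds 7 k-mers in `M = 3` classes (`{0,1,2}`, `{1,2}`, `{1}`); the
greedy SPSS packs them into three simplitigs (19 characters for 7 k-mers),
and decompression returns the exact k-mer → class mapping.

On something less tiny — a synthetic 3-color pan-genome via the CLI:

```console
$ cdbgc synth --colors 3 --backbones 4 --len 2000 --mut-rate 0.005 \
      --dropout 0.2 --k 31 --seed 7 --out demo
INFO cdbgc: wrote 3 colors under demo (10124 union k-mers, 7 classes, 33.0% single-color)
$ cdbgc compress --manifest demo/manifest.txt --k 31 --out demo.cdbgc
INFO cdbgc: wrote demo.cdbgc: 4330 bytes for 10124 k-mers over 3 colors (7 classes, 70 simplitigs)
$ cdbgc verify demo.cdbgc --manifest demo/manifest.txt --k 31
INFO cdbgc: ok: 10124 k-mers recovered exactly
```

4330 bytes for 10 124 k-mers is ≈ 3.4 bits per k-mer *including* the k-mer
sequences themselves; the color information proper (`MBITS` + metadata +
tables) is a few hundred bytes against the `3 × 10124` bits a naive matrix
would spend. `cdbgc stats demo.cdbgc` prints the per-section and per-mode
breakdown; `cdbgc decompress demo.cdbgc --spss out.fa --matrix out.tsv`
restores the simplitigs and the rank-ordered `<kmer>\t<bitstring>` matrix.

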