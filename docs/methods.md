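# Methods

## Model and procedure

`cdbgc` treats a colored de Bruijn graph as pure set data: `C` sets of
canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement represents both strands). Compression proceeds in four stages.

**1. Input materialization.** Per-color FASTA files are k-mer-counted
in-process and filtered by an abundance threshold `a` (k-mers seen `≥ a`
times per color are kept); plain-text `.kmers` lists are taken verbatim after
canonicalization. Windows containing non-ACGT characters are skipped rather
than rejected, matching common practice for N-containing assemblies.
Lowercase is folded before validation. The union map `Ē → {0,1}^C` is built
with color 0 as the leftmost/most-significant bit; this MSB-first convention
is a free choice (nothing in the math prefers an endianness) but it is fixed
once and used consistently for the numeric class order, the delta coding and
the matrix dumps.

**2. SPSS construction.** Simplitigs are built greedily: seed with the
lexicographically smallest unused canonical k-mer, extend right then left,
always appending the smallest admissible base (A<C<G<T), a base being
admissible when the new window's canonical form is an unused union k-mer.
This is deterministic, O(total characters), and yields a valid
spectrum-preserving string set for any input; it makes no attempt at
minimum-size output (eulertig/matchtig-style optimization is out of scope)
because the color codec is correct for *any* valid SPSS — only archive size,
not losslessness, depends on the decomposition.

**3. Color matrix and class table.** Ranks follow (simplitig index, window
offset). Class frequencies are counted in one scan; Huffman code lengths are
derived with a tie rule (equal frequencies merge the smaller numeric class
first) and codewords assigned canonically (shorter codes first, then by class
value), so the codes are a pure function of `(classes, frequencies)` — which
is exactly what the archive stores. With `M = 1` the single class gets the
empty codeword; Huffman coding is undefined on a one-symbol alphabet, and the
empty code makes a store encoding cost just its type bit. Index width in the
delta coding is `⌈log₂ C⌉` with a floor of one bit so that `C ≤ 2` still has
a representable index; `ℓ − 1` rather than `ℓ` is stored for local-table
sizes because `ℓ = M` would otherwise not fit in `⌈log₂ M⌉` bits.

**4. Per-simplitig encoding.** The four-case analysis (skip / small class
difference / end of run / store class ID) is exhaustive and mutually
exclusive at every position: the first k-mer always stores its ID (differences
never cross simplitig boundaries), an interior k-mer equal to both neighbours
is skipped, a k-mer equal to its predecessor but not its successor (or final
in the simplitig) closes a run, and everything else is a difference or store
depending on `h ≤ maxDif`. The run length counts the closer's consecutive
same-class *predecessors*; since the run's opener was emitted by its own
store/difference encoding, the decoder emits exactly `runLen` k-mers at a run
marker (the skipped interior plus the closer) and total output always equals
the simplitig's window count, which the decoder knows from the stored
simplitig lengths. A run marker with `runLen = 0` cannot be produced and is
treated as corruption. `runDivisor` is restricted to powers of two (default
16) so the remainder field is exactly `log₂ runDivisor` bits.

All six `(maxDif, useLocalID)` modes are encoded and the cheapest kept, cost
being 3 metadata bits + `|m|` + the serialized local table if used; ties
resolve to smaller `maxDif`, then to no local table, for reproducible
archives.

## Archive format

Little-endian header (magic `CDBC`, version, `k`, `C`, `M`, `runDivisor`,
simplitig and k-mer counts), a seven-entry section directory (codec id, raw
and stored lengths, CRC32 of the raw payload), then the payloads:
simplitig FASTA, Δ, boundary, frequencies (ASCII, one decimal per line),
metadata, local tables, m. Bit-carrying sections are MSB-first packed with an
explicit 64-bit bit count. Each section is DEFLATE-compressed when that is
smaller, stored raw otherwise. Two design substitutions relative to
rank/select-capable representations: succinct bitvectors are replaced by
generic byte compression (disk compression needs no rank/select), and
minimal-perfect-hash class lookups by ordinary dictionaries (a construction
convenience with no effect on the bytes). Per-simplitig k-mer counts are not
stored — simplitig lengths carry them for free.

## Synthetic data generator

`synthio` emulates a small pan-genome: `n_backbones` i.i.d. uniform DNA
backbones shared by all colors; each color drops each backbone with
probability `dropout` and substitutes retained bases at `mutation_rate`
(never to the same base, no indels). Ground truth is obtained by re-counting
k-mers over the emitted sequences, so mutated k-mers that collide with
existing ones are classified exactly as a reader would classify them. Knob
defaults used across the test suite: small instances use 8 backbones of
60–300 bp (scaled down with `C` so high-color instances stay desk-sized) at
`k ∈ {11, 31}`; larger round-trip instances go up to ≈ 9 × 10⁴ union k-mers.
What it does *not* emulate: sequencing error profiles, coverage variation,
indels and rearrangements, real genome repeat structure. Passing round-trips
on this generator demonstrate losslessness of the codec over the full
structural range it can encounter (any class sequence is reachable), but
compression *ratios* measured on it do not transfer to real data, where run
lengths and class skew differ.

A color ending up with zero k-mers (e.g. `dropout = 1`) is rejected: an
all-zero color column cannot occur in a colored de Bruijn graph, whose colors
are defined by their member k-mers.

## Numerical and degenerate-input choices

* Empty union → compression error; empty SPSS is representable but an
  archive must hold at least one k-mer.
* `C = 1` degenerates gracefully: `M = 1`, empty codeword, each simplitig's m
  is a 1-bit store plus (for length > 1) one run encoding.
* Huffman mean code length satisfies `H ≤ L̄ < H + 1` (checked against the
  empirical class entropy in tests).
* Decoders fail loudly: truncated streams, out-of-range difference indices or
  local IDs, run-before-class, unconsumed trailing bits, CRC mismatches and
  header inconsistencies all raise format errors; nothing is silently
  repaired.

## Known limitations

* The greedy SPSS is not size-minimal, and archive sizes are therefore not
  comparable bit-for-bit with pipelines built on other SPSS constructions —
  only the lossless mapping is canonical.
* No queries on the compressed file (membership, color lookup); decompress
  first.
* Pure-Python bit handling favors clarity over throughput; the intended
  scale is desk-sized inputs (≤ a few million k-mers), not petabyte
  archives.
* FASTQ is not parsed specially; quality-aware filtering is out of scope.
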