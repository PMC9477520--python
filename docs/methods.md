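# Methods

This note records the model behind `kffio`, the dialect decisions the wire
format required, the defaults and why they were chosen, and what the
synthetic data generator does and does not emulate.

## The container model

A KFF file is a header plus an ordered list of sections. The header carries
the format version (1.0 for files written here), the nucleotide 2-bit
encoding, two global flags — `unique_kmers` (no k-mer occurs twice within
any one section) and `canonical_kmers` (every stored k-mer equals the
lexicographically smaller of itself and its reverse complement) — and an
opaque metadata field. Variable (V) sections define a running name → u64
map; raw (R) and minimizer (M) sections are parsed under whatever `k`,
`max`, `data_size` and `m` are in force at their position, and later
definitions override earlier ones, so one file can hold several k values in
sequence. Uniqueness and canonicity are defined per section: a file may
legitimately store the same set twice, once raw and once minimizer-bucketed.

Per-k-mer data is opaque: exactly `data_size` bytes per k-mer, in window
order. The library assigns no semantics to it beyond the text converter,
which encodes counts big-endian. This keeps the container honest — whether
the payload is an abundance, a colour class or a bitfield is the producer's
business.

## Dialect decisions

The container's byte-level layout involves choices no model can derive, so
this implementation fixes one normative, versioned dialect and documents it
in `kffio.io`:

* all multi-byte integers are big-endian (platform-neutral network order);
* the encoding byte packs the codes of A, C, G, T high-to-low (the default
  A:0, C:1, G:3, T:2 table is `0x1E`);
* packing is *right-aligned*: a sequence is a base-4 numeral written
  big-endian into `ceil(len/4)` bytes, so padding bits sit zeroed in the
  most-significant bits of the first byte. Under an order-preserving
  encoding the numeric value of a packed k-mer then orders exactly like its
  lexicographic rank, for equal k;
* the per-block count `n` occupies `ceil(bits(max)/8)` bytes and is omitted
  when `max = 1`; the minimizer position occupies
  `ceil(bits(max + k − 1 − m)/8)` bytes (at least one), since the largest
  legal insertion point is the full skeleton length `max + k − 1 − m`. Both
  widths are computable from the variable state alone, so blocks need no
  per-block headers;
* index offsets are signed and relative to the first byte after their index
  section; a trailing signed offset chains to the next index (0 = none);
* the terminal `KFF` magic is verified when present, but its absence is a
  validation warning rather than a read error — deliberately truncated
  streams remain consumable;
* unknown section types abort parsing: with no length field there is no
  safe skip;
* compression is layered outside the file (whole-file gzip), never inside
  sections.

Canonical order, and the minimizer order, are defined on the letter alphabet
A < C < G < T regardless of the file's numeric encoding: both are properties
of the k-mer set and must survive re-encoding. Files produced under a
code-order convention by other writers would bucket differently; the
validator would still accept them, since M sections are only required to
contain their section minimizer at the stated position (see below).

## Minimizers and super-k-mers

`minimizer_of` returns the lexicographically smallest m-window with leftmost
tie-break. `split_into_superkmers` computes per-window minimizers with a
monotonic deque (O(length) amortized comparisons; equal keys are kept behind
the front so the leftmost occurrence wins, matching the scalar operation
exactly) and cuts the k-mer run wherever the minimizer m-mer *or its
absolute position* changes. Every window of a resulting super-k-mer
therefore has that exact minimizer occurrence, and concatenating the runs'
windows reproduces the sequence's windows in order, each once.

M-section blocks are validated under the weaker contract "contains the
section minimizer at the stated position" rather than "every window's own
minimizer is the section minimizer". The toy worked example itself needs
the weaker contract: stored as a single 12-nt block under minimizer
`AAACTGAT`, its first 10-mer's own minimizer is `ACTAAACT`. Strictness is a
producer choice; this library's own bucketing producer is strict.

## Greedy SPSS

`greedy_compact` builds a spectrum-preserving string set by greedy path
cover of the (k−1)-overlap graph: seed with an unused k-mer, extend right
then left through unused neighbours, trying extensions in A < C < G < T
order. Seeds are taken in ascending lexicographic order — Python's set
iteration order is hash-randomized across processes, and a deterministic
artifact (identical output for identical input, on any machine) was judged
worth the one sort. The result is a true SPSS — every window of every
string is an input k-mer and every input k-mer appears exactly once — but
not a minimum one; minimality is a much harder optimization and out of
scope. Compaction requires duplicate-free input (an SPSS is defined on
sets) and marks its output `unique_kmers`; the naive writer accepts
duplicates.

Data payloads survive every re-layout by construction: window i of any
written block carries payload i, and the bucketing/SPSS builders reattach
each k-mer's payload by lookup when they re-order.

## Defaults

| parameter | default | rationale |
|---|---|---|
| encoding | A:0, C:1, G:3, T:2 | the format's customary example table |
| `max` (superkmer mode) | 255 | n fits one byte; runs longer than 255 k-mers are chunked |
| `m` (compact) | 10 | small enough to bucket well at k = 32, large enough that 4^m ≫ typical set sizes |
| `data_size` (from-text) | minimal bytes for the largest count | lossless and compact without a flag |
| version written | 1.0 | first dialect revision |

## The synthetic generator

`generate_spectrum_set` draws `n_strings` uniform random ACGT strings of
`string_length` and takes the union of their k-windows with occurrence
counts, plus `noise_kmers` isolated uniform k-mers (collisions merge counts,
as error k-mers merge in real counters). Defaults are 10 strings of 100 kb
at k = 32 — about 10^6 distinct k-mers, the scale used for the layout size
comparison; the randomness is Python's seeded Mersenne Twister, reproducible
across machines, with the seed recorded in fixture metadata.

What it emulates: the spectrum-like property (long shared backbones), count
multiplicity, error-like singletons. What it does not: real base
composition and repeat structure (uniform random strings have almost no
repeats, so greedy chains recover the sources nearly perfectly — real
genomes fragment more), reverse-complement strandedness (sources are
single-stranded; canonical-form files must be produced by the caller), and
sequencing coverage depth. Passing tests therefore demonstrate correctness
and the qualitative size ordering of the layouts, not the exact
bits-per-k-mer of any real dataset — on this generator the super-k-mer
layout lands near 13–14 bits/k-mer and the greedy SPSS near 2, and real
read sets with uneven coverage and repeats will sit higher.

## Numerical and degenerate-input choices

Lower-case input is upper-cased; any other character (including N) is an
error naming the offending position — the format has no ambiguity codes, so
producers must pre-filter. Empty sequences pack to an empty payload. A
sequence section appearing before its governing variables is an ordering
error on write and read alike. Zero-block sections are representable on the
wire and flagged by the validator rather than the parser. `validate`
reports parse failures as violations (exit 1) and reserves exit 3 for I/O
errors, so a corrupt file and an unreadable file are distinguishable in
pipelines. Merging drops index sections (their offsets would be stale) —
re-run `kff index` afterwards; merge re-verifies geometry (`k`,
`data_size`) across inputs and ANDs the global flags.

## Problem sizes in the test suite

The randomized suites run at the sizes stated in their tests: 1000
round-trip files, 10^5 minimizer-oracle instances, 500-k-mer SPSS sets, and
one 10 × 100 kb spectrum set for the size-ordering check (~10^6 k-mers,
about 12 s end to end). These sizes were chosen to exercise every field
width and code path while keeping the whole suite interactive.

## Known limitations

Byte-for-byte compatibility with files written by other KFF implementations
is not asserted; the dialect here is self-consistent and versioned, and the
documented field widths are the interop contract. Random access by k-mer is
out of scope by design. The greedy SPSS is not abundance-aware and not
minimal. Index building requires a seekable file; all other operations
stream.
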