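# kffio

A pure-Python library and command-line toolkit for the **K-mer File Format
(KFF)** — a sectioned binary container for sets of k-mers with optional
fixed-width per-k-mer data (abundances, colours, ...).

K-mer sets are the lingua franca of sequence analysis: k-mer counters
produce them, and assemblers, aligner indexes and large-scale search tools
consume them. Historically every producer used its own ad-hoc binary dump,
forcing every consumer to write bespoke parsers. A common container with a
compact on-disk layout fixes both problems at once: interoperability, and
space — genomic k-mer sets are highly compressible because most k-mers arise
as overlapping windows of a few long underlying strings (the *spectrum-like
property*), so storing strings longer than k beats storing k-mers one by one.

## The format in one paragraph

A file is a 12-byte-plus-metadata header (format version, the nucleotide
2-bit encoding as a permutation such as A:0, C:1, G:3, T:2, and global
uniqueness/canonicity flags) followed by sections. **V** sections define
named u64 variables (`k`, `max`, `data_size`, `m`) governing what follows.
**R** sections hold blocks of explicit sequences: a block of `n` k-mers
stores one string of `n + k − 1` nucleotides packed at 2 bits/nt plus `n`
data payloads. **M** sections group blocks sharing one *minimizer* (the
lexicographically smallest m-mer of a sequence, leftmost on ties); the
minimizer is stored once per section, and each block keeps only its
*skeleton* — the sequence with the minimizer deleted — plus the position at
which to re-insert it. **I** sections index section positions for seeking.
Consumption is strictly sequential; there is no random access by k-mer.

On top of the codec, the library builds compact layouts from flat k-mer
sets: a greedy **spectrum-preserving string set** (SPSS — strings whose
length-k windows are exactly the input set, each once, built as a greedy
path cover of the (k−1)-overlap graph) and **super-k-mers** (maximal runs of
consecutive k-mers sharing a minimizer occurrence), bucketed per minimizer
into M sections.

## Worked example

The toy set is the 12-nt sequence `ACTAAACTGATG` with k = 10 and m = 8. Its
minimizer is `AAACTGAT` at position 3, so an M-section block stores only the
skeleton `ACTG` and the position:

```python
>>> from kffio import minimizer_of, reconstruct_sequence, MinimizerBlock, kmers_of_sequence
>>> minimizer_of("ACTAAACTGATG", 8)
('AAACTGAT', 3)
>>> reconstruct_sequence(MinimizerBlock("ACTG", 3), "AAACTGAT")
'ACTAAACTGATG'
>>> kmers_of_sequence("ACTAAACTGATG", 10)
['ACTAAACTGA', 'CTAAACTGAT', 'TAAACTGATG']
```

The reconstruction has length 12 and yields exactly three 10-mers — the
same set the equivalent R section stores explicitly.

At realistic scale the layouts separate clearly. Ten simulated 10-kb source
strings (k = 32, no counts) written in the three layouts:

```
99690 distinct 32-mers from 10 source strings
naive          797589 bytes   64.01 bits/k-mer
super-k-mer    175475 bytes   14.08 bits/k-mer
greedy SPSS     25089 bytes    2.01 bits/k-mer
```

Naive storage costs 64 bits/k-mer (a packed 32-mer is exactly 64 bits);
overlap-aware layouts amortize those bits across neighbouring k-mers. On
tiny inputs the fixed header/section overhead dominates and the ordering can
invert — compaction pays off from thousands of k-mers upward.

## Command line

```
kff validate|instr|to-text|from-text|merge|split|index|compact|uncompact
```

```sh
kff from-text counts.tsv -o counts.kff          # KMER<TAB>COUNT lines in
kff compact counts.kff -o compact.kff --mode superkmer -m 10
kff instr compact.kff --json                    # bits/k-mer, section census
kff to-text compact.kff                         # dump records back out
```

Exit statuses are stable: 0 success, 1 validation/data failure, 2 usage
error, 3 I/O or parse error. Text I/O reads and writes `.gz` transparently.

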