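"""Space-efficient layouts for flat k-mer sets.

Three layouts are produced here, in increasing order of compaction:

* *naive* — one k-mer per raw block (``max = 1``), the simplest producer
  output and the baseline for size comparisons;
* *super-k-mers* — k-mers are first chained into overlapping sequences,
  each sequence is split into maximal runs of consecutive k-mers sharing
  one minimizer occurrence, and the runs are bucketed per minimizer into
  minimizer sections that store only skeletons;
* *greedy SPSS* — a spectrum-preserving string set: a small set of strings
  whose length-k windows are exactly the input k-mers, each appearing once,
  built as a greedy path cover of the (k-1)-overlap graph.

The minimizer order is plain lexicographic on letters (A < C < G < T),
non-canonical, with leftmost tie-break; an alternative order can be supplied
as a key function.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import DuplicateKmerError, ParameterError, TooShortError
from .model import (
    FileHeader,
    MinimizerBlock,
    MinimizerSection,
    RawSection,
    Section,
    SequenceBlock,
    ValuesSection,
)
from .io import write_file
from .stream import KmerRecord, collect_records

EXTENSION_ORDER = "ACGT"


@dataclass(frozen=True)
class SuperKmer:
    """A maximal run of consecutive k-mers sharing one minimizer occurrence.

    ``minimizer_position`` is the 0-based offset of the shared m-mer within
    ``sequence``; every length-k window of ``sequence`` contains it.
    """

    sequence: str
    minimizer: str
    minimizer_position: int


def minimizer_of(
    sequence: str, m: int, order: Callable[[str], object] | None = None
) -> tuple[str, int]:
    """The smallest length-m window of ``sequence`` and its 0-based position.

    Smallest under lexicographic letter order by default, or under the key
    function ``order``; ties go to the leftmost occurrence.
    """
    if len(sequence) < m:
        raise TooShortError(f"sequence of {len(sequence)} nt holds no {m}-mer")
    best = sequence[:m]
    best_key = best if order is None else order(best)
    best_pos = 0
    for i in range(1, len(sequence) - m + 1):
        window = sequence[i : i + m]
        key = window if order is None else order(window)
        if key < best_key:
            best, best_key, best_pos = window, key, i
    return best, best_pos


def _window_minimizers(
    sequence: str, k: int, m: int, order: Callable[[str], object] | None = None
) -> list[tuple[int, str]]:
    """Per k-window minimizers of a long sequence, via a monotonic deque.

    Returns one ``(absolute position, m-mer)`` pair per k-window, identical
    to running :func:`minimizer_of` on each window but in O(len) amortized
    comparisons.  Equal keys are kept behind the front so the leftmost
    occurrence wins, matching the tie-break of :func:`minimizer_of`.
    """
    mmers = [sequence[j : j + m] for j in range(len(sequence) - m + 1)]
    keys: Sequence[object] = mmers if order is None else [order(x) for x in mmers]
    span = k - m  # index gap between a k-window and its last m-window
    dq: deque[int] = deque()
    out: list[tuple[int, str]] = []
    for j in range(len(mmers)):
        key = keys[j]
        while dq and keys[dq[-1]] > key:
            dq.pop()
        dq.append(j)
        window_start = j - span
        if window_start >= 0:
            while dq[0] < window_start:
                dq.popleft()
            front = dq[0]
            out.append((front, mmers[front]))
    return out


def split_into_superkmers(
    sequence: str, k: int, m: int, order: Callable[[str], object] | None = None
) -> list[SuperKmer]:
    """Partition a sequence's k-mer run into super-k-mers.

    Consecutive k-windows whose minimizers are the same m-mer *at the same
    absolute position* form one super-k-mer; the concatenation of the
    returned runs' windows reproduces the sequence's windows in order,
    each exactly once.
    """
    if not 1 <= m <= k:
        raise ParameterError(f"need 1 <= m={m} <= k={k}")
    if len(sequence) < k:
        raise TooShortError(f"sequence of {len(sequence)} nt holds no {k}-mer")
    mins = _window_minimizers(sequence, k, m, order)
    out: list[SuperKmer] = []
    run_start = 0
    for i in range(1, len(mins) + 1):
        if i == len(mins) or mins[i] != mins[run_start]:
            pos, mmer = mins[run_start]
            out.append(
                SuperKmer(
                    sequence[run_start : i - 1 + k], mmer, pos - run_start
                )
            )
            run_start = i
    return out


def greedy_compact(kmers: Iterable[str], k: int | None = None) -> list[str]:
    """Greedy spectrum-preserving string set over a duplicate-free k-mer set.

    Repeatedly seeds with the smallest unused k-mer and extends it first
    rightwards then leftwards through (k-1)-overlaps to unused k-mers,
    trying extensions in A < C < G < T order.  Every window of every output
    string is an input k-mer and every input k-mer appears as a window of
    exactly one output string, exactly once.
    """
    pool = list(kmers)
    if not pool:
        return []
    if k is None:
        k = len(pool[0])
    unused = set(pool)
    if len(unused) != len(pool):
        raise DuplicateKmerError("input k-mers are not a set")
    for kmer in pool:
        if len(kmer) != k:
            raise ParameterError(f"{kmer!r} is not a {k}-mer")
    out: list[str] = []
    for seed in sorted(unused):
        if seed not in unused:
            continue
        unused.remove(seed)
        # rightward
        right: list[str] = []
        suffix = seed[1:]
        while True:
            for base in EXTENSION_ORDER:
                candidate = suffix + base
                if candidate in unused:
                    unused.remove(candidate)
                    right.append(base)
                    suffix = candidate[1:]
                    break
            else:
                break
        # leftward
        left: list[str] = []
        prefix = seed[: k - 1]
        while True:
            for base in EXTENSION_ORDER:
                candidate = base + prefix
                if candidate in unused:
                    unused.remove(candidate)
                    left.append(base)
                    prefix = candidate[: k - 1]
                    break
            else:
                break
        left.reverse()
        out.append("".join(left) + seed + "".join(right))
    return out


def _data_map(
    records: Iterable[KmerRecord | tuple[str, bytes]], k: int | None
) -> tuple[int, dict[str, bytes]]:
    data_of: dict[str, bytes] = {}
    for record in records:
        kmer, data = (
            (record.kmer, record.data)
            if isinstance(record, KmerRecord)
            else record
        )
        if k is None:
            k = len(kmer)
        if len(kmer) != k:
            raise ParameterError(f"{kmer!r} is not a {k}-mer")
        if kmer in data_of:
            raise DuplicateKmerError(f"duplicate k-mer {kmer}")
        data_of[kmer] = data
    if k is None:
        raise ParameterError("no k-mers given and no k specified")
    return k, data_of


def bucket_and_write_minimizer_sections(
    records: Iterable[KmerRecord | tuple[str, bytes]],
    k: int,
    m: int,
    max_: int,
    data_size: int,
    order: Callable[[str], object] | None = None,
) -> list[MinimizerSection]:
    """Chain, split and bucket a k-mer set into minimizer sections.

    K-mers are chained with :func:`greedy_compact`, each chain is split into
    super-k-mers, runs longer than ``max_`` k-mers are chunked, and blocks
    are grouped into one section per distinct minimizer (sections sorted by
    minimizer for determinism).  Per-k-mer data payloads follow their k-mer
    through the re-layout: window i of a block carries payload i.
    """
    if not 1 <= m <= k:
        raise ParameterError(f"need 1 <= m={m} <= k={k}")
    k, data_of = _data_map(records, k)
    buckets: dict[str, list[MinimizerBlock]] = {}
    for chain in greedy_compact(data_of.keys(), k):
        for sk in split_into_superkmers(chain, k, m, order):
            n = len(sk.sequence) - k + 1
            for start in range(0, n, max_):
                count = min(max_, n - start)
                sub = sk.sequence[start : start + count + k - 1]
                pos = sk.minimizer_position - start
                skeleton = sub[:pos] + sub[pos + m :]
                data = b"".join(
                    data_of[sub[i : i + k]] for i in range(count)
                )
                buckets.setdefault(sk.minimizer, []).append(
                    MinimizerBlock(skeleton, pos, data)
                )
    return [
        MinimizerSection(mmer, blocks) for mmer, blocks in sorted(buckets.items())
    ]


# ---------------------------------------------------------------------------
# section builders for the three layouts


def naive_sections(
    records: Iterable[KmerRecord | tuple[str, bytes]],
    k: int | None,
    data_size: int,
    max_: int = 1,
) -> list[Section]:
    """One k-mer per block; duplicates are allowed in this layout."""
    blocks = []
    for record in records:
        kmer, data = (
            (record.kmer, record.data)
            if isinstance(record, KmerRecord)
            else record
        )
        if k is None:
            k = len(kmer)
        blocks.append(SequenceBlock(kmer, data))
    if k is None:
        return []
    return [
        ValuesSection({"k": k, "max": max_, "data_size": data_size}),
        RawSection(blocks),
    ]


def superkmer_sections(
    records: Iterable[KmerRecord | tuple[str, bytes]],
    k: int,
    m: int,
    data_size: int,
    max_: int = 255,
) -> list[Section]:
    sections = bucket_and_write_minimizer_sections(records, k, m, max_, data_size)
    return [
        ValuesSection({"k": k, "max": max_, "data_size": data_size, "m": m}),
        *sections,
    ]


def spss_sections(
    records: Iterable[KmerRecord | tuple[str, bytes]],
    k: int,
    data_size: int,
) -> list[Section]:
    """Greedy SPSS layout: one raw block per string, ``max`` = longest run."""
    k, data_of = _data_map(records, k)
    blocks = []
    for chain in greedy_compact(data_of.keys(), k):
        data = b"".join(
            data_of[chain[i : i + k]] for i in range(len(chain) - k + 1)
        )
        blocks.append(SequenceBlock(chain, data))
    max_ = max(block.n_kmers(k) for block in blocks)
    return [
        ValuesSection({"k": k, "max": max_, "data_size": data_size}),
        RawSection(blocks),
    ]


# ---------------------------------------------------------------------------
# whole-file rewriters

MODES = ("naive", "superkmer", "spss")


def compact_file(
    in_path: str | Path,
    out_path: str | Path,
    mode: str = "superkmer",
    m: int = 10,
    max_: int = 255,
) -> None:
    """Rewrite a file in one of the three layouts, preserving the k-mer
    multiset and per-k-mer data.

    The super-k-mer and SPSS layouts require a duplicate-free input (they
    are defined on sets) and mark the output ``unique_kmers``.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; pick one of {MODES}")
    header, k, data_size, records = collect_records(in_path)
    if k is None:
        write_file(header, [], out_path)
        return
    if mode == "naive":
        sections = naive_sections(records, k, data_size)
    elif mode == "superkmer":
        sections = superkmer_sections(records, k, m, data_size, max_)
        header = FileHeader(
            header.encoding, True, header.canonical_kmers, header.metadata
        )
    else:
        sections = spss_sections(records, k, data_size)
        header = FileHeader(
            header.encoding, True, header.canonical_kmers, header.metadata
        )
    write_file(header, sections, out_path)


def uncompact(in_path: str | Path, out_path: str | Path) -> None:
    """Rewrite any file with one k-mer per block (``max = 1``)."""
    header, k, data_size, records = collect_records(in_path)
    sections = naive_sections(records, k, data_size) if k is not None else []
    write_file(header, sections, out_path)
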