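"""Deterministic synthetic k-mer sets and ready-made fixture files.

Real k-mer collections come out of k-mer counters run on sequencing reads;
what makes them compressible is the *spectrum-like property*: most k-mers
arise as windows of a few long underlying strings.  The generator here
emulates exactly that — a handful of uniform random source strings whose
windows form the k-mer set (with occurrence counts), plus an optional dash
of isolated random "noise" k-mers standing in for sequencing errors.  It is
fully reproducible from its seed, which is recorded in the metadata field of
every fixture file written.

Also provided is the toy worked example used throughout the documentation:
the 12-nt sequence ``ACTAAACTGATG`` with k=10 and m=8, whose minimizer
``AAACTGAT`` sits at position 3, stored once as a raw section and once as
the equivalent minimizer section (skeleton ``ACTG``).
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .errors import ParameterError
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
from .compaction import naive_sections, spss_sections, superkmer_sections

# the toy example: one 12-mer, three 10-mers, minimizer of size 8
TOY_SEQUENCE = "ACTAAACTGATG"
TOY_K = 10
TOY_M = 8
TOY_MINIMIZER = "AAACTGAT"
TOY_MINIMIZER_POSITION = 3
TOY_SKELETON = "ACTG"
TOY_KMERS = ("ACTAAACTGA", "CTAAACTGAT", "TAAACTGATG")


@dataclass(frozen=True)
class SpectrumParams:
    """Parameters of the spectrum-like generator.

    ``n_strings`` uniform random source strings of ``string_length`` nt are
    drawn; the k-mer set is the union of their length-k windows with
    occurrence counts, plus ``noise_kmers`` isolated uniform random k-mers
    (which may collide with genuine k-mers, merging counts — as error
    k-mers do in real counters).
    """

    n_strings: int = 10
    string_length: int = 100_000
    k: int = 32
    noise_kmers: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.string_length < self.k:
            raise ParameterError(
                f"string_length={self.string_length} shorter than k={self.k}"
            )
        if min(self.n_strings, self.k, self.noise_kmers) < 0 or self.k == 0:
            raise ParameterError("counts must be >= 0 and k >= 1")


def generate_spectrum_set(
    params: SpectrumParams,
) -> tuple[list[str], dict[str, int]]:
    """Draw source strings and their k-mer multiset, reproducibly.

    Returns ``(source_strings, {kmer: count})``; counts sum to the total
    number of windows plus noise draws.  The generator is Python's seeded
    Mersenne Twister, so output is identical across runs and machines.
    """
    rng = random.Random(params.seed)
    strings = [
        "".join(rng.choices("ACGT", k=params.string_length))
        for _ in range(params.n_strings)
    ]
    counts: Counter[str] = Counter()
    for s in strings:
        for i in range(len(s) - params.k + 1):
            counts[s[i : i + params.k]] += 1
    for _ in range(params.noise_kmers):
        counts["".join(rng.choices("ACGT", k=params.k))] += 1
    return strings, dict(counts)


def records_with_counts(
    counts: dict[str, int], data_size: int
) -> list[tuple[str, bytes]]:
    """Sorted (k-mer, big-endian count) records ready for the writers."""
    if data_size == 0:
        return [(kmer, b"") for kmer in sorted(counts)]
    return [
        (kmer, counts[kmer].to_bytes(data_size, "big")) for kmer in sorted(counts)
    ]


def toy_sections() -> list[Section]:
    """The toy file body: variables, a raw section and the equivalent
    minimizer section holding the same three 10-mers."""
    return [
        ValuesSection({"k": TOY_K, "max": 255, "data_size": 0, "m": TOY_M}),
        RawSection([SequenceBlock(TOY_SEQUENCE)]),
        MinimizerSection(
            TOY_MINIMIZER,
            [MinimizerBlock(TOY_SKELETON, TOY_MINIMIZER_POSITION)],
        ),
    ]


def write_toy_file(path: str | Path) -> Path:
    """Materialize the toy file (unique within each section, non-canonical)."""
    path = Path(path)
    header = FileHeader(unique_kmers=True, metadata=b'{"fixture": "toy"}')
    write_file(header, toy_sections(), path)
    return path


def write_fasta(strings: list[str], path: str | Path, width: int = 70) -> Path:
    """Emit source strings as FASTA for end-to-end demos with k-mer counters."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, s in enumerate(strings):
            fh.write(f">source_{i}\n")
            for j in range(0, len(s), width):
                fh.write(s[j : j + width] + "\n")
    return path


def write_fixture_suite(directory: str | Path) -> dict[str, Path]:
    """Write the standard fixture files into a directory.

    Produces the toy file plus a small and a medium spectrum-like set, each
    in naive, super-k-mer and greedy-SPSS layouts (counts carried as 2-byte
    payloads), a matching text dump and the source strings as FASTA.
    Returns a name -> path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {"toy": write_toy_file(directory / "toy.kff")}

    suites = {
        "small": (SpectrumParams(5, 400, 21, noise_kmers=10, seed=42), 8),
        "medium": (SpectrumParams(20, 2000, 32, noise_kmers=50, seed=43), 10),
    }
    for name, (params, m) in suites.items():
        strings, counts = generate_spectrum_set(params)
        records = records_with_counts(counts, data_size=2)
        metadata = json.dumps(
            {"generator": "spectrum", "seed": params.seed, "k": params.k}
        ).encode()
        header = FileHeader(unique_kmers=True, metadata=metadata)
        layouts = {
            "naive": naive_sections(records, params.k, data_size=2),
            "superkmer": superkmer_sections(records, params.k, m, data_size=2),
            "spss": spss_sections(records, params.k, data_size=2),
        }
        for layout, sections in layouts.items():
            path = directory / f"{name}_{layout}.kff"
            write_file(header, sections, path)
            out[f"{name}_{layout}"] = path
        text = directory / f"{name}.tsv"
        with open(text, "w") as fh:
            for kmer in sorted(counts):
                fh.write(f"{kmer}\t{counts[kmer]}\n")
        out[f"{name}_text"] = text
        out[f"{name}_fasta"] = write_fasta(strings, directory / f"{name}.fasta")
    return out
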