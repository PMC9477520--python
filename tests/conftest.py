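"""Shared test helpers: randomized file models and multiset comparison."""

from __future__ import annotations

import random
from collections import Counter

import pytest

from kffio import (
    Encoding,
    FileHeader,
    IndexEntry,
    IndexSection,
    MinimizerBlock,
    MinimizerSection,
    RawSection,
    SequenceBlock,
    ValuesSection,
    iterate_kmers,
)


def rand_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choices("ACGT", k=length))


def random_file_model(rng: random.Random):
    """A random but well-formed (header, sections) pair.

    Random encoding permutation, k in 2..64, m in 1..k, data_size in 0..4,
    a mix of raw, minimizer and index sections, and occasional mid-file
    redefinition of max/data_size.
    """
    enc = Encoding(*rng.sample(range(4), 4))
    k = rng.randint(2, 64)
    m = rng.randint(1, k)
    data_size = rng.randint(0, 4)
    max_ = 1 if rng.random() < 0.25 else rng.randint(2, 300)
    header = FileHeader(
        enc,
        unique_kmers=False,
        canonical_kmers=False,
        metadata=rng.randbytes(rng.randint(0, 8)),
    )
    sections = [
        ValuesSection({"k": k, "max": max_, "data_size": data_size, "m": m})
    ]
    for _ in range(rng.randint(0, 4)):
        roll = rng.random()
        if roll < 0.40:
            blocks = []
            for _ in range(rng.randint(1, 3)):
                n = rng.randint(1, min(max_, 6))
                blocks.append(
                    SequenceBlock(
                        rand_seq(rng, n + k - 1), rng.randbytes(n * data_size)
                    )
                )
            sections.append(RawSection(blocks))
        elif roll < 0.80:
            blocks = []
            for _ in range(rng.randint(1, 3)):
                n = rng.randint(1, min(max_, 6))
                skeleton = rand_seq(rng, n + k - 1 - m)
                blocks.append(
                    MinimizerBlock(
                        skeleton,
                        rng.randint(0, len(skeleton)),
                        rng.randbytes(n * data_size),
                    )
                )
            sections.append(MinimizerSection(rand_seq(rng, m), blocks))
        elif roll < 0.90:
            entries = [
                IndexEntry(rng.choice("vrmi"), rng.randint(-(2**40), 2**40))
                for _ in range(rng.randint(0, 3))
            ]
            sections.append(IndexSection(entries, 0))
        else:
            max_ = 1 if rng.random() < 0.25 else rng.randint(2, 300)
            data_size = rng.randint(0, 4)
            sections.append(
                ValuesSection({"max": max_, "data_size": data_size})
            )
    return header, sections


def kmer_multiset(path) -> Counter:
    """The (k-mer, data) multiset of a file, for losslessness checks."""
    return Counter((r.kmer, r.data) for r in iterate_kmers(path))


@pytest.fixture
def toy_file(tmp_path):
    from kffio.fixtures import write_toy_file

    return write_toy_file(tmp_path / "toy.kff")
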