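"""Minimizers, super-k-mer splitting, greedy SPSS and lossless re-layout."""

import random
from collections import Counter

import pytest

from conftest import kmer_multiset, rand_seq
from kffio import (
    FileHeader,
    bucket_and_write_minimizer_sections,
    compact_file,
    greedy_compact,
    iterate_kmers,
    kmers_of_sequence,
    minimizer_of,
    split_into_superkmers,
    uncompact,
    write_file,
)
from kffio.compaction import naive_sections, spss_sections, superkmer_sections
from kffio.errors import DuplicateKmerError, TooShortError
from kffio.fixtures import (
    SpectrumParams,
    TOY_KMERS,
    generate_spectrum_set,
    records_with_counts,
    write_toy_file,
)


def brute_minimizer(sequence, m):
    windows = [sequence[i : i + m] for i in range(len(sequence) - m + 1)]
    best = min(windows)
    return best, windows.index(best)


def test_toy_minimizer_sits_at_position_3():
    assert minimizer_of("ACTAAACTGATG", 8) == ("AAACTGAT", 3)


def test_minimizer_tie_breaks_to_the_leftmost_occurrence():
    assert minimizer_of("AAAA", 2) == ("AA", 0)


def test_minimizer_rejects_short_sequences():
    with pytest.raises(TooShortError):
        minimizer_of("ACG", 4)


def test_minimizer_matches_exhaustive_scan_on_random_sequences():
    rng = random.Random(11)
    for _ in range(2000):
        m = rng.randint(1, 10)
        seq = rand_seq(rng, rng.randint(m, 50))
        assert minimizer_of(seq, m) == brute_minimizer(seq, m)


def test_toy_sequence_splits_into_two_superkmers():
    sks = split_into_superkmers("ACTAAACTGATG", k=10, m=8)
    assert [(s.sequence, s.minimizer) for s in sks] == [
        ("ACTAAACTGA", "ACTAAACT"),
        ("CTAAACTGATG", "AAACTGAT"),
    ]
    # each super-k-mer contains its minimizer at the stated position
    for s in sks:
        assert s.sequence[s.minimizer_position :].startswith(s.minimizer)


def test_length_k_sequence_is_a_single_superkmer():
    sks = split_into_superkmers("ACGTACGT", k=8, m=3)
    assert len(sks) == 1 and sks[0].sequence == "ACGTACGT"


def test_superkmers_cover_each_window_exactly_once():
    rng = random.Random(23)
    for _ in range(300):
        k = rng.randint(4, 24)
        m = rng.randint(1, k)
        seq = rand_seq(rng, rng.randint(k, k + 40))
        sks = split_into_superkmers(seq, k, m)
        covered = []
        for s in sks:
            covered.extend(kmers_of_sequence(s.sequence, k))
            # strictness: every window of a super-k-mer has the same minimizer
            for w in kmers_of_sequence(s.sequence, k):
                assert brute_minimizer(w, m)[0] == s.minimizer
        assert covered == kmers_of_sequence(seq, k)


def test_greedy_compact_joins_overlapping_kmers():
    assert greedy_compact({"ACG", "CGT"}, 3) == ["ACGT"]
    assert greedy_compact({"AAA"}, 3) == ["AAA"]
    assert greedy_compact([], 3) == []


def test_greedy_compact_rejects_duplicates():
    with pytest.raises(DuplicateKmerError):
        greedy_compact(["ACG", "ACG"], 3)


def test_greedy_compact_windows_equal_input_set_exactly_once():
    rng = random.Random(31)
    for seed in range(5):
        _, counts = generate_spectrum_set(
            SpectrumParams(3, 200, 21, noise_kmers=20, seed=seed)
        )
        kmer_set = set(counts)
        strings = greedy_compact(kmer_set, 21)
        windows = Counter()
        for s in strings:
            windows.update(kmers_of_sequence(s, 21))
        assert windows == Counter({kmer: 1 for kmer in kmer_set})
        assert len(strings) <= len(kmer_set)
        assert sum(len(s) for s in strings) <= len(kmer_set) * 21


def test_bucketing_the_toy_kmers_streams_them_back(tmp_path):
    sections = superkmer_sections(
        [(kmer, b"") for kmer in TOY_KMERS], k=10, m=8, data_size=0
    )
    path = tmp_path / "bucketed.kff"
    write_file(FileHeader(unique_kmers=True), sections, path)
    assert {r.kmer for r in iterate_kmers(path)} == set(TOY_KMERS)


def test_single_kmer_bucket_has_a_k_minus_m_skeleton():
    sections = bucket_and_write_minimizer_sections(
        [("ACGTACGT", b"")], k=8, m=3, max_=255, data_size=0
    )
    assert len(sections) == 1 and len(sections[0].blocks) == 1
    assert len(sections[0].blocks[0].skeleton) == 8 - 3


def test_bucketing_respects_max_by_chunking(tmp_path):
    _, counts = generate_spectrum_set(SpectrumParams(2, 120, 11, seed=5))
    sections = bucket_and_write_minimizer_sections(
        records_with_counts(counts, 1), k=11, m=4, max_=2, data_size=1
    )
    for section in sections:
        for block in section.blocks:
            assert 1 <= block.n_kmers(11, 4) <= 2
    from kffio import ValuesSection

    path = tmp_path / "chunked.kff"
    write_file(
        FileHeader(unique_kmers=True),
        [ValuesSection({"k": 11, "max": 2, "data_size": 1, "m": 4}), *sections],
        path,
    )
    got = {(r.kmer, r.data) for r in iterate_kmers(path)}
    want = set(records_with_counts(counts, 1))
    assert got == want


def test_compaction_paths_preserve_kmers_and_data(tmp_path):
    _, counts = generate_spectrum_set(
        SpectrumParams(4, 300, 15, noise_kmers=15, seed=9)
    )
    records = records_with_counts(counts, 2)
    naive = tmp_path / "naive.kff"
    write_file(FileHeader(), naive_sections(records, 15, 2), naive)
    reference = kmer_multiset(naive)
    for mode in ("naive", "superkmer", "spss"):
        out = tmp_path / f"{mode}.kff"
        compact_file(naive, out, mode, m=6)
        assert kmer_multiset(out) == reference, mode
    # uncompact inverts compaction
    back = tmp_path / "back.kff"
    uncompact(tmp_path / "superkmer.kff", back)
    assert kmer_multiset(back) == reference


def test_uncompact_turns_the_toy_m_section_into_single_kmer_blocks(tmp_path):
    toy = write_toy_file(tmp_path / "toy.kff")
    out = tmp_path / "naive.kff"
    uncompact(toy, out)
    from kffio import RawSection, ValuesSection, scan_file

    _, pairs, _ = scan_file(out)
    raw = [s for _, s in pairs if isinstance(s, RawSection)]
    values = [s for _, s in pairs if isinstance(s, ValuesSection)]
    assert values[0].variables["max"] == 1
    assert all(len(b.sequence) == 10 for sec in raw for b in sec.blocks)
    assert kmer_multiset(out) == kmer_multiset(toy)


def test_superkmer_layout_beats_naive_on_spectrum_data(tmp_path):
    _, counts = generate_spectrum_set(SpectrumParams(5, 800, 32, seed=13))
    records = records_with_counts(counts, 0)
    naive, sk = tmp_path / "naive.kff", tmp_path / "sk.kff"
    write_file(FileHeader(), naive_sections(records, 32, 0), naive)
    write_file(
        FileHeader(unique_kmers=True),
        superkmer_sections(records, 32, 10, 0),
        sk,
    )
    assert sk.stat().st_size < naive.stat().st_size
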