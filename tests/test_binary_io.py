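"""Wire format: exact field widths, parse errors, round trips, indexing."""

import io
import random

import pytest

from conftest import random_file_model
from kffio import (
    FileHeader,
    IndexEntry,
    IndexSection,
    MinimizerBlock,
    MinimizerSection,
    RawSection,
    SequenceBlock,
    ValuesSection,
    VariableState,
    build_index,
    read_file,
    scan_file,
    validate_file,
    write_file,
)
from kffio.errors import (
    BlockOverflowError,
    MissingVariableError,
    NotAKffError,
    OrderingError,
    TruncationError,
    UnknownSectionError,
)
from kffio.io import (
    walk_index_chain,
    write_index_section,
    write_minimizer_section,
    write_raw_section,
    write_values_section,
)
from kffio.fixtures import toy_sections, write_toy_file

TOY_VARS = {"k": 10, "max": 255, "data_size": 0, "m": 8}


def write_bytes(header, sections) -> bytes:
    buf = io.BytesIO()
    write_file(header, sections, buf)
    return buf.getvalue()


def reread(data: bytes):
    header, sections = read_file(io.BytesIO(data))
    return header, list(sections)


# ---------------------------------------------------------------------------
# field widths


def test_header_only_file_is_15_bytes_plus_metadata():
    assert len(write_bytes(FileHeader(), [])) == 15
    assert len(write_bytes(FileHeader(metadata=b"abc"), [])) == 18


def test_values_section_of_the_toy_variables_is_59_bytes():
    buf = io.BytesIO()
    # 1 + 8 + (2+8) + (4+8) + (10+8) + (2+8)
    assert write_values_section(dict(TOY_VARS), buf) == 59


def test_empty_values_section_is_9_bytes():
    buf = io.BytesIO()
    assert write_values_section({}, buf) == 9


def test_raw_section_of_the_toy_sequence_is_9_bytes():
    buf = io.BytesIO()
    n = write_raw_section(
        RawSection([SequenceBlock("ACTAAACTGATG")]),
        VariableState(TOY_VARS),
        FileHeader().encoding,
        buf,
    )
    assert n == 1 + 4 + 1 + 3  # type, count, n, ceil(12/4) payload


def test_raw_block_of_one_32mer_with_max_1_has_8_payload_bytes():
    buf = io.BytesIO()
    n = write_raw_section(
        RawSection([SequenceBlock("ACGT" * 8)]),
        VariableState({"k": 32, "max": 1, "data_size": 0}),
        FileHeader().encoding,
        buf,
    )
    # n field omitted when max=1: type + count + 64-bit packed sequence
    assert n == 1 + 4 + 8


def test_minimizer_section_width_follows_the_position_bound():
    # position bound is max + k - 1 - m = 256 -> 9 bits -> 2 bytes
    buf = io.BytesIO()
    n = write_minimizer_section(
        MinimizerSection("AAACTGAT", [MinimizerBlock("ACTG", 3)]),
        VariableState(TOY_VARS),
        FileHeader().encoding,
        buf,
    )
    assert n == 1 + 2 + 4 + (1 + 2 + 1)


def test_empty_index_section_is_13_bytes():
    buf = io.BytesIO()
    assert write_index_section(IndexSection([], 0), buf) == 13


# ---------------------------------------------------------------------------
# parse behaviour


def test_bad_leading_magic_raises_not_a_kff():
    with pytest.raises(NotAKffError):
        read_file(io.BytesIO(b"KFX" + b"\x00" * 20))


def test_self_written_version_reads_back_as_1_0():
    header, _ = reread(write_bytes(FileHeader(), []))
    assert header.version == (1, 0)


def test_unknown_section_type_aborts_with_offset():
    data = write_bytes(FileHeader(), [])[:-3] + b"zzz"
    header, sections = read_file(io.BytesIO(data))
    with pytest.raises(UnknownSectionError, match="offset 12"):
        list(sections)


def test_sequence_section_before_variables_is_an_ordering_error():
    with pytest.raises(OrderingError):
        write_bytes(FileHeader(), [RawSection([SequenceBlock("ACGT")])])


def test_minimizer_section_without_m_is_a_missing_variable_error():
    sections = [
        ValuesSection({"k": 4, "max": 2, "data_size": 0}),
        MinimizerSection("AC", [MinimizerBlock("AC", 0)]),
    ]
    with pytest.raises(MissingVariableError):
        write_bytes(FileHeader(), sections)


def test_block_larger_than_max_is_rejected_on_write_and_read():
    with pytest.raises(BlockOverflowError):
        write_bytes(
            FileHeader(),
            [
                ValuesSection({"k": 3, "max": 2, "data_size": 0}),
                RawSection([SequenceBlock("ACGTACG")]),  # 5 k-mers
            ],
        )
    # forge the same overflow on the wire: declare max=2, store n=3
    good = write_bytes(
        FileHeader(),
        [
            ValuesSection({"k": 3, "max": 3, "data_size": 0}),
            RawSection([SequenceBlock("ACGTA")]),  # n=3
        ],
    )
    forged = bytearray(good)
    key = b"max\x00" + (3).to_bytes(8, "big")
    at = forged.find(key)
    forged[at : at + len(key)] = b"max\x00" + (2).to_bytes(8, "big")
    header, sections = read_file(io.BytesIO(bytes(forged)))
    with pytest.raises(BlockOverflowError):
        list(sections)


def test_truncated_section_raises_truncation_error():
    data = write_bytes(
        FileHeader(),
        [ValuesSection(TOY_VARS), RawSection([SequenceBlock("ACTAAACTGATG")])],
    )
    header, sections = read_file(io.BytesIO(data[:-5]))
    with pytest.raises(TruncationError):
        list(sections)


def test_missing_end_magic_parses_but_warns(tmp_path):
    data = write_bytes(FileHeader(), [ValuesSection(TOY_VARS)])
    path = tmp_path / "truncated.kff"
    path.write_bytes(data[:-3])
    header, sections = read_file(path)
    assert len(list(sections)) == 1
    violations, warnings = validate_file(path)
    assert violations == [] and len(warnings) == 1


def test_later_values_sections_override_earlier_ones():
    sections = [
        ValuesSection({"k": 3, "max": 10, "data_size": 0}),
        RawSection([SequenceBlock("ACGT")]),
        ValuesSection({"k": 4}),
        RawSection([SequenceBlock("ACGT")]),
    ]
    _, got = reread(write_bytes(FileHeader(), sections))
    assert got == sections


# ---------------------------------------------------------------------------
# round trips


def test_toy_file_roundtrips_to_an_identical_model():
    header = FileHeader(unique_kmers=True)
    data = write_bytes(header, toy_sections())
    got_header, got_sections = reread(data)
    assert got_header == header
    assert got_sections == toy_sections()


def test_200_randomized_files_roundtrip_and_reserialize_bit_identically():
    rng = random.Random(20_240_001)
    for _ in range(200):
        header, sections = random_file_model(rng)
        data = write_bytes(header, sections)
        got_header, got_sections = reread(data)
        assert got_header == header
        assert got_sections == sections
        assert write_bytes(got_header, got_sections) == data


# ---------------------------------------------------------------------------
# index


def test_build_index_resolves_every_section(toy_file, tmp_path):
    out = tmp_path / "indexed.kff"
    section = build_index(toy_file, out)
    assert [e.section_type for e in section.entries] == ["v", "r", "m"]
    assert all(e.relative_offset < 0 for e in section.entries)
    violations, warnings = validate_file(out)
    assert violations == [] and warnings == []


def test_reindexing_replaces_the_old_index(toy_file, tmp_path):
    once = tmp_path / "once.kff"
    twice = tmp_path / "twice.kff"
    build_index(toy_file, once)
    build_index(once, twice)
    _, pairs, _ = scan_file(twice)
    assert sum(1 for d, _ in pairs if d.section_type == "i") == 1
    assert once.read_bytes() == twice.read_bytes()


def test_indexing_a_header_only_file_yields_an_empty_index(tmp_path):
    src, out = tmp_path / "empty.kff", tmp_path / "indexed.kff"
    write_file(FileHeader(), [], src)
    section = build_index(src, out)
    assert section.entries == []


def test_index_chain_walker_enumerates_linked_indexes(tmp_path):
    # layout: header | V(59) | I1(13, next -> I2 after the 9-byte R) | R(9) | I2
    sections = [
        ValuesSection(TOY_VARS),
        IndexSection([], next_index_offset=9),
        RawSection([SequenceBlock("ACTAAACTGATG")]),
        IndexSection([], 0),
    ]
    path = tmp_path / "chained.kff"
    write_file(FileHeader(), sections, path)
    chain = walk_index_chain(path, 12 + 59)
    assert len(chain) == 2
    assert [offset for offset, _ in chain] == [71, 71 + 13 + 9]


def test_build_index_preserves_the_kmer_stream(tmp_path):
    from conftest import kmer_multiset

    rng = random.Random(7)
    for _ in range(20):
        header, sections = random_file_model(rng)
        src, out = tmp_path / "src.kff", tmp_path / "out.kff"
        write_file(header, sections, src)
        build_index(src, out)
        assert kmer_multiset(out) == kmer_multiset(src)
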