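"""Bit-exact serialization of the KFF dialect.

Wire layout (all multi-byte integers big-endian):

* file header — magic ``KFF``; one byte each of major and minor version;
  one encoding byte (codes of A, C, G, T packed high-to-low); one uniqueness
  byte; one canonicity byte; 4-byte ``free_size``; ``free_size`` metadata
  bytes.  The file ends with the magic ``KFF`` again.
* ``v`` section — 8-byte variable count, then per variable a NUL-terminated
  ASCII name and an 8-byte value.
* ``r`` section — 4-byte block count; per block the k-mer count ``n``
  (``ceil(bits(max)/8)`` bytes, omitted entirely when ``max == 1``), the
  packed sequence of ``n + k - 1`` nucleotides, and ``n * data_size`` data
  bytes.
* ``m`` section — packed minimizer of ``m`` nucleotides; 4-byte block count;
  per block ``n`` as above, the minimizer position
  (``ceil(bits(max + k - 1 - m)/8)`` bytes), the packed skeleton of
  ``n + k - 1 - m`` nucleotides, and the data bytes.
* ``i`` section — 4-byte entry count; per entry one section-type byte and an
  8-byte *signed* offset relative to the first byte after this index
  section; then an 8-byte signed offset to the next index section in the
  chain (0 = none).

A missing end magic is tolerated on read (streams may be truncated
deliberately) and surfaces as a validation warning, never a parse error.
Unknown section types abort parsing: without a length field there is no safe
way to skip them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterable, Iterator

from .encoding import Encoding, decode_sequence, encode_sequence, PackedSequence
from .errors import (
    BlockOverflowError,
    EmptyBlockError,
    KffError,
    MalformedBlockError,
    MalformedVariableError,
    NotAKffError,
    OrderingError,
    ParameterError,
    TruncationError,
    UnknownSectionError,
)
from .model import (
    FileHeader,
    IndexEntry,
    IndexSection,
    MinimizerBlock,
    MinimizerSection,
    RawSection,
    Section,
    SequenceBlock,
    U64_MAX,
    ValuesSection,
    VariableState,
    validate_section,
)

MAGIC = b"KFF"

SECTION_TYPES = frozenset("vrmi")


def n_field_width(max_: int) -> int:
    """Bytes used to store a block's k-mer count ``n``.

    Computable from ``max`` alone so blocks need no per-block headers; the
    field is omitted on the wire when ``max == 1``.
    """
    return (max(max_.bit_length(), 1) + 7) // 8


def position_field_width(max_: int, k: int, m: int) -> int:
    """Bytes used to store a minimizer position (bounded by max + k - 1 - m)."""
    return max(1, ((max_ + k - 1 - m).bit_length() + 7) // 8)


@dataclass(frozen=True)
class SectionDescriptor:
    """Location of one section: type character, absolute offset, byte length."""

    section_type: str
    byte_start: int
    byte_length: int


class _Reader:
    """Counting byte reader over any binary stream (seekable or not)."""

    def __init__(self, raw: BinaryIO) -> None:
        self._raw = raw
        self.offset = 0
        self.end_magic_seen = False

    def read_maybe(self, n: int) -> bytes:
        """Read up to ``n`` bytes; short only at end of stream."""
        chunks = []
        remaining = n
        while remaining:
            chunk = self._raw.read(remaining)
            if not chunk:
                break
            chunks.append(chunk)
            remaining -= len(chunk)
        data = b"".join(chunks)
        self.offset += len(data)
        return data

    def read_exact(self, n: int) -> bytes:
        data = self.read_maybe(n)
        if len(data) != n:
            raise TruncationError(
                f"stream ended at offset {self.offset}: "
                f"wanted {n} bytes, got {len(data)}"
            )
        return data

    def read_uint(self, width: int) -> int:
        return int.from_bytes(self.read_exact(width), "big")

    def read_int(self, width: int) -> int:
        return int.from_bytes(self.read_exact(width), "big", signed=True)


# ---------------------------------------------------------------------------
# header


def write_header(header: FileHeader, sink: BinaryIO) -> int:
    major, minor = header.version
    out = bytearray(MAGIC)
    out += bytes((major, minor, header.encoding.to_byte()))
    out += bytes((int(bool(header.unique_kmers)), int(bool(header.canonical_kmers))))
    out += len(header.metadata).to_bytes(4, "big")
    out += header.metadata
    sink.write(bytes(out))
    return len(out)


def read_header(reader: _Reader) -> FileHeader:
    magic = reader.read_maybe(3)
    if magic != MAGIC:
        raise NotAKffError(f"bad leading magic {magic!r}")
    major, minor = reader.read_exact(2)
    encoding = Encoding.from_byte(reader.read_exact(1)[0])
    unique = reader.read_exact(1)[0] != 0
    canon = reader.read_exact(1)[0] != 0
    free_size = reader.read_uint(4)
    metadata = reader.read_exact(free_size)
    return FileHeader(encoding, unique, canon, metadata, (major, minor))


def header_size(header: FileHeader) -> int:
    return 12 + len(header.metadata)


# ---------------------------------------------------------------------------
# section writers (each returns the byte count it emitted)


def write_values_section(variables: dict[str, int], sink: BinaryIO) -> int:
    out = bytearray(b"v")
    out += len(variables).to_bytes(8, "big")
    for name, value in variables.items():
        if not name or not name.isascii() or "\x00" in name:
            raise MalformedVariableError(f"bad variable name {name!r}")
        if not 0 <= value <= U64_MAX:
            raise MalformedVariableError(f"variable {name}={value} outside u64")
        out += name.encode("ascii") + b"\x00"
        out += value.to_bytes(8, "big")
    sink.write(bytes(out))
    return len(out)


def _require_sequence_vars(state: VariableState) -> tuple[int, int, int]:
    state.require(*VariableState.REQUIRED_FOR_SEQUENCES, error=OrderingError)
    k, max_, data_size = state.k, state.max, state.data_size
    if k < 1 or max_ < 1 or data_size < 0:
        raise ParameterError(
            f"invalid variables k={k}, max={max_}, data_size={data_size}"
        )
    return k, max_, data_size


def write_raw_section(
    section: RawSection, state: VariableState, encoding: Encoding, sink: BinaryIO
) -> int:
    k, max_, data_size = _require_sequence_vars(state)
    w_n = n_field_width(max_)
    out = bytearray(b"r")
    out += len(section.blocks).to_bytes(4, "big")
    for block in section.blocks:
        n = block.n_kmers(k)
        if n < 1:
            raise EmptyBlockError(
                f"sequence of {len(block.sequence)} nt holds no {k}-mer"
            )
        if n > max_:
            raise BlockOverflowError(f"block of {n} k-mers exceeds max={max_}")
        if len(block.data) != n * data_size:
            raise MalformedBlockError(
                f"{len(block.data)} data bytes, expected {n}x{data_size}"
            )
        if max_ > 1:
            out += n.to_bytes(w_n, "big")
        out += encode_sequence(block.sequence, encoding).payload
        out += block.data
    sink.write(bytes(out))
    return len(out)


def write_minimizer_section(
    section: MinimizerSection, state: VariableState, encoding: Encoding, sink: BinaryIO
) -> int:
    k, max_, data_size = _require_sequence_vars(state)
    state.require("m")
    m = state.m
    if not 1 <= m <= k:
        raise ParameterError(f"m={m} outside 1..k={k}")
    if len(section.minimizer) != m:
        raise MalformedBlockError(
            f"minimizer {section.minimizer!r} is not an {m}-mer"
        )
    w_n = n_field_width(max_)
    w_p = position_field_width(max_, k, m)
    out = bytearray(b"m")
    out += encode_sequence(section.minimizer, encoding).payload
    out += len(section.blocks).to_bytes(4, "big")
    for block in section.blocks:
        n = block.n_kmers(k, m)
        if n < 1:
            raise EmptyBlockError(
                f"skeleton of {len(block.skeleton)} nt holds no {k}-mer"
            )
        if n > max_:
            raise BlockOverflowError(f"block of {n} k-mers exceeds max={max_}")
        if not 0 <= block.minimizer_position <= len(block.skeleton):
            raise MalformedBlockError(
                f"minimizer position {block.minimizer_position} outside "
                f"skeleton of length {len(block.skeleton)}"
            )
        if len(block.data) != n * data_size:
            raise MalformedBlockError(
                f"{len(block.data)} data bytes, expected {n}x{data_size}"
            )
        if max_ > 1:
            out += n.to_bytes(w_n, "big")
        out += block.minimizer_position.to_bytes(w_p, "big")
        out += encode_sequence(block.skeleton, encoding).payload
        out += block.data
    sink.write(bytes(out))
    return len(out)


def write_index_section(section: IndexSection, sink: BinaryIO) -> int:
    out = bytearray(b"i")
    out += len(section.entries).to_bytes(4, "big")
    for entry in section.entries:
        if entry.section_type not in SECTION_TYPES:
            raise UnknownSectionError(
                f"index entry with unknown type {entry.section_type!r}"
            )
        out += entry.section_type.encode("ascii")
        out += entry.relative_offset.to_bytes(8, "big", signed=True)
    out += section.next_index_offset.to_bytes(8, "big", signed=True)
    sink.write(bytes(out))
    return len(out)


def write_section(
    section: Section, state: VariableState, encoding: Encoding, sink: BinaryIO
) -> int:
    """Write one section and fold values sections into ``state``."""
    if isinstance(section, ValuesSection):
        n = write_values_section(section.variables, sink)
        state.update(section.variables)
        return n
    if isinstance(section, RawSection):
        return write_raw_section(section, state, encoding, sink)
    if isinstance(section, MinimizerSection):
        return write_minimizer_section(section, state, encoding, sink)
    if isinstance(section, IndexSection):
        return write_index_section(section, sink)
    raise TypeError(f"not a KFF section: {section!r}")


def write_file(
    header: FileHeader,
    sections: Iterable[Section],
    sink: BinaryIO | str | Path,
) -> int:
    """Serialize a whole file; returns the total byte count written."""
    if isinstance(sink, (str, Path)):
        with open(sink, "wb") as fh:
            return write_file(header, sections, fh)
    total = write_header(header, sink)
    state = VariableState()
    for section in sections:
        total += write_section(section, state, header.encoding, sink)
    sink.write(MAGIC)
    return total + len(MAGIC)


# ---------------------------------------------------------------------------
# section readers


def _read_values(reader: _Reader) -> ValuesSection:
    count = reader.read_uint(8)
    variables: dict[str, int] = {}
    for _ in range(count):
        raw_name = bytearray()
        while True:
            byte = reader.read_exact(1)
            if byte == b"\x00":
                break
            raw_name += byte
        if not raw_name or not all(b < 128 for b in raw_name):
            raise MalformedVariableError(f"bad variable name {bytes(raw_name)!r}")
        variables[raw_name.decode("ascii")] = reader.read_uint(8)
    return ValuesSection(variables)


def _read_block_count(reader: _Reader, max_: int) -> int:
    if max_ == 1:
        return 1
    n = reader.read_uint(n_field_width(max_))
    if n == 0:
        raise EmptyBlockError("block with n=0 k-mers")
    if n > max_:
        raise BlockOverflowError(f"block of {n} k-mers exceeds max={max_}")
    return n


def _read_packed(reader: _Reader, nt: int, encoding: Encoding) -> str:
    payload = reader.read_exact((nt + 3) // 4)
    return decode_sequence(PackedSequence(payload, nt), encoding)


def _read_raw(reader: _Reader, state: VariableState, encoding: Encoding) -> RawSection:
    k, max_, data_size = _require_sequence_vars(state)
    blocks = []
    for _ in range(reader.read_uint(4)):
        n = _read_block_count(reader, max_)
        sequence = _read_packed(reader, n + k - 1, encoding)
        data = reader.read_exact(n * data_size)
        blocks.append(SequenceBlock(sequence, data))
    return RawSection(blocks)


def _read_minimizer(
    reader: _Reader, state: VariableState, encoding: Encoding
) -> MinimizerSection:
    k, max_, data_size = _require_sequence_vars(state)
    state.require("m")
    m = state.m
    if not 1 <= m <= k:
        raise ParameterError(f"m={m} outside 1..k={k}")
    w_p = position_field_width(max_, k, m)
    minimizer = _read_packed(reader, m, encoding)
    blocks = []
    for _ in range(reader.read_uint(4)):
        n = _read_block_count(reader, max_)
        position = reader.read_uint(w_p)
        skeleton = _read_packed(reader, n + k - 1 - m, encoding)
        if position > len(skeleton):
            raise MalformedBlockError(
                f"minimizer position {position} outside skeleton "
                f"of length {len(skeleton)}"
            )
        data = reader.read_exact(n * data_size)
        blocks.append(MinimizerBlock(skeleton, position, data))
    return MinimizerSection(minimizer, blocks)


def _read_index(reader: _Reader) -> IndexSection:
    entries = []
    for _ in range(reader.read_uint(4)):
        type_byte = reader.read_exact(1)
        type_char = chr(type_byte[0])
        if type_char not in SECTION_TYPES:
            raise UnknownSectionError(
                f"index entry with unknown type byte {type_byte!r}"
            )
        entries.append(IndexEntry(type_char, reader.read_int(8)))
    return IndexSection(entries, reader.read_int(8))


def _iter_sections(
    reader: _Reader, header: FileHeader
) -> Iterator[tuple[SectionDescriptor, Section]]:
    """Yield (descriptor, section) pairs until end magic or end of stream.

    Sets ``reader.end_magic_seen`` when the terminal magic was present.
    """
    state = VariableState()
    while True:
        start = reader.offset
        type_byte = reader.read_maybe(1)
        if type_byte == b"":
            return  # truncated stream: tolerated, flagged by validate
        if type_byte == MAGIC[:1]:
            if reader.read_maybe(2) == MAGIC[1:]:
                reader.end_magic_seen = True
                return
            raise UnknownSectionError(f"unexpected bytes at offset {start}")
        type_char = chr(type_byte[0])
        if type_char == "v":
            section: Section = _read_values(reader)
            state.update(section.variables)
        elif type_char == "r":
            section = _read_raw(reader, state, header.encoding)
        elif type_char == "m":
            section = _read_minimizer(reader, state, header.encoding)
        elif type_char == "i":
            section = _read_index(reader)
        else:
            raise UnknownSectionError(
                f"unknown section type {type_byte!r} at offset {start}"
            )
        yield SectionDescriptor(type_char, start, reader.offset - start), section


def read_file(
    source: BinaryIO | str | Path,
) -> tuple[FileHeader, Iterator[Section]]:
    """Parse the header eagerly and return a lazy section iterator.

    Sections are yielded in file order; variable state is applied internally
    so raw/minimizer sections parse with the values in force at their
    position in the file.
    """
    close = isinstance(source, (str, Path))
    raw = open(source, "rb") if close else source
    try:
        reader = _Reader(raw)
        header = read_header(reader)
    except Exception:
        if close:
            raw.close()
        raise

    def sections() -> Iterator[Section]:
        try:
            for _desc, section in _iter_sections(reader, header):
                yield section
        finally:
            if close:
                raw.close()

    return header, sections()


def scan_file(
    source: BinaryIO | str | Path,
) -> tuple[FileHeader, list[tuple[SectionDescriptor, Section]], bool]:
    """Eagerly parse a whole file, keeping byte offsets of every section.

    Returns ``(header, [(descriptor, section), ...], end_magic_seen)``.
    """
    close = isinstance(source, (str, Path))
    raw = open(source, "rb") if close else source
    try:
        reader = _Reader(raw)
        header = read_header(reader)
        pairs = list(_iter_sections(reader, header))
        return header, pairs, reader.end_magic_seen
    finally:
        if close:
            raw.close()


# ---------------------------------------------------------------------------
# index building and walking


def build_index(in_path: str | Path, out_path: str | Path) -> IndexSection:
    """Rewrite a file with a fresh terminal index section.

    Existing index sections are dropped; every other section is copied
    byte-for-byte, then indexed by one trailing ``i`` section whose offsets
    are relative to the byte just after it (hence negative).  The k-mer
    content of the file is untouched.
    """
    header, pairs, _magic = scan_file(in_path)
    kept = [d for d, s in pairs if d.section_type != "i"]
    hsize = header_size(header)
    with open(in_path, "rb") as src, open(out_path, "wb") as dst:
        dst.write(src.read(hsize))
        positions = []
        cursor = hsize
        for desc in kept:
            src.seek(desc.byte_start)
            dst.write(src.read(desc.byte_length))
            positions.append((desc.section_type, cursor))
            cursor += desc.byte_length
        index_length = 1 + 4 + 9 * len(kept) + 8
        after_index = cursor + index_length
        section = IndexSection(
            [IndexEntry(t, pos - after_index) for t, pos in positions], 0
        )
        write_index_section(section, dst)
        dst.write(MAGIC)
    return section


def read_index_at(path: str | Path, offset: int) -> tuple[IndexSection, int]:
    """Parse the index section starting at an absolute byte offset.

    Returns the section and its byte length.
    """
    with open(path, "rb") as fh:
        fh.seek(offset)
        reader = _Reader(fh)
        type_byte = reader.read_exact(1)
        if type_byte != b"i":
            raise UnknownSectionError(
                f"no index section at offset {offset} (found {type_byte!r})"
            )
        section = _read_index(reader)
        return section, reader.offset


def walk_index_chain(
    path: str | Path, first_offset: int
) -> list[tuple[int, IndexSection]]:
    """Follow the chain of index sections starting at ``first_offset``.

    Returns ``[(absolute_offset, section), ...]`` in chain order.
    """
    out = []
    offset = first_offset
    while True:
        section, length = read_index_at(path, offset)
        out.append((offset, section))
        if section.next_index_offset == 0:
            return out
        offset = offset + length + section.next_index_offset


# ---------------------------------------------------------------------------
# whole-file validation


def validate_file(path: str | Path) -> tuple[list[str], list[str]]:
    """Validate a file end to end; returns ``(violations, warnings)``.

    Parse failures become violations rather than exceptions so that callers
    can report them uniformly; a missing end magic is only a warning.  Index
    entries are resolved against the actual file bytes: each must land on a
    byte equal to its declared section-type character.
    """
    violations: list[str] = []
    warnings: list[str] = []
    try:
        header, pairs, end_magic = scan_file(path)
    except KffError as exc:
        return [f"parse error: {exc}"], []
    if not end_magic:
        warnings.append("file does not end with the KFF magic")
    state = VariableState()
    index_sections: list[tuple[SectionDescriptor, IndexSection]] = []
    for desc, section in pairs:
        for text in validate_section(section, state, header):
            violations.append(
                f"offset {desc.byte_start} ({desc.section_type} section): {text}"
            )
        if isinstance(section, ValuesSection):
            state.update(section.variables)
        elif isinstance(section, IndexSection):
            index_sections.append((desc, section))
    file_size = os.path.getsize(path)
    if index_sections:
        with open(path, "rb") as fh:
            for desc, section in index_sections:
                base = desc.byte_start + desc.byte_length
                targets = [(e.section_type, e.relative_offset) for e in section.entries]
                if section.next_index_offset != 0:
                    targets.append(("i", section.next_index_offset))
                for type_char, rel in targets:
                    absolute = base + rel
                    if not 0 <= absolute < file_size:
                        violations.append(
                            f"offset {desc.byte_start} (i section): entry resolves "
                            f"outside the file ({absolute})"
                        )
                        continue
                    fh.seek(absolute)
                    found = fh.read(1)
                    if found != type_char.encode("ascii"):
                        violations.append(
                            f"offset {desc.byte_start} (i section): entry for "
                            f"{type_char!r} at {absolute} lands on {found!r}"
                        )
    return violations, warnings
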