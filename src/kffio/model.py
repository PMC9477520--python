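"""In-memory model of every KFF construct.

A file is a :class:`FileHeader` followed by an ordered list of sections:

* :class:`ValuesSection` — (re)defines named unsigned integers (``k``,
  ``max``, ``data_size``, ``m``, ...) that govern subsequent sections;
* :class:`RawSection` — blocks of explicit overlapping sequences, each block
  carrying ``n`` k-mers as its length-k windows plus ``n`` fixed-width data
  payloads;
* :class:`MinimizerSection` — blocks that share one m-mer (the minimizer);
  each block stores only the *skeleton* (the sequence with the minimizer
  deleted) and the position at which to re-insert it;
* :class:`IndexSection` — byte offsets of other sections, for seeking.

Blocks hold decoded nucleotide strings; the 2-bit packing is purely a wire
concern handled in :mod:`kffio.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .encoding import DEFAULT_ENCODING, Encoding, canonical
from .errors import MalformedBlockError, MissingVariableError

U64_MAX = 2**64 - 1


@dataclass
class FileHeader:
    """File-level metadata written once at the start of a KFF file.

    ``unique_kmers`` asserts that no k-mer appears twice within any one
    section; ``canonical_kmers`` asserts that every stored k-mer equals its
    canonical form.  ``metadata`` is an opaque, possibly empty byte string
    for producers to use freely.
    """

    encoding: Encoding = DEFAULT_ENCODING
    unique_kmers: bool = False
    canonical_kmers: bool = False
    metadata: bytes = b""
    version: tuple[int, int] = (1, 0)


class VariableState:
    """The running name -> u64 map accumulated from values sections.

    Later definitions override earlier ones, so ``k`` may change mid-file.
    """

    REQUIRED_FOR_SEQUENCES = ("k", "max", "data_size")

    def __init__(self, variables: dict[str, int] | None = None) -> None:
        self.variables: dict[str, int] = dict(variables or {})

    def update(self, variables: dict[str, int]) -> None:
        self.variables.update(variables)

    def get(self, name: str) -> int:
        try:
            return self.variables[name]
        except KeyError:
            raise MissingVariableError(f"variable {name!r} is not defined") from None

    def require(self, *names: str, error: type = MissingVariableError) -> None:
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise error(f"variable(s) {', '.join(missing)} not defined yet")

    @property
    def k(self) -> int:
        return self.get("k")

    @property
    def max(self) -> int:
        return self.get("max")

    @property
    def data_size(self) -> int:
        return self.get("data_size")

    @property
    def m(self) -> int:
        return self.get("m")

    def copy(self) -> "VariableState":
        return VariableState(self.variables)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VariableState) and self.variables == other.variables

    def __repr__(self) -> str:
        return f"VariableState({self.variables!r})"


@dataclass
class ValuesSection:
    variables: dict[str, int]


@dataclass
class SequenceBlock:
    """One entry of a raw section: a sequence plus its per-k-mer payloads.

    The block's k-mers are the length-k windows of ``sequence``, so it holds
    ``n = len(sequence) - k + 1`` of them; ``data`` concatenates ``n``
    payloads of ``data_size`` bytes each, in window order.
    """

    sequence: str
    data: bytes = b""

    def n_kmers(self, k: int) -> int:
        return len(self.sequence) - k + 1


@dataclass
class RawSection:
    blocks: list[SequenceBlock] = field(default_factory=list)


@dataclass
class MinimizerBlock:
    """A skeleton plus the insertion point of the section's minimizer.

    ``minimizer_position`` is 0-based and indexes the *reconstructed*
    sequence — equivalently, it is the insertion offset into ``skeleton``.
    """

    skeleton: str
    minimizer_position: int
    data: bytes = b""

    def n_kmers(self, k: int, m: int) -> int:
        return len(self.skeleton) + m - k + 1


@dataclass
class MinimizerSection:
    minimizer: str
    blocks: list[MinimizerBlock] = field(default_factory=list)


@dataclass
class IndexEntry:
    """One index record: a section type and a signed byte offset.

    The offset is relative to the first byte *after* the index section that
    contains the entry, so entries pointing at earlier sections are negative.
    """

    section_type: str
    relative_offset: int


@dataclass
class IndexSection:
    entries: list[IndexEntry] = field(default_factory=list)
    next_index_offset: int = 0


Section = Union[ValuesSection, RawSection, MinimizerSection, IndexSection]


def section_type_char(section: Section) -> str:
    if isinstance(section, ValuesSection):
        return "v"
    if isinstance(section, RawSection):
        return "r"
    if isinstance(section, MinimizerSection):
        return "m"
    if isinstance(section, IndexSection):
        return "i"
    raise TypeError(f"not a KFF section: {section!r}")


def reconstruct_sequence(block: MinimizerBlock, minimizer: str) -> str:
    """Re-insert a section's minimizer into a block's skeleton.

    Returns ``skeleton[:pos] + minimizer + skeleton[pos:]``; the result has
    length ``len(skeleton) + len(minimizer)``.
    """
    pos = block.minimizer_position
    if not 0 <= pos <= len(block.skeleton):
        raise MalformedBlockError(
            f"minimizer position {pos} outside skeleton of "
            f"length {len(block.skeleton)}"
        )
    return block.skeleton[:pos] + minimizer + block.skeleton[pos:]


def _block_violations(
    label: str,
    sequence: str,
    data: bytes,
    state: VariableState,
    header: FileHeader,
    seen: set[str],
) -> list[str]:
    """Shared checks for raw and (reconstructed) minimizer blocks."""
    k, max_, data_size = state.k, state.max, state.data_size
    out: list[str] = []
    n = len(sequence) - k + 1
    if n < 1:
        out.append(f"{label}: sequence of {len(sequence)} nt holds no {k}-mer")
        return out
    if n > max_:
        out.append(f"{label}: {n} k-mers exceed max={max_}")
    if len(data) != n * data_size:
        out.append(
            f"{label}: {len(data)} data bytes, expected {n}x{data_size}"
        )
    for i in range(n):
        kmer = sequence[i : i + k]
        if header.unique_kmers:
            if kmer in seen:
                out.append(f"{label}: duplicate k-mer {kmer}")
            seen.add(kmer)
        if header.canonical_kmers and canonical(kmer) != kmer:
            out.append(f"{label}: k-mer {kmer} is not canonical")
    return out


def validate_section(
    section: Section, state: VariableState, header: FileHeader
) -> list[str]:
    """Check one section against the type invariants and header flags.

    Returns a list of human-readable violations (empty when the section is
    well formed); violations are data, not exceptions.  Index offsets need
    the surrounding file to resolve and are checked in
    :func:`kffio.io.validate_file` instead.
    """
    out: list[str] = []
    if isinstance(section, ValuesSection):
        for name, value in section.variables.items():
            if not name or not name.isascii():
                out.append(f"variable name {name!r} is not non-empty ASCII")
            if not 0 <= value <= U64_MAX:
                out.append(f"variable {name}={value} outside u64 range")
        return out

    if isinstance(section, IndexSection):
        for entry in section.entries:
            if entry.section_type not in "vrmi":
                out.append(f"index entry with unknown type {entry.section_type!r}")
        return out

    try:
        state.require(*VariableState.REQUIRED_FOR_SEQUENCES)
        if isinstance(section, MinimizerSection):
            state.require("m")
    except MissingVariableError as exc:
        return [str(exc)]

    seen: set[str] = set()
    if isinstance(section, RawSection):
        if not section.blocks:
            out.append("raw section with zero blocks")
        for i, block in enumerate(section.blocks):
            out.extend(
                _block_violations(
                    f"block {i}", block.sequence, block.data, state, header, seen
                )
            )
        return out

    if isinstance(section, MinimizerSection):
        m = state.m
        if not 1 <= m <= state.k:
            out.append(f"m={m} outside 1..k={state.k}")
            return out
        if len(section.minimizer) != m:
            out.append(
                f"minimizer {section.minimizer} has length "
                f"{len(section.minimizer)}, expected m={m}"
            )
            return out
        if not section.blocks:
            out.append("minimizer section with zero blocks")
        for i, block in enumerate(section.blocks):
            try:
                sequence = reconstruct_sequence(block, section.minimizer)
            except MalformedBlockError as exc:
                out.append(f"block {i}: {exc}")
                continue
            out.extend(
                _block_violations(
                    f"block {i}", sequence, block.data, state, header, seen
                )
            )
        return out

    raise TypeError(f"not a KFF section: {section!r}")
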