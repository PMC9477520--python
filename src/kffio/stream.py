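"""Consumer-facing k-mer iteration.

KFF is a sequential format — there is no random access by k-mer — so the one
thing every consumer does is stream ``(k-mer, data)`` records out of a file
in file order.  :func:`iterate_kmers` does that for any mix of raw and
minimizer sections, applying variable redefinitions as they pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterator

from .errors import IncompatibilityError, TooShortError
from .io import read_file
from .model import (
    FileHeader,
    IndexSection,
    MinimizerSection,
    RawSection,
    ValuesSection,
    VariableState,
    reconstruct_sequence,
)


@dataclass(frozen=True)
class KmerRecord:
    """One k-mer and its fixed-width data payload (empty when data_size=0)."""

    kmer: str
    data: bytes = b""


def kmers_of_sequence(sequence: str, k: int) -> list[str]:
    """The ``len(sequence) - k + 1`` length-k windows, left to right."""
    if len(sequence) < k:
        raise TooShortError(
            f"sequence of {len(sequence)} nt holds no {k}-mer"
        )
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def _block_records(sequence: str, data: bytes, k: int, data_size: int):
    n = len(sequence) - k + 1
    for i in range(n):
        yield KmerRecord(
            sequence[i : i + k], data[i * data_size : (i + 1) * data_size]
        )


def iterate_kmers(source: BinaryIO | str | Path) -> Iterator[KmerRecord]:
    """Stream every (k-mer, data) record of a KFF file in file order.

    Raw blocks yield their windows directly; minimizer blocks are first
    reconstructed by re-inserting the section minimizer.  Values sections
    update k/max/data_size/m mid-stream; index sections are skipped.
    """
    header, sections = read_file(source)
    state = VariableState()
    for section in sections:
        if isinstance(section, ValuesSection):
            state.update(section.variables)
        elif isinstance(section, RawSection):
            k, data_size = state.k, state.data_size
            for block in section.blocks:
                yield from _block_records(block.sequence, block.data, k, data_size)
        elif isinstance(section, MinimizerSection):
            k, data_size = state.k, state.data_size
            for block in section.blocks:
                sequence = reconstruct_sequence(block, section.minimizer)
                yield from _block_records(sequence, block.data, k, data_size)
        elif isinstance(section, IndexSection):
            continue


def collect_records(
    source: BinaryIO | str | Path,
) -> tuple[FileHeader, int | None, int, list[KmerRecord]]:
    """Materialize a file as ``(header, k, data_size, records)``.

    Convenience for rewriting tools that need the whole content plus the
    governing parameters.  ``k`` is ``None`` for a file with no k-mers.
    Raises :class:`IncompatibilityError` if k or data_size changes between
    sections that actually contain k-mers — rewriters assume one geometry.
    """
    header, sections = read_file(source)
    state = VariableState()
    k: int | None = None
    data_size = 0
    records: list[KmerRecord] = []
    for section in sections:
        if isinstance(section, ValuesSection):
            state.update(section.variables)
            continue
        if isinstance(section, (RawSection, MinimizerSection)):
            if k is None:
                k, data_size = state.k, state.data_size
            elif (state.k, state.data_size) != (k, data_size):
                raise IncompatibilityError(
                    f"mixed geometries in one file: ({k}, {data_size}) then "
                    f"({state.k}, {state.data_size})"
                )
            if isinstance(section, RawSection):
                for block in section.blocks:
                    records.extend(
                        _block_records(block.sequence, block.data, k, data_size)
                    )
            else:
                for block in section.blocks:
                    sequence = reconstruct_sequence(block, section.minimizer)
                    records.extend(
                        _block_records(sequence, block.data, k, data_size)
                    )
    return header, k, data_size, records
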