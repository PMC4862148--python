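"""Streaming, pairing-safe FASTQ input/output.

Reads are paired positionally, the way Illumina lane output is organised:
record i of the forward files corresponds to record i of the reverse files,
with multiple files per side concatenated in the order given (merging runs
or lanes during processing).  Identifiers are checked loosely — equal after
stripping a /1, /2 or comment suffix — and a mismatch raises a warning, not
an error.  Gzip compression is auto-detected on input by magic bytes and
chosen on output by a ``.gz`` suffix.  Qualities are Phred+33.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .trimmer import ReadPair, ReadRecord, pair_id

__all__ = [
    "PairedReadStream",
    "open_paired_reader",
    "write_pairs",
    "PairingError",
    "FastqFormatError",
]

_GZIP_MAGIC = b"\x1f\x8b"


class FastqFormatError(ValueError):
    """A FASTQ record violates the 4-line Phred+33 format."""


class PairingError(ValueError):
    """Forward and reverse streams hold unequal numbers of records."""


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_records(paths: Sequence[str | Path]) -> Iterator[tuple[Path, int, ReadRecord]]:
    """Yield (file, record-index-within-side, record) across files in order."""
    index = 0
    for raw_path in paths:
        path = Path(raw_path)
        with _open_text(path) as handle:
            records = FastqGeneralIterator(handle)
            while True:
                try:
                    title, seq, qual = next(records)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise FastqFormatError(
                        f"{path}, record {index + 1} (approx. line {index * 4 + 1}): {exc}"
                    ) from exc
                if len(seq) != len(qual):
                    raise FastqFormatError(
                        f"{path}, record {index + 1}: sequence and quality "
                        f"lengths differ ({len(seq)} vs {len(qual)})"
                    )
                encoded = qual.encode("ascii", errors="replace")
                if encoded and (min(encoded) < 33 or max(encoded) > 126):
                    raise FastqFormatError(
                        f"{path}, record {index + 1}: quality characters outside "
                        "the Phred+33 range [0, 93]"
                    )
                try:
                    record = ReadRecord(title, seq, qual)
                except ValueError as exc:
                    raise FastqFormatError(f"{path}, record {index + 1}: {exc}") from exc
                yield path, index, record
                index += 1


@dataclass
class PairedReadStream:
    """Iterable over synchronized ReadPair objects from two file lists."""

    fwd_paths: tuple[Path, ...]
    rev_paths: tuple[Path, ...]
    _warned_id_mismatch: bool = False

    def __iter__(self) -> Iterator[ReadPair]:
        fwd_iter = _iter_records(self.fwd_paths)
        rev_iter = _iter_records(self.rev_paths)
        for fwd_item, rev_item in zip_longest(fwd_iter, rev_iter):
            if fwd_item is None or rev_item is None:
                side, path, index = (
                    ("reverse",) + rev_item[:2] if fwd_item is None
                    else ("forward",) + fwd_item[:2]
                )
                raise PairingError(
                    f"unpaired record on the {side} side: {path}, record {index + 1} "
                    "has no mate (forward and reverse inputs hold unequal record counts)"
                )
            _, _, fwd = fwd_item
            _, _, rev = rev_item
            if not self._warned_id_mismatch and pair_id(fwd.id) != pair_id(rev.id):
                warnings.warn(
                    f"read id mismatch between mates: {fwd.id!r} vs {rev.id!r} "
                    "(pairing is positional; further mismatches not reported)",
                    stacklevel=2,
                )
                self._warned_id_mismatch = True
            yield ReadPair(fwd, rev)


def open_paired_reader(
    fwd_paths: Sequence[str | Path], rev_paths: Sequence[str | Path]
) -> PairedReadStream:
    """Open paired FASTQ inputs, concatenating multiple files per side."""
    fwd_paths = tuple(Path(p) for p in fwd_paths)
    rev_paths = tuple(Path(p) for p in rev_paths)
    if len(fwd_paths) != len(rev_paths):
        raise PairingError(
            f"{len(fwd_paths)} forward files vs {len(rev_paths)} reverse files"
        )
    if not fwd_paths:
        raise ValueError("at least one file per side is required")
    for path in (*fwd_paths, *rev_paths):
        if not path.exists():
            raise FileNotFoundError(path)
    return PairedReadStream(fwd_paths, rev_paths)


def open_writer(path: str | Path) -> IO[str]:
    """Text FASTQ writer; gzip-compressed when the suffix is ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def format_record(record: ReadRecord) -> str:
    return f"@{record.id}\n{record.bases}\n+\n{record.quals}\n"


def write_pairs(
    pairs: Iterable[ReadPair], out_fwd: str | Path, out_rev: str | Path
) -> int:
    """Write pairs as 4-line Phred+33 FASTQ; returns the pair count written.

    Both outputs always receive the same number of records in the same
    order.  Empty reads are a contract violation (length filtering happens
    upstream) and raise.
    """
    count = 0
    with open_writer(out_fwd) as fh_fwd, open_writer(out_rev) as fh_rev:
        for pair in pairs:
            if len(pair.fwd) == 0 or len(pair.rev) == 0:
                raise ValueError(
                    f"refusing to write empty read for pair {pair.fwd.id!r}"
                )
            fh_fwd.write(format_record(pair.fwd))
            fh_rev.write(format_record(pair.rev))
            count += 1
    return count
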