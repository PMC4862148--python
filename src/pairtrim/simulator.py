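"""Paired-end read simulator with read-through adapter contamination.

Emulates an Illumina paired-end library: fragment (insert) lengths are
drawn from a normal distribution, rounded to integers and redrawn until
positive (a discrete truncated normal); each fragment is sequenced from
both ends, and whenever the insert is shorter than the read length the read
runs through into the adapter — the contamination the trimmer must remove.
Bases past the end of the adapter are filled with random sequence (the
instrument keeps producing signal there).  Substitution errors are applied
uniformly per base; indel errors are not modelled, matching the
substitution-dominated error profile of Illumina instruments.

Every simulated pair is accompanied by a ground-truth record giving the
true insert length, hence the exact number of bases a perfect trimmer
keeps: ``min(read_length, insert_length)`` per mate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .match_model import reverse_complement
from .trimmer import AdapterPair, ReadPair, ReadRecord
from . import fastq_io

__all__ = [
    "DEFAULT_FWD_ADAPTER",
    "DEFAULT_REV_ADAPTER",
    "default_adapters",
    "SimConfig",
    "TruthRecord",
    "draw_insert_length",
    "draw_insert_lengths",
    "make_fragment",
    "synthesize_pair",
    "generate_pairs",
    "simulate",
    "read_truth",
    "write_truth",
]

# Illumina TruSeq read-through adapter starts (forward / reverse direction).
DEFAULT_FWD_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_REV_ADAPTER = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def default_adapters() -> AdapterPair:
    return AdapterPair(DEFAULT_FWD_ADAPTER, DEFAULT_REV_ADAPTER)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    The defaults describe a library of 100 bp reads with insert lengths
    from Normal(100, 50) truncated at 1 — a library in which about half of
    all pairs read through into the adapter.
    """

    n_pairs: int = 1000
    read_length: int = 100
    insert_mean: float = 100.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    adapters: AdapterPair = field(default_factory=default_adapters)
    fragment_source: str = "random"
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.base_quality <= 93:
            raise ValueError("base_quality must be in [0, 93]")


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """Ground truth for one simulated pair."""

    pair_id: str
    insert_length: int
    expected_kept_fwd: int
    expected_kept_rev: int

    def __post_init__(self) -> None:
        if self.insert_length < 1:
            raise ValueError("insert_length must be >= 1")


def draw_insert_length(config: SimConfig, rng: np.random.Generator) -> int:
    """One insert length: round(Normal(mean, sd)), redrawn until >= 1."""
    if config.insert_sd == 0:
        length = round(config.insert_mean)
        if length < 1:
            raise ValueError("degenerate insert distribution entirely below 1")
        return length
    while True:
        length = round(rng.normal(config.insert_mean, config.insert_sd))
        if length >= 1:
            return length


def draw_insert_lengths(
    config: SimConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Vectorized truncated draws; same distribution as draw_insert_length."""
    if config.insert_sd == 0:
        return np.full(size, draw_insert_length(config, rng), dtype=np.int64)
    out = np.rint(rng.normal(config.insert_mean, config.insert_sd, size)).astype(np.int64)
    bad = out < 1
    while bad.any():
        out[bad] = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, int(bad.sum()))
        ).astype(np.int64)
        bad = out < 1
    return out


def _random_bases(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _load_reference(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


_REFERENCE_CACHE: dict[str, list[tuple[str, str]]] = {}


def make_fragment(length: int, config: SimConfig, rng: np.random.Generator) -> str:
    """A fragment of the given length from the configured source.

    Random mode draws i.i.d. uniform bases.  Reference mode picks a FASTA
    record uniformly, then a window uniformly within it and a strand
    uniformly; windows containing N are rejected and redrawn.
    """
    if length < 1:
        raise ValueError("fragment length must be >= 1")
    if config.fragment_source == "random":
        return _random_bases(length, rng)
    key = str(config.fragment_source)
    if key not in _REFERENCE_CACHE:
        _REFERENCE_CACHE[key] = _load_reference(key)
    records = _REFERENCE_CACHE[key]
    name, seq = records[rng.integers(0, len(records))]
    if len(seq) < length:
        raise ValueError(
            f"reference record {name!r} ({len(seq)} bp) is shorter than the "
            f"requested fragment length {length}"
        )
    for _ in range(1000):
        start = int(rng.integers(0, len(seq) - length + 1))
        window = seq[start : start + length]
        if "N" not in window:
            break
    else:
        raise ValueError(f"could not draw an N-free window from record {name!r}")
    if rng.integers(0, 2) == 1:
        window = reverse_complement(window)
    return window


def _apply_errors(bases: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return bases
    codes = _CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)].copy()
    mask = rng.random(len(codes)) < error_rate
    n_err = int(mask.sum())
    if n_err:
        # substitute with one of the three other bases, uniformly
        codes[mask] = (codes[mask] + rng.integers(1, 4, n_err)) % 4
    return _BASES[codes].tobytes().decode("ascii")


def synthesize_pair(
    fragment: str,
    config: SimConfig,
    rng: np.random.Generator,
    pair_id: str = "sim",
) -> tuple[ReadPair, TruthRecord]:
    """Sequence one fragment from both ends.

    Forward read: fragment, then forward adapter, then random fill, cut to
    the read length.  Reverse read: reverse-complemented fragment, then
    reverse adapter, then random fill.  Substitution errors are applied to
    each read independently; qualities are constant.
    """
    if len(fragment) < 1:
        raise ValueError("fragment must be non-empty")
    rl = config.read_length
    qual = chr(33 + config.base_quality) * rl

    def build(template: str, adapter: str) -> str:
        read = (template + adapter)[:rl]
        if len(read) < rl:
            read += _random_bases(rl - len(read), rng)
        return _apply_errors(read, config.error_rate, rng)

    fwd_bases = build(fragment, config.adapters.fwd_adapter)
    rev_bases = build(reverse_complement(fragment), config.adapters.rev_adapter)
    pair = ReadPair(
        ReadRecord(f"{pair_id}/1", fwd_bases, qual),
        ReadRecord(f"{pair_id}/2", rev_bases, qual),
    )
    kept = min(rl, len(fragment))
    truth = TruthRecord(pair_id, len(fragment), kept, kept)
    return pair, truth


def generate_pairs(config: SimConfig) -> Iterator[tuple[ReadPair, TruthRecord]]:
    """Deterministic stream of simulated pairs with ground truth."""
    rng = np.random.default_rng(config.seed)
    width = max(6, len(str(config.n_pairs)))
    for i in range(config.n_pairs):
        length = draw_insert_length(config, rng)
        fragment = make_fragment(length, config, rng)
        yield synthesize_pair(fragment, config, rng, pair_id=f"sim:{i:0{width}d}")


TRUTH_COLUMNS = ("pair_id", "insert_length", "expected_kept_fwd", "expected_kept_rev")


def write_truth(records: Iterable[TruthRecord], path: str | Path) -> int:
    count = 0
    with open(path, "wt", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for rec in records:
            writer.writerow(
                (rec.pair_id, rec.insert_length, rec.expected_kept_fwd, rec.expected_kept_rev)
            )
            count += 1
    return count


def read_truth(path: str | Path) -> Iterator[TruthRecord]:
    with open(path, "rt", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"{path}: not a truth table (header {header!r})")
        for row in reader:
            yield TruthRecord(row[0], int(row[1]), int(row[2]), int(row[3]))


def simulate(
    config: SimConfig,
    out_fwd: str | Path,
    out_rev: str | Path,
    truth_path: str | Path,
) -> int:
    """Write paired FASTQ plus the truth TSV; returns the pair count.

    Byte-identical outputs for identical configs (including the seed).
    """
    with open(truth_path, "wt", newline="") as truth_fh:
        writer = csv.writer(truth_fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)

        def pairs_writing_truth() -> Iterator[ReadPair]:
            for pair, truth in generate_pairs(config):
                writer.writerow(
                    (
                        truth.pair_id,
                        truth.insert_length,
                        truth.expected_kept_fwd,
                        truth.expected_kept_rev,
                    )
                )
                yield pair

        return fastq_io.write_pairs(pairs_writing_truth(), out_fwd, out_rev)
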