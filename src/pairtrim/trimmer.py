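"""Paired-end adapter trimming engine.

Adapter contamination in paired-end data arises from library fragments
shorter than the read length: the sequencer reads through the insert into
the adapter, symmetrically in both mates.  The engine removes it with two
complementary detectors:

* **insert match** — scan every possible insert length L and test whether
  the forward read and the reverse-complemented reverse read agree
  significantly over the insert positions both mates cover.  The best
  (lowest-P) significant candidate is accepted only if the bases flanking
  the putative insert also look like the known adapter in at least one
  mate, which suppresses false offsets inside simple repeats.
* **adapter match** — fallback when no insert match is found: locate the
  adapter sequence itself in each mate; a hit in one mate trims both at the
  same offset, because read-through is always symmetrical.

Afterwards optional 3' quality trimming, no-call-run trimming and a minimum
length filter are applied.  Trimming only ever shortens reads from the 3'
end: every output read is a prefix of its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .match_model import (
    MatchModel,
    count_matches,
    non_random_match_probability,
    reverse_complement,
)

__all__ = [
    "ReadRecord",
    "ReadPair",
    "AdapterPair",
    "TrimParams",
    "TrimResult",
    "InsertMatch",
    "AdapterMatch",
    "find_insert_match",
    "adapter_flank_confirmed",
    "find_adapter_match",
    "trim_pair",
    "quality_trim",
    "ncut_trim",
    "pair_id",
]

_ALLOWED_BASES = frozenset("ACGTNacgtn")

# Base encodings for the vectorized offset scans.  The two sides of every
# comparison use disjoint codes for N and for padding, so an N (or a pad
# position outside the overlap) can never count as a match.
_FWD_CODE = np.full(256, 250, dtype=np.uint8)
_REV_CODE = np.full(256, 251, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    for _c in (_b, _b.lower()):
        _FWD_CODE[ord(_c)] = _i + 1
        _REV_CODE[ord(_c)] = _i + 1
_FWD_CODE[ord("N")] = _FWD_CODE[ord("n")] = 5
_REV_CODE[ord("N")] = _REV_CODE[ord("n")] = 6
_PAD = 252  # matches nothing on either side

# Flanks shorter than this are confirmed only by an exact match; no binomial
# or fraction test is meaningful on one or two bases.
FLANK_MIN_FRACTION_LENGTH = 3


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One FASTQ read: identifier, bases, and Phred+33-encoded qualities."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality characters"
            )
        if not _ALLOWED_BASES.issuperset(self.bases):
            bad = sorted(set(self.bases) - _ALLOWED_BASES)
            raise ValueError(f"read {self.id!r}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.bases)

    def phred_scores(self) -> np.ndarray:
        """Per-base Phred scores as integers."""
        return np.frombuffer(self.quals.encode("ascii"), dtype=np.uint8) - 33

    def prefix(self, n: int) -> "ReadRecord":
        """The first ``n`` bases (3' truncation)."""
        if n >= len(self.bases):
            return self
        return ReadRecord(self.id, self.bases[:n], self.quals[:n])


def pair_id(read_id: str) -> str:
    """Fragment identifier: read id without a /1, /2 or comment suffix."""
    head = read_id.split(None, 1)[0] if read_id else read_id
    if head.endswith(("/1", "/2")):
        head = head[:-2]
    return head


@dataclass(frozen=True, slots=True)
class ReadPair:
    """Synchronized forward/reverse mates of one fragment."""

    fwd: ReadRecord
    rev: ReadRecord

    def ids_consistent(self) -> bool:
        return pair_id(self.fwd.id) == pair_id(self.rev.id)


@dataclass(frozen=True, slots=True)
class AdapterPair:
    """Adapter appended after the insert in each read direction."""

    fwd_adapter: str
    rev_adapter: str

    def __post_init__(self) -> None:
        for name, seq in (("fwd_adapter", self.fwd_adapter),
                          ("rev_adapter", self.rev_adapter)):
            if not seq:
                raise ValueError(f"{name} must be non-empty")
            if not _ALLOWED_BASES.issuperset(seq):
                raise ValueError(f"{name}: invalid bases in {seq!r}")


@dataclass(frozen=True, slots=True)
class TrimParams:
    """Post-adapter trimming parameters.

    qcut: Phred cutoff for 3' quality trimming (0 disables).
    ncut: minimum length of an N run that triggers truncation (0 disables).
    min_len: pairs with either mate shorter than this are discarded.
    """

    qcut: int = 0
    ncut: int = 7
    min_len: int = 15

    def __post_init__(self) -> None:
        if self.qcut < 0 or self.ncut < 0:
            raise ValueError("qcut and ncut must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True, slots=True)
class InsertMatch:
    insert_length: int
    probability: float


@dataclass(frozen=True, slots=True)
class AdapterMatch:
    offset: int
    probability: float


TrimPath = Literal["insert_match", "adapter_match", "untrimmed", "discarded"]


@dataclass(frozen=True, slots=True)
class TrimResult:
    """Outcome for one pair: which detector fired and what was removed."""

    path: TrimPath
    insert_length: Optional[int] = None
    probability: Optional[float] = None
    removed_fwd: int = 0
    removed_rev: int = 0


def _overlap_scan(fwd_bases: str, rev_bases: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match counts for every candidate insert length.

    Returns (L, n, k) arrays over all L in [0, m1 + m2 - 1], where n is the
    overlap length (may be 0) and k the number of agreeing bases between the
    forward read and the reverse-complemented reverse read over the insert
    positions both reads cover.
    """
    m1, m2 = len(fwd_bases), len(rev_bases)
    f = _encode(fwd_bases, _FWD_CODE)
    r = _encode(reverse_complement(rev_bases), _REV_CODE)
    ext = np.full(m1 - 1 + m2 + m1, _PAD, dtype=np.uint8)
    ext[m1 - 1 : m1 - 1 + m2] = r
    # row s aligns r shifted so that fwd position i faces r[i - (L - m2)],
    # with L = m1 + m2 - 1 - s
    windows = sliding_window_view(ext, m1)[: m1 + m2]
    k = (windows == f).sum(axis=1)
    L = m1 + m2 - 1 - np.arange(m1 + m2)
    n = np.minimum(m1, L) - np.maximum(0, L - m2)
    return L, np.maximum(n, 0), k


def adapter_flank_confirmed(
    pair: ReadPair, L: int, adapters: AdapterPair, model: MatchModel
) -> bool:
    """Does the sequence beyond the putative insert look like the adapter?

    Confirmation is required in only one of the two mates.  Flanks of at
    least FLANK_MIN_FRACTION_LENGTH bases confirm when the fraction of
    matching bases reaches the model's minimum match fraction; shorter
    flanks must match the adapter start exactly.  When L reaches beyond both
    reads there is nothing to confirm and the check passes.
    """
    if L < 0:
        raise ValueError("insert length must be >= 0")
    flank_fwd = pair.fwd.bases[L:]
    flank_rev = pair.rev.bases[L:]
    if not flank_fwd and not flank_rev:
        return True
    for flank, adapter in (
        (flank_fwd, adapters.fwd_adapter),
        (flank_rev, adapters.rev_adapter),
    ):
        f = min(len(flank), len(adapter))
        if f == 0:
            continue
        matches = count_matches(flank[:f], adapter[:f], f)
        if f >= FLANK_MIN_FRACTION_LENGTH:
            if matches / f >= model.min_match_fraction:
                return True
        elif matches == f:
            return True
    return False


def find_insert_match(
    pair: ReadPair, adapters: AdapterPair, model: MatchModel
) -> Optional[InsertMatch]:
    """Best significant, adapter-confirmed overlap between the two mates.

    Candidates are ordered by tail probability P (ties prefer the larger
    insert length, i.e. trimming less); the first candidate whose flank is
    confirmed wins.  An insert length of 0 (adapter dimer) has no overlap to
    test, so it is accepted purely on flank confirmation, with P reported as
    1.0, and only when no overlapping candidate qualifies.
    """
    m1, m2 = len(pair.fwd), len(pair.rev)
    if m1 == 0 or m2 == 0:
        return None
    if min(m1, m2) > model.max_length:
        raise ValueError(
            f"reads of length {min(m1, m2)} exceed model capacity {model.max_length}"
        )
    L_all, n_all, k_all = _overlap_scan(pair.fwd.bases, pair.rev.bases)
    valid = n_all >= 1
    significant = np.zeros_like(valid)
    significant[valid] = k_all[valid] >= model.min_significant_matches(n_all[valid])
    if significant.any():
        idx = np.nonzero(significant)[0]
        ranked = sorted(
            (
                non_random_match_probability(int(k_all[i]), int(n_all[i]), model),
                -int(L_all[i]),
                int(L_all[i]),
            )
            for i in idx
        )
        for prob, _neg_L, L in ranked:
            if adapter_flank_confirmed(pair, L, adapters, model):
                return InsertMatch(insert_length=L, probability=prob)
    # adapter dimer: zero-length insert, detectable only through its flanks
    if adapter_flank_confirmed(pair, 0, adapters, model):
        return InsertMatch(insert_length=0, probability=1.0)
    return None


def find_adapter_match(
    read: ReadRecord, adapter: str, model: MatchModel
) -> Optional[AdapterMatch]:
    """Lowest-P significant occurrence of the adapter start within a read.

    Every offset is tested against the adapter prefix that fits in the
    remaining read; ties on P prefer the smallest offset (trimming more —
    in the 3' tail, adapter sequence dominates).
    """
    rlen, alen = len(read), len(adapter)
    if rlen == 0:
        return None
    rc = _encode(read.bases, _FWD_CODE)
    ac = _encode(adapter, _REV_CODE)
    ext = np.full(rlen + alen, _PAD, dtype=np.uint8)
    ext[:rlen] = rc
    windows = sliding_window_view(ext, alen)[:rlen]
    k = (windows == ac).sum(axis=1)
    w = np.minimum(alen, rlen - np.arange(rlen))
    significant = k >= model.min_significant_matches(w)
    if not significant.any():
        return None
    best: Optional[tuple[float, int]] = None
    for o in np.nonzero(significant)[0]:
        prob = non_random_match_probability(int(k[o]), int(w[o]), model)
        if best is None or (prob, int(o)) < best:
            best = (prob, int(o))
    return AdapterMatch(offset=best[1], probability=best[0])


def quality_trim(read: ReadRecord, qcut: int) -> ReadRecord:
    """Remove the 3' run of bases with quality below ``qcut``.

    Scanning from the 3' end, bases are dropped while their quality is below
    the cutoff; the scan stops at the first base meeting it, so low-quality
    bases in the interior survive.
    """
    if qcut <= 0:
        return read
    quals = read.quals
    i = len(quals)
    floor = qcut + 33
    while i > 0 and ord(quals[i - 1]) < floor:
        i -= 1
    return read.prefix(i)


def ncut_trim(read: ReadRecord, ncut: int) -> ReadRecord:
    """Truncate at the first run of at least ``ncut`` consecutive no-calls."""
    if ncut <= 0:
        return read
    pos = read.bases.upper().find("N" * ncut)
    if pos < 0:
        return read
    return read.prefix(pos)


def trim_pair(
    pair: ReadPair,
    adapters: AdapterPair,
    model: MatchModel,
    params: TrimParams,
) -> tuple[Optional[ReadPair], TrimResult]:
    """Full per-pair pipeline.

    Insert match first; adapter match as fallback (a hit in either mate
    trims both at the same offset — the lower-P hit wins if both fire);
    then quality and no-call trimming; finally the pair is discarded
    whole if either mate falls below ``params.min_len``.  The returned
    removed counts refer to adapter trimming only.
    """
    m1, m2 = len(pair.fwd), len(pair.rev)
    fwd, rev = pair.fwd, pair.rev
    path: TrimPath = "untrimmed"
    insert_length: Optional[int] = None
    probability: Optional[float] = None

    insert = find_insert_match(pair, adapters, model)
    if insert is not None:
        L = insert.insert_length
        fwd = fwd.prefix(min(m1, L))
        rev = rev.prefix(min(m2, L))
        path = "insert_match"
        insert_length = L
        probability = insert.probability
    else:
        hit_f = find_adapter_match(pair.fwd, adapters.fwd_adapter, model)
        hit_r = find_adapter_match(pair.rev, adapters.rev_adapter, model)
        hit = None
        if hit_f is not None and (
            hit_r is None or hit_f.probability <= hit_r.probability
        ):
            hit = hit_f
        elif hit_r is not None:
            hit = hit_r
        if hit is not None:
            # read-through is symmetrical: one mate's hit trims both
            fwd = fwd.prefix(min(m1, hit.offset))
            rev = rev.prefix(min(m2, hit.offset))
            path = "adapter_match"
            probability = hit.probability

    removed_fwd = m1 - len(fwd)
    removed_rev = m2 - len(rev)

    if params.qcut > 0:
        fwd = quality_trim(fwd, params.qcut)
        rev = quality_trim(rev, params.qcut)
    if params.ncut > 0:
        fwd = ncut_trim(fwd, params.ncut)
        rev = ncut_trim(rev, params.ncut)

    if len(fwd) < params.min_len or len(rev) < params.min_len:
        # discard verdict: pair-level, conveyed by the None pair; the path
        # keeps the detector that fired, "discarded" marks drops where none did
        result = TrimResult(
            path="discarded" if path == "untrimmed" else path,
            insert_length=insert_length,
            probability=probability,
            removed_fwd=removed_fwd,
            removed_rev=removed_rev,
        )
        return None, result

    result = TrimResult(
        path=path,
        insert_length=insert_length,
        probability=probability,
        removed_fwd=removed_fwd,
        removed_rev=removed_rev,
    )
    return ReadPair(fwd, rev), result
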