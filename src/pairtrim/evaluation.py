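"""Truth-based trimming metrics and basic read QC.

For simulated data the correct trim point of every read is known, so
trimming accuracy reduces to exact bookkeeping per read:

* ``overtrimmed`` bases — insert bases erroneously removed (kept length
  below the expected kept length); a specificity loss.
* ``undertrimmed`` bases — adapter bases erroneously kept; a sensitivity
  loss.
* remaining **adapter 20-mers** — occurrences of the first 20 adapter
  bases in the output; a crude sensitivity check on real or simulated data
  (after perfect trimming none should remain).

Discarded pairs are tallied separately and contribute to neither base
count, keeping read filtering distinct from base-level accuracy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Optional

from .simulator import TruthRecord
from .trimmer import AdapterPair, ReadPair, ReadRecord, pair_id

__all__ = [
    "TrimStats",
    "count_adapter_kmers",
    "truth_trim_accounting",
    "basic_qc",
    "evaluate_trimming",
]

ADAPTER_KMER_LENGTH = 20


@dataclass(frozen=True, slots=True)
class TrimStats:
    """Aggregate trimming metrics for one run."""

    pairs_in: int
    pairs_out: int
    pairs_discarded: int
    bases_out: int
    overtrimmed_bases: int
    undertrimmed_bases: int
    adapter_kmers_remaining: int
    reads_overtrimmed: int
    max_overtrim_per_read: int
    bases_in: Optional[int] = None  # unknown when only trimmed output + truth exist

    def __post_init__(self) -> None:
        if self.pairs_out + self.pairs_discarded != self.pairs_in:
            raise ValueError("pairs_out + pairs_discarded must equal pairs_in")
        counts = (
            self.pairs_in, self.pairs_out, self.pairs_discarded, self.bases_out,
            self.overtrimmed_bases, self.undertrimmed_bases,
            self.adapter_kmers_remaining, self.reads_overtrimmed,
            self.max_overtrim_per_read,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.bases_in is not None and self.bases_out > self.bases_in:
            raise ValueError("bases_out must not exceed bases_in")

    def to_dict(self) -> dict:
        return asdict(self)


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    pos = haystack.find(needle)
    while pos >= 0:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def count_adapter_kmers(
    pairs: Iterable[ReadPair], adapters: AdapterPair, k: int = ADAPTER_KMER_LENGTH
) -> int:
    """Occurrences of each adapter's first ``k`` bases in the matching mate.

    Exact, case-insensitive substring matching; overlapping occurrences all
    count.  Forward reads are searched for the forward adapter k-mer,
    reverse reads for the reverse one.
    """
    if len(adapters.fwd_adapter) < k or len(adapters.rev_adapter) < k:
        raise ValueError(f"both adapters must be at least {k} bases long")
    kmer_fwd = adapters.fwd_adapter[:k].upper()
    kmer_rev = adapters.rev_adapter[:k].upper()
    total = 0
    for pair in pairs:
        total += _count_overlapping(pair.fwd.bases.upper(), kmer_fwd)
        total += _count_overlapping(pair.rev.bases.upper(), kmer_rev)
    return total


def truth_trim_accounting(
    kept_lengths: Mapping[str, Optional[tuple[int, int]]],
    truth: Iterable[TruthRecord],
) -> tuple[int, int, int, int]:
    """Compare surviving read lengths against ground truth.

    ``kept_lengths`` maps pair id to (kept_fwd, kept_rev), or to ``None``
    for a discarded pair.  Returns (overtrimmed_bases, undertrimmed_bases,
    reads_overtrimmed, max_overtrim_per_read); discarded pairs contribute to
    none of them.  Every read's deviation decomposes exactly into one of the
    two base counts: max(0, expected - kept) is overtrim, max(0, kept -
    expected) is undertrim.
    """
    truth_by_id = {rec.pair_id: rec for rec in truth}
    overtrimmed = 0
    undertrimmed = 0
    reads_overtrimmed = 0
    max_overtrim = 0
    for pid, kept in kept_lengths.items():
        if pid not in truth_by_id:
            raise KeyError(f"pair id {pid!r} not present in the truth table")
        if kept is None:
            continue
        rec = truth_by_id[pid]
        for expected, actual in (
            (rec.expected_kept_fwd, kept[0]),
            (rec.expected_kept_rev, kept[1]),
        ):
            over = max(0, expected - actual)
            under = max(0, actual - expected)
            overtrimmed += over
            undertrimmed += under
            if over > 0:
                reads_overtrimmed += 1
                max_overtrim = max(max_overtrim, over)
    return overtrimmed, undertrimmed, reads_overtrimmed, max_overtrim


def basic_qc(reads: Iterable[ReadRecord]) -> dict:
    """Raw-read quality control summary.

    Counts, mean read length, GC and N base fractions, and the fractions of
    bases at or above Phred 20 and 30.  Fractions are ``None`` when there
    are no bases to compute them over.
    """
    read_count = 0
    base_count = 0
    gc = 0
    n = 0
    q20 = 0
    q30 = 0
    for read in reads:
        read_count += 1
        base_count += len(read)
        upper = read.bases.upper()
        gc += upper.count("G") + upper.count("C")
        n += upper.count("N")
        scores = read.phred_scores()
        q20 += int((scores >= 20).sum())
        q30 += int((scores >= 30).sum())
    if base_count:
        fractions = {
            "mean_read_length": base_count / read_count,
            "gc_fraction": gc / base_count,
            "n_fraction": n / base_count,
            "q20_fraction": q20 / base_count,
            "q30_fraction": q30 / base_count,
        }
    else:
        fractions = {
            "mean_read_length": None,
            "gc_fraction": None,
            "n_fraction": None,
            "q20_fraction": None,
            "q30_fraction": None,
        }
    return {"read_count": read_count, "base_count": base_count, **fractions}


def evaluate_trimming(
    trimmed_pairs: Iterable[ReadPair],
    truth: Iterable[TruthRecord],
    adapters: AdapterPair,
    k: int = ADAPTER_KMER_LENGTH,
    bases_in: Optional[int] = None,
) -> TrimStats:
    """Full truth-based evaluation of a trimmed pair stream.

    Pairs present in the truth table but absent from the trimmed output are
    counted as discarded.
    """
    truth_records = list(truth)
    kept: dict[str, Optional[tuple[int, int]]] = {
        rec.pair_id: None for rec in truth_records
    }
    kmer_fwd = adapters.fwd_adapter[:k].upper()
    kmer_rev = adapters.rev_adapter[:k].upper()
    if len(kmer_fwd) < k or len(kmer_rev) < k:
        raise ValueError(f"both adapters must be at least {k} bases long")
    pairs_out = 0
    bases_out = 0
    kmers = 0
    for pair in trimmed_pairs:
        pid = pair_id(pair.fwd.id)
        if pid not in kept:
            raise KeyError(f"pair id {pid!r} not present in the truth table")
        kept[pid] = (len(pair.fwd), len(pair.rev))
        pairs_out += 1
        bases_out += len(pair.fwd) + len(pair.rev)
        kmers += _count_overlapping(pair.fwd.bases.upper(), kmer_fwd)
        kmers += _count_overlapping(pair.rev.bases.upper(), kmer_rev)
    over, under, reads_over, max_over = truth_trim_accounting(kept, truth_records)
    return TrimStats(
        pairs_in=len(truth_records),
        pairs_out=pairs_out,
        pairs_discarded=len(truth_records) - pairs_out,
        bases_in=bases_in,
        bases_out=bases_out,
        overtrimmed_bases=over,
        undertrimmed_bases=under,
        adapter_kmers_remaining=kmers,
        reads_overtrimmed=reads_over,
        max_overtrim_per_read=max_over,
    )
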