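"""Probabilistic sequence-match model.

The trimming algorithm never aligns reads.  Instead it asks, for two
equal-length base windows with ``k`` matching positions out of ``n``: how
likely is a match at least this good if the sequences were unrelated?  Under
a uniform-composition null model every position matches independently with
probability ``p`` (0.25 for DNA), so the answer is the upper binomial tail

    P = sum_{i=k..n} C(n, i) p^i (1 - p)^(n - i)

A window is declared a *non-random match* when P falls below a significance
threshold and, additionally, at least a fixed fraction of its positions
match.  Indels need no modelling: an insertion or deletion inside the
sequenced fragment appears identically in both read directions, so the
forward read and the reverse-complemented reverse read stay in register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "MatchModel",
    "non_random_match_probability",
    "count_matches",
    "is_significant",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class MatchModel:
    """Parameters of the non-random-match test.

    Parameters
    ----------
    p
        Single-base match probability under the random (unrelated-sequence)
        null model. 0.25 assumes uniform base composition.
    threshold
        Significance cutoff on the binomial tail probability P; a comparison
        with P below this value counts as a non-random match. At the default
        1e-6 the shortest perfect overlap that can reach significance is
        10 bases (0.25**10 ~ 9.5e-7).
    min_match_fraction
        Minimum fraction of matching bases required in any comparison,
        regardless of P. Doubles as the early-exit bound when counting
        matches.
    max_length
        Largest comparison length supported; the log-factorial cache covers
        0 .. max_length (sized for twice the longest expected read).
    """

    p: float = 0.25
    threshold: float = 1e-6
    min_match_fraction: float = 0.80
    max_length: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if not 0.0 < self.min_match_fraction <= 1.0:
            raise ValueError(
                f"min_match_fraction must be in (0, 1], got {self.min_match_fraction}"
            )
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")

    @cached_property
    def log_factorial_cache(self) -> np.ndarray:
        """log(i!) for i = 0 .. max_length, immutable."""
        table = np.array([math.lgamma(i + 1) for i in range(self.max_length + 1)])
        table.setflags(write=False)
        return table

    @cached_property
    def _min_k_table(self) -> np.ndarray:
        """Smallest significant match count for every comparison length.

        ``table[n]`` is the least k with P(k, n) < threshold and
        k >= ceil(min_match_fraction * n); ``n + 1`` when no k qualifies.
        Lets the trimmer test significance of whole offset scans with one
        vectorized comparison.
        """
        table = np.zeros(self.max_length + 1, dtype=np.int64)
        table[0] = 1  # n = 0 can never be significant
        for n in range(1, self.max_length + 1):
            lo, hi = 0, n + 1  # invariant: significance is monotone in k
            while lo < hi:
                mid = (lo + hi) // 2
                if non_random_match_probability(mid, n, self) < self.threshold:
                    hi = mid
                else:
                    lo = mid + 1
            k = max(lo, math.ceil(self.min_match_fraction * n))
            table[n] = k  # may equal n + 1: unattainable
        table.setflags(write=False)
        return table

    def min_significant_matches(self, n: int | np.ndarray) -> int | np.ndarray:
        """Least match count that makes a length-``n`` comparison significant."""
        return self._min_k_table[n]


def non_random_match_probability(k: int, n: int, model: MatchModel) -> float:
    """Upper binomial tail: probability of >= ``k`` matches in ``n`` positions.

    Computed in log space from the model's cached log-factorials so that
    comparison lengths up to twice the read length cannot overflow.
    """
    if n < 1:
        raise ValueError(f"comparison length must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"match count {k} outside [0, {n}]")
    if n > model.max_length:
        raise ValueError(
            f"comparison length {n} exceeds cache capacity {model.max_length}"
        )
    if k == 0:
        return 1.0
    lf = model.log_factorial_cache
    i = np.arange(k, n + 1)
    log_terms = (
        lf[n]
        - lf[i]
        - lf[n - i]
        + i * math.log(model.p)
        + (n - i) * math.log1p(-model.p)
    )
    # stable logsumexp; the largest term anchors the scale
    m = log_terms.max()
    total = m + math.log(np.exp(log_terms - m).sum())
    return float(min(1.0, math.exp(total)))


def count_matches(a: str, b: str, max_mismatches: int) -> int | None:
    """Count positions where ``a`` and ``b`` agree, with mismatch early exit.

    Returns the exact match count if at most ``max_mismatches`` positions
    disagree, else ``None`` ("not a candidate" — the remainder of the
    comparison is skipped). Case-insensitive; any position involving an
    ambiguous base (N) counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    matches = 0
    mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == y and x != "N":
            matches += 1
        else:
            mismatches += 1
            if mismatches > max_mismatches:
                return None
    return matches


def is_significant(k: int, n: int, model: MatchModel) -> bool:
    """True iff ``k`` of ``n`` matching bases constitute a non-random match."""
    if n < 1:
        return False
    if k < math.ceil(model.min_match_fraction * n):
        return False
    return non_random_match_probability(k, n, model) < model.threshold


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (case preserved)."""
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"invalid bases for reverse complement: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]
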