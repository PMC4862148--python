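"""Trimming engine: insert match, adapter fallback, post-trimming filters."""

import numpy as np
import pytest

from pairtrim import (
    AdapterPair,
    MatchModel,
    ReadPair,
    ReadRecord,
    TrimParams,
    adapter_flank_confirmed,
    find_adapter_match,
    find_insert_match,
    ncut_trim,
    quality_trim,
    reverse_complement,
    trim_pair,
)
from pairtrim.simulator import SimConfig, synthesize_pair

from conftest import random_dna


def make_pair(fwd: str, rev: str, name: str = "p") -> ReadPair:
    return ReadPair(
        ReadRecord(f"{name}/1", fwd, "I" * len(fwd)),
        ReadRecord(f"{name}/2", rev, "I" * len(rev)),
    )


def read_through_pair(
    insert: str, adapters: AdapterPair, read_length: int = 100
) -> ReadPair:
    """Error-free pair for a fragment, with random fill past the adapter."""
    rng = np.random.default_rng(abs(hash(insert)) % 2**31)

    def build(template: str, adapter: str) -> str:
        read = (template + adapter)[:read_length]
        if len(read) < read_length:
            read += random_dna(rng, read_length - len(read))
        return read

    return make_pair(
        build(insert, adapters.fwd_adapter),
        build(reverse_complement(insert), adapters.rev_adapter),
    )


class TestFindInsertMatch:
    def test_recovers_constructed_insert_length(self, model, adapters, rng):
        insert = random_dna(rng, 90)
        pair = read_through_pair(insert, adapters)
        match = find_insert_match(pair, adapters, model)
        assert match is not None
        assert match.insert_length == 90
        assert match.probability < 1e-6
        # the selected overlap compares all 90 insert positions, all matching
        assert pair.fwd.bases[:90] == insert
        assert reverse_complement(pair.rev.bases[:90]) == insert

    def test_adapter_dimer_detected_through_flanks(self, model, adapters):
        # insert length zero: the reads are pure adapter, no overlap to test
        fwd = adapters.fwd_adapter[:30]
        rev = adapters.rev_adapter[:30]
        match = find_insert_match(make_pair(fwd, rev), adapters, model)
        assert match is not None
        assert match.insert_length == 0

    def test_unrelated_random_reads_yield_no_match(self, model, adapters):
        rng = np.random.default_rng(424242)
        false_hits = 0
        for _ in range(1000):
            pair = make_pair(random_dna(rng, 100), random_dna(rng, 100))
            if find_insert_match(pair, adapters, model) is not None:
                false_hits += 1
        assert false_hits <= 1

    def test_long_insert_overlap_without_read_through(self, model, adapters, rng):
        # insert longer than the read: the mates overlap mid-insert only
        insert = random_dna(rng, 150)
        pair = make_pair(insert[:100], reverse_complement(insert)[:100])
        match = find_insert_match(pair, adapters, model)
        assert match is not None
        assert match.insert_length == 150

    def test_empty_read_degenerates_to_none(self, model, adapters):
        pair = ReadPair(
            ReadRecord("p/1", "", ""), ReadRecord("p/2", "ACGTACGTACGT", "I" * 12)
        )
        assert find_insert_match(pair, adapters, model) is None


class TestAdapterFlankConfirmed:
    def test_perfect_ten_base_forward_flank_confirms(self, model, adapters, rng):
        insert = random_dna(rng, 20)
        fwd = insert + adapters.fwd_adapter[:10]
        rev = random_dna(rng, 30)
        assert adapter_flank_confirmed(make_pair(fwd, rev), 20, adapters, model)

    def test_no_read_confirms(self, model, adapters):
        pair = make_pair("G" * 20 + "T" * 10, "G" * 20 + "T" * 10)
        assert not adapter_flank_confirmed(pair, 20, adapters, model)

    def test_one_base_exact_flank_in_one_read_suffices(self, model):
        adapters = AdapterPair("AGATCGGAAGAGCACACGTC", "AGATCGGAAGAGCGTCGTGT")
        # fwd flank "A" matches the adapter start exactly; rev flank "T" does not
        pair = make_pair("GGGGG" + "A", "GGGGG" + "T")
        assert adapter_flank_confirmed(pair, 5, adapters, model)
        pair = make_pair("GGGGG" + "T", "GGGGG" + "T")
        assert not adapter_flank_confirmed(pair, 5, adapters, model)

    def test_beyond_both_reads_passes_vacuously(self, model, adapters):
        pair = make_pair("ACGTACGTAC", "ACGTACGTAC")
        assert adapter_flank_confirmed(pair, 10, adapters, model)
        assert adapter_flank_confirmed(pair, 25, adapters, model)


class TestFindAdapterMatch:
    def test_finds_constructed_offset(self, model, rng):
        adapter = random_dna(rng, 40)
        read_bases = random_dna(rng, 60) + adapter
        read = ReadRecord("r", read_bases, "I" * len(read_bases))
        match = find_adapter_match(read, adapter, model)
        assert match is not None
        assert match.offset == 60

    def test_random_reads_rarely_match(self, model, adapters):
        rng = np.random.default_rng(99)
        false_hits = 0
        for _ in range(1000):
            read = ReadRecord("r", random_dna(rng, 100), "I" * 100)
            if find_adapter_match(read, adapters.fwd_adapter, model) is not None:
                false_hits += 1
        assert false_hits <= 1

    def test_short_reads_cannot_reach_significance(self, model, adapters):
        # below 10 bases no window can beat the default threshold
        read = ReadRecord("r", adapters.fwd_adapter[:9], "I" * 9)
        assert find_adapter_match(read, adapters.fwd_adapter, model) is None


class TestTrimPair:
    def test_read_through_pair_trimmed_to_insert(self, model, adapters, params, rng):
        insert = random_dna(rng, 90)
        pair = read_through_pair(insert, adapters)
        kept, result = trim_pair(pair, adapters, model, params)
        assert result.path == "insert_match"
        assert result.insert_length == 90
        assert kept is not None
        assert kept.fwd.bases == insert
        assert kept.rev.bases == reverse_complement(insert)
        assert result.removed_fwd == result.removed_rev == 10

    def test_adapter_dimer_discarded(self, model, adapters, params):
        pair = make_pair(adapters.fwd_adapter[:30], adapters.rev_adapter[:30])
        kept, result = trim_pair(pair, adapters, model, params)
        assert kept is None
        assert result.path == "insert_match"
        assert result.insert_length == 0
        assert result.removed_fwd == result.removed_rev == 30

    def test_unrelated_reads_pass_unchanged(self, model, adapters, params):
        rng = np.random.default_rng(5)
        pair = make_pair(random_dna(rng, 100), random_dna(rng, 100))
        kept, result = trim_pair(pair, adapters, model, params)
        assert result.path == "untrimmed"
        assert kept is not None
        assert kept.fwd.bases == pair.fwd.bases
        assert kept.rev.bases == pair.rev.bases
        assert result.removed_fwd == result.removed_rev == 0

    def test_adapter_match_fallback_trims_both_mates_symmetrically(
        self, model, adapters, params, rng
    ):
        # destroy the overlap in the reverse read so only the forward read's
        # adapter hit can fire; both mates must still be cut at its offset
        insert = random_dna(rng, 40)
        fwd = insert + adapters.fwd_adapter[:60]
        rev = random_dna(rng, 100)
        kept, result = trim_pair(make_pair(fwd, rev), adapters, model, params)
        assert result.path == "adapter_match"
        assert kept is not None
        assert len(kept.fwd) == len(kept.rev) == 40
        assert kept.fwd.bases == insert

    def test_prefix_property_on_simulated_pairs(self, model, adapters, params):
        config = SimConfig(n_pairs=1, error_rate=0.02, seed=3)
        rng = np.random.default_rng(17)
        for i in range(300):
            length = int(rng.integers(1, 220))
            fragment = random_dna(rng, length)
            pair, _ = synthesize_pair(fragment, config, rng, pair_id=f"p{i}")
            kept, _ = trim_pair(pair, adapters, model, params)
            if kept is None:
                continue
            for before, after in ((pair.fwd, kept.fwd), (pair.rev, kept.rev)):
                assert before.bases.startswith(after.bases)
                assert before.quals.startswith(after.quals)

    def test_indel_in_insert_does_not_shift_adapter_boundary(
        self, model, adapters, params, rng
    ):
        # an insertion in the fragment appears in both mates, so the overlap
        # stays in register and the adapter boundary just moves with it
        insert = random_dna(rng, 60)
        mutated = insert[:30] + "A" + insert[30:]
        for fragment in (insert, mutated):
            pair = read_through_pair(fragment, adapters)
            kept, result = trim_pair(pair, adapters, model, params)
            assert result.path == "insert_match"
            assert result.insert_length == len(fragment)
            assert kept.fwd.bases == fragment

    def test_unequal_read_lengths_supported(self, model, adapters, params, rng):
        insert = random_dna(rng, 50)
        full = read_through_pair(insert, adapters)
        pair = ReadPair(full.fwd, full.rev.prefix(80))
        kept, result = trim_pair(pair, adapters, model, params)
        assert result.insert_length == 50
        assert len(kept.fwd) == len(kept.rev) == 50

    def test_quality_and_ncut_discard_marks_path_discarded(self, model, adapters):
        bases = "ACGTACGTAC" + "N" * 90
        pair = make_pair(bases, bases)
        kept, result = trim_pair(
            pair, adapters, model, TrimParams(qcut=0, ncut=7, min_len=15)
        )
        assert kept is None
        assert result.path == "discarded"


class TestQualityTrim:
    @staticmethod
    def read_with_quals(scores) -> ReadRecord:
        return ReadRecord(
            "r", "A" * len(scores), "".join(chr(33 + s) for s in scores)
        )

    @pytest.mark.parametrize(
        "scores, qcut, kept",
        [
            ([30, 30, 2, 2], 15, 2),
            ([30, 30, 30], 15, 3),
            ([2, 30, 2], 15, 2),  # interior low-quality base survives
            ([2, 2, 2], 15, 0),
            ([30, 30], 0, 2),  # disabled
        ],
    )
    def test_examples(self, scores, qcut, kept):
        read = self.read_with_quals(scores)
        trimmed = quality_trim(read, qcut)
        assert len(trimmed) == kept
        assert read.bases.startswith(trimmed.bases)


class TestNcutTrim:
    @pytest.mark.parametrize(
        "bases, ncut, expected",
        [
            ("ACGTNNNNNNNACGT", 7, "ACGT"),
            ("ACGTNNNACGT", 7, "ACGTNNNACGT"),
            ("NNNNNNN", 7, ""),
            ("ACGTNNNNNNNACGT", 0, "ACGTNNNNNNNACGT"),  # disabled
        ],
    )
    def test_examples(self, bases, ncut, expected):
        read = ReadRecord("r", bases, "I" * len(bases))
        assert ncut_trim(read, ncut).bases == expected


class TestDomainTypes:
    def test_read_record_validation(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "ACGT", "II")
        with pytest.raises(ValueError):
            ReadRecord("r", "ACXT", "IIII")

    def test_adapter_pair_validation(self):
        with pytest.raises(ValueError):
            AdapterPair("", "ACGT")
        with pytest.raises(ValueError):
            AdapterPair("ACGT", "AC-T")

    def test_trim_params_validation(self):
        with pytest.raises(ValueError):
            TrimParams(min_len=0)
        with pytest.raises(ValueError):
            TrimParams(qcut=-1)

    def test_pair_id_consistency(self):
        pair = make_pair("ACGT", "ACGT", name="frag1")
        assert pair.ids_consistent()
        other = ReadPair(
            ReadRecord("a/1", "ACGT", "IIII"), ReadRecord("b/2", "ACGT", "IIII")
        )
        assert not other.ids_consistent()
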