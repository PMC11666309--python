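"""Circular-genome mutation operators: hand examples, invariants, replay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bitevol.genome import (
    Genome,
    GenomeExtinctionError,
    MutationRates,
    MutationType,
    apply_duplication,
    apply_events,
    apply_inversion,
    apply_large_deletion,
    apply_small_indel,
    apply_substitution,
    apply_translocation,
    draw_event,
    replicate,
    sample_mutation_counts,
    span_length,
)


def g(s: str) -> Genome:
    return Genome.from_string(s)


class TestSubstitution:
    def test_single_flip(self):
        assert apply_substitution(g("0000"), 2) == g("0010")

    def test_involution(self):
        x = g("010011")
        assert apply_substitution(apply_substitution(x, 4), 4) == x

    def test_length_conserved(self):
        assert len(apply_substitution(g("0110"), 0)) == 4

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            apply_substitution(g("0110"), 4)


class TestSmallIndel:
    def test_insertion_hand(self):
        assert apply_small_indel(g("00"), 0, "insertion", 3, "101") == g("10100")

    def test_deletion_hand(self):
        assert apply_small_indel(g("0110"), 1, "deletion", 2) == g("00")

    def test_deletion_wraps(self):
        # span of 3 starting at position 3 of "abcd" removes d, a, b
        assert apply_small_indel(g("0111"), 3, "deletion", 3) == g("1")

    def test_extinction_rejected(self):
        with pytest.raises(GenomeExtinctionError):
            apply_small_indel(g("011"), 0, "deletion", 3)

    @pytest.mark.parametrize("size", [0, 7])
    def test_size_range(self, size):
        with pytest.raises(ValueError):
            apply_small_indel(g("000000000"), 0, "deletion", size)

    def test_payload_length_checked(self):
        with pytest.raises(ValueError):
            apply_small_indel(g("00"), 0, "insertion", 3, "10")


class TestRearrangements:
    def test_duplicate_whole_genome(self):
        assert apply_duplication(g("01"), 0, 1, 0) == g("0101")

    def test_duplication_grows_by_span(self):
        x = g("0011001110")
        assert len(apply_duplication(x, 2, 6, 0)) == 10 + span_length(10, 2, 6)

    def test_large_deletion_hand(self):
        assert apply_large_deletion(g("0110"), 1, 2) == g("00")

    def test_large_deletion_whole_genome_rejected(self):
        with pytest.raises(GenomeExtinctionError):
            apply_large_deletion(g("0110"), 1, 0)  # span of length 4

    def test_duplication_then_deletion_roundtrip(self):
        rng = np.random.default_rng(0)
        x = Genome.random(20, rng)
        dup = apply_duplication(x, 3, 7, 12)  # 5-bp copy inserted before 12
        assert apply_large_deletion(dup, 12, 16) == x

    def test_deletion_then_reinsertion_roundtrip(self):
        x = g("0011010111")
        seg = "".join("01"[b] for b in x.bits[4:7])
        cut = apply_large_deletion(x, 4, 6)
        back = np.insert(cut.bits, 4, np.frombuffer(seg.encode(), np.uint8) - ord("0"))
        assert Genome(bits=back) == x

    def test_translocation_identity(self):
        x = g("0011010111")
        assert apply_translocation(x, 2, 5, 2, inverted=False) == x

    def test_translocation_hand(self):
        # excise "000" from "000111", reinsert after the remaining 3 bases
        assert apply_translocation(g("000111"), 0, 2, 3, inverted=False) == g("111000")

    def test_translocation_p3_range_checked(self):
        with pytest.raises(IndexError):
            apply_translocation(g("000111"), 0, 2, 4)

    def test_inversion_hand(self):
        # span "001" -> complement "110" -> reversed "011"
        assert apply_inversion(g("00100"), 0, 2) == g("01100")

    def test_inversion_involution(self):
        x = g("01101001110")
        assert apply_inversion(apply_inversion(x, 3, 8), 3, 8) == x

    def test_inversion_wrapping_involution(self):
        x = g("01101001110")
        assert apply_inversion(apply_inversion(x, 8, 2), 8, 2) == x


class TestSampling:
    def test_zero_rates_zero_counts(self, rng):
        counts = sample_mutation_counts(5000, MutationRates(), rng)
        assert (counts == 0).all()

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            MutationRates(substitution=-1e-9)
        with pytest.raises(ValueError):
            MutationRates(substitution=1.5)

    def test_mean_total_count(self, rng):
        # 7 types at 1e-6 on 10 kb: mean total = 7 L mu = 0.07
        n, L = 30_000, 10_000
        rates = MutationRates.uniform(1e-6)
        totals = np.array(
            [sample_mutation_counts(L, rates, rng).sum() for _ in range(n)]
        )
        expected = 7 * L * 1e-6
        se = np.sqrt(expected / n)  # Poisson-scale error of the mean
        assert abs(totals.mean() - expected) < 3 * se

    def test_probability_of_no_event_closed_form(self, rng):
        rates = MutationRates.uniform(1e-6)
        p = rates.p_no_event(14_046)
        assert p == pytest.approx(0.90636, abs=5e-5)
        n = 100_000
        draws = rng.binomial(14_046, np.full(7, 1e-6), size=(n, 7)).sum(axis=1)
        p_hat = (draws == 0).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se


class TestReplicate:
    def test_zero_rates_identity(self, rng):
        x = Genome.random(500, rng)
        child, log = replicate(x, MutationRates(), rng)
        assert child == x and log == []

    def test_substitution_mean_hamming(self, rng):
        # substitutions only at 1e-3 on 1 kb: mean Hamming distance = 1
        x = Genome.random(1000, rng)
        rates = MutationRates(substitution=1e-3)
        n = 10_000
        dist = np.empty(n)
        for i in range(n):
            child, _ = replicate(x, rates, rng)
            dist[i] = (child.bits != x.bits).sum()
        se = np.sqrt(1.0 / n)  # Binomial(1000, 1e-3) variance ~ mean = 1
        assert abs(dist.mean() - 1.0) < 3 * se

    def test_replay_reproduces_child(self, rng):
        rates = MutationRates.uniform(2e-3)
        for _ in range(50):
            x = Genome.random(int(rng.integers(30, 300)), rng)
            child, log = replicate(x, rates, rng)
            replayed = apply_events(x.bits, log)
            assert np.array_equal(replayed, child.bits)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    length=st.integers(2, 60),
    mtype=st.sampled_from(list(MutationType)),
    seed=st.integers(0, 2**31 - 1),
)
def test_operator_laws(length, mtype, seed):
    """Alphabet closure, the length law of each operator class, L >= 1."""
    rng = np.random.default_rng(seed)
    x = Genome.random(length, rng)
    ev = draw_event(x.bits, mtype, rng)
    from bitevol.genome import apply_event

    child = apply_event(x.bits, ev)
    assert set(np.unique(child)) <= {0, 1}
    assert child.size >= 1
    if ev.discarded:
        assert np.array_equal(child, x.bits)
    elif mtype in (
        MutationType.SUBSTITUTION,
        MutationType.TRANSLOCATION,
        MutationType.INVERSION,
    ):
        assert child.size == length
    elif mtype in (MutationType.SMALL_INSERTION, MutationType.DUPLICATION):
        assert child.size == length + ev.size
    else:
        assert child.size == length - ev.size
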