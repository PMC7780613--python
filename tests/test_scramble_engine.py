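"""Tests for the Cre recombination engine: event arithmetic, conservation
laws, replayability, and sampling distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, spearmanr

from sgc import (
    RecombinationEvent,
    apply_event,
    apply_events,
    make_toy_chromosome,
    reference_state,
    sample_events,
    simulate_population,
    site_positions,
    total_bp,
)
from sgc.scramble_engine import RecombinationError


@pytest.fixture(scope="module")
def toy8():
    return make_toy_chromosome(8, lengths=[500, 900, 1300, 700, 1100, 600,
                                           800, 1000])


class TestApplyEvent:
    def test_single_lu_deletion_arithmetic(self, synxiil):
        st0 = reference_state(synxiil)
        child = apply_event(st0, RecombinationEvent("deletion", 7, 8))
        assert len(child.segments) == 45 and len(child.sites) == 46
        assert "LU-8" not in {lu for lu, _ in child.segments}
        assert total_bp(synxiil, child) == \
               170_000 - synxiil.lu("LU-8").length_bp

    def test_deletion_conserves_bp(self, toy8):
        st0 = reference_state(toy8)
        child = apply_event(st0, RecombinationEvent("deletion", 2, 6))
        excised = sum(toy8.lus[k].length_bp for k in range(2, 6))
        assert total_bp(toy8, child) + excised == total_bp(toy8, st0)

    def test_inversion_is_an_involution(self, toy8):
        st0 = reference_state(toy8)
        ev = RecombinationEvent("inversion", 1, 5)
        assert apply_event(apply_event(st0, ev), ev) == st0

    def test_inversion_flips_order_and_orientation(self, toy8):
        st0 = reference_state(toy8)
        child = apply_event(st0, RecombinationEvent("inversion", 1, 4))
        assert [s for s in child.segments[1:4]] == \
               [("LU-4", -1), ("LU-3", -1), ("LU-2", -1)]
        assert total_bp(toy8, child) == total_bp(toy8, st0)

    def test_duplication_adds_block_length(self, toy8):
        st0 = reference_state(toy8)
        child = apply_event(st0, RecombinationEvent("duplication", 2, 6))
        block = sum(toy8.lus[k].length_bp for k in range(2, 6))
        assert total_bp(toy8, child) == total_bp(toy8, st0) + block
        assert len(child.sites) == len(child.segments) + 1

    def test_degenerate_pair_rejected(self):
        with pytest.raises(RecombinationError, match="degenerate"):
            RecombinationEvent("deletion", 3, 3)

    def test_out_of_range_pair_rejected(self, toy8):
        st0 = reference_state(toy8)
        with pytest.raises(RecombinationError, match="invalid"):
            apply_event(st0, RecombinationEvent("deletion", 0, 99))


@settings(max_examples=60, deadline=None)
@given(data=st.data())
def test_random_event_sequences_conserve_structure(data):
    """Site/segment count invariant and bp bookkeeping hold under arbitrary
    event sequences; deletions only remove bp, duplications only add it."""
    toy = make_toy_chromosome(6, lengths=[400, 800, 600, 1200, 500, 900])
    state = reference_state(toy)
    bp = total_bp(toy, state)
    for _ in range(data.draw(st.integers(0, 6))):
        n = len(state.sites)
        if n < 2:
            break
        i = data.draw(st.integers(0, n - 2))
        j = data.draw(st.integers(i + 1, n - 1))
        etype = data.draw(st.sampled_from(["deletion", "inversion",
                                           "duplication"]))
        state = apply_event(state, RecombinationEvent(etype, i, j))
        new_bp = total_bp(toy, state)
        assert len(state.sites) == len(state.segments) + 1
        if etype == "deletion":
            assert new_bp <= bp
        elif etype == "inversion":
            assert new_bp == bp
        else:
            assert new_bp >= bp
        bp = new_bp


class TestSampling:
    def test_uniform_weights_are_multinomial_over_pairs(self):
        toy = make_toy_chromosome(2)
        state = reference_state(toy)  # 3 sites -> 3 pairs
        w = np.ones((3, 3)) - np.eye(3)
        rng = np.random.default_rng(0)
        events = sample_events(state, 10_000, w, rng=rng)
        counts = np.zeros(3)
        pairs = [(0, 1), (0, 2), (1, 2)]
        for e in events:
            counts[pairs.index((e.i, e.j))] += 1
        assert chisquare(counts).pvalue > 1e-3

    def test_forced_pair_is_always_sampled(self):
        toy = make_toy_chromosome(2)
        state = reference_state(toy)
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        events = sample_events(state, 200, w, rng=np.random.default_rng(1))
        assert all((e.i, e.j) == (0, 1) for e in events)

    def test_power_law_prefers_adjacent_pairs(self, synxiil):
        state = reference_state(synxiil)
        pos = site_positions(synxiil, state)
        d = np.abs(pos[:, None] - pos[None, :])
        w = (d + 1000.0) ** -1.5
        np.fill_diagonal(w, 0.0)
        events = sample_events(state, 10_000, w,
                               rng=np.random.default_rng(2))
        dists = [pos[e.j] - pos[e.i] for e in events]
        counts: dict[float, int] = {}
        for x in dists:
            counts[x] = counts.get(x, 0) + 1
        xs = sorted(counts)
        rho = spearmanr(xs, [counts[x] for x in xs]).statistic
        assert rho < -0.5

    def test_all_zero_weights_rejected(self):
        toy = make_toy_chromosome(2)
        with pytest.raises(RecombinationError, match="zero"):
            sample_events(reference_state(toy), 1, np.zeros((3, 3)),
                          rng=np.random.default_rng(0))


class TestPopulation:
    def test_lambda_zero_leaves_population_untouched(self, synxiil):
        pop = simulate_population(synxiil, 200, lambda_events=0.0, seed=4)
        base = reference_state(synxiil)
        assert all(s.state == base and not s.events for s in pop)

    def test_replayability(self, synxiil_lu24):
        pop = simulate_population(synxiil_lu24, 150, 2.0, seed=9)
        base = reference_state(synxiil_lu24)
        for s in pop:
            assert apply_events(base, s.events) == s.state

    def test_determinism(self, synxiil):
        a = simulate_population(synxiil, 100, 2.0, seed=21)
        b = simulate_population(synxiil, 100, 2.0, seed=21)
        assert [s.state for s in a] == [s.state for s in b]
        assert [s.events for s in a] == [s.events for s in b]
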