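"""Simulated-annealing optimizer: proposals, losses, schedule, full runs."""

import numpy as np
import pytest

from groovebinder.hallucination import (
    AMINO_ACIDS, BLOSUM62_BACKGROUND, HashOracle, LossWeights, OracleError,
    OraclePrediction, PlantedOracle, Schedule, chain_residue_index,
    eligible_positions, init_sequence, metropolis_accept, propose, run,
    temperature_at, total_loss,
)
from groovebinder.metrics import Distogram, PaeMatrix


class TestInitSequence:
    def test_zero_length_rejected(self, rng):
        with pytest.raises(ValueError):
            init_sequence(0, rng)

    def test_seeded_determinism(self):
        a = init_sequence(50, np.random.default_rng(5))
        b = init_sequence(50, np.random.default_rng(5))
        assert a == b

    def test_background_frequencies_recovered(self):
        seq = init_sequence(100000, np.random.default_rng(2))
        n = len(seq)
        for aa in "LAWC":
            p = BLOSUM62_BACKGROUND[aa]
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(seq.count(aa) / n - p) < 3 * sigma


class TestPropose:
    def test_hamming_distance_exactly_k(self, rng):
        seq = init_sequence(60, rng)
        plddt = rng.uniform(20, 90, size=60)
        for k in (1, 2, 3):
            cand = propose(seq, plddt, k, rng)
            assert sum(a != b for a, b in zip(seq, cand)) == k

    def test_uniform_plddt_makes_all_positions_eligible(self):
        assert len(eligible_positions(np.full(40, 70.0))) == 40

    def test_positions_restricted_to_lowest_half(self, rng):
        plddt = np.r_[np.full(20, 30.0), np.full(20, 95.0)]
        seq = "A" * 40
        for _ in range(50):
            cand = propose(seq, plddt, 3, rng)
            changed = [i for i, (a, b) in enumerate(zip(seq, cand)) if a != b]
            assert all(i < 20 for i in changed)

    def test_k_reduced_to_eligible_count(self, rng):
        plddt = np.r_[np.full(2, 10.0), np.full(38, 10.0)]  # all equal: 40
        plddt = np.r_[np.full(2, 10.0), np.full(2, 95.0)]
        cand = propose("AAAA", plddt, 3, rng)
        assert sum(a != b for a, b in zip("AAAA", cand)) == 2


def _prediction(plddt, ptm, pae_value, contact_low: bool, coords):
    L = len(plddt)
    probs = np.zeros((L, L, 5))
    probs[..., 0 if contact_low else -1] = 1.0
    edges = np.array([2.0, 4, 6, 8, 10, 31.0])
    half = L // 2
    spans = dict(binder_span=(0, half), target_span=(half, L))
    return OraclePrediction(
        plddt=np.asarray(plddt, dtype=float), ptm=ptm,
        pae=PaeMatrix(np.full((L, L), pae_value), **spans),
        distogram=Distogram(probs, edges, **spans),
        coords=coords)


class TestTotalLoss:
    def test_perfect_prediction_leaves_only_rg_term(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8)  # compact: small rg term c
        pred = _prediction([100.0] * 8, 1.0, 0.0, True, coords)
        total, comps = total_loss(pred)
        assert total == pytest.approx(0.1 * comps["rg"], abs=1e-12)

    def test_worst_case_sums_weights(self):
        # rg term forced to exactly 1 via two atoms at the right spread
        r_sphere = (3 * 2 * 110.0 / (4 * np.pi)) ** (1 / 3)
        coords = np.array([[0.0, 0, 0], [2 * r_sphere, 0, 0]])
        pred = _prediction([0.0, 0.0], 0.0, 31.0, False, coords)
        total, _ = total_loss(pred)
        assert total == pytest.approx(1 + 1 + 0.1 + 3 + 5, abs=1e-9)

    def test_matches_hand_computed_weighted_sum(self, rng):
        L = 10
        plddt = rng.uniform(40, 95, size=L)
        coords = rng.normal(size=(L, 3)) * 6
        pred = _prediction(plddt, 0.63, 11.5, True, coords)
        total, comps = total_loss(pred)
        from groovebinder.metrics import (contact_probability_loss,
                                          interface_pae, rg_loss_normalized)
        hand = (1.0 * (1 - plddt.mean() / 100)
                + 1.0 * (1 - 0.63)
                + 0.1 * rg_loss_normalized(coords, L)
                + 3.0 * (1 - contact_probability_loss(pred.distogram))
                + 5.0 * interface_pae(pred.pae) / 31.0)
        assert total == pytest.approx(hand, abs=1e-12)


class TestMetropolis:
    def test_improvement_always_accepted(self, rng):
        assert all(metropolis_accept(-0.01, 0.01, rng) for _ in range(100))

    def test_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, 0.01, rng) for _ in range(100))

    def test_half_acceptance_at_t_ln2(self):
        rng = np.random.default_rng(8)
        T = 0.01
        acc = sum(metropolis_accept(T * np.log(2), T, rng)
                  for _ in range(10000)) / 10000
        assert acc == pytest.approx(0.5, abs=0.02)


class TestSchedule:
    def test_default_totals_5000_steps(self):
        assert Schedule().total_steps == 5000

    def test_phase_mutation_counts(self):
        s = Schedule()
        assert s.mutations_at(0) == 3
        assert s.mutations_at(1249) == 3
        assert s.mutations_at(1250) == 2
        assert s.mutations_at(3749) == 2
        assert s.mutations_at(3750) == 1
        assert s.mutations_at(4999) == 1

    @pytest.mark.parametrize("step,expect", [(0, 0.01), (500, 0.005),
                                             (1000, 0.0025)])
    def test_temperature_halving(self, step, expect):
        assert temperature_at(step) == pytest.approx(expect)

    def test_chain_break_offset(self):
        idx = chain_residue_index(3, 2)
        np.testing.assert_array_equal(idx, [0, 1, 2, 35, 36])


class TestTemperatureProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 20000), st.floats(1.0, 2000.0))
    @settings(max_examples=50, derandomize=True)
    def test_halving_property(self, step, half_life):
        t_now = temperature_at(step, 0.01, half_life)
        t_later = temperature_at(step + int(half_life), 0.01, half_life)
        assert t_later == pytest.approx(
            t_now * 2.0 ** (-int(half_life) / half_life), rel=1e-9)


class TestRun:
    def test_trajectory_length_matches_schedule(self):
        sched = Schedule(phases=((50, 3), (50, 2), (50, 1)))
        rec = run(HashOracle(), "ASNTW", 10, schedule=sched, seed=4)
        assert len(rec.steps) == 150

    def test_best_so_far_non_increasing(self):
        sched = Schedule(phases=((100, 2), (100, 1)))
        rec = run(HashOracle(), "ASNTW", 10, schedule=sched, seed=4)
        best = np.inf
        for s in rec.steps:
            if s.accepted and s.total < best:
                best = s.total
        assert rec.best_loss <= best + 1e-12

    def test_component_bookkeeping_reproduces_totals(self):
        sched = Schedule(phases=((60, 2), (60, 1)))
        rec = run(HashOracle(), "ASNTW", 10, schedule=sched, seed=4)
        w = LossWeights()
        for s in rec.steps:
            recomputed = (w.plddt * s.components["plddt"]
                          + w.ptm * s.components["ptm"]
                          + w.rg * s.components["rg"]
                          + w.contact * s.components["contact"]
                          + w.pae * s.components["pae"])
            assert abs(recomputed - s.total) < 1e-12

    def test_bitwise_reproducible(self):
        sched = Schedule(phases=((80, 2), (80, 1)))
        a = run(HashOracle(), "ASNTW", 12, schedule=sched, seed=9)
        b = run(HashOracle(), "ASNTW", 12, schedule=sched, seed=9)
        assert a.best_sequence == b.best_sequence
        assert [s.sequence_hash for s in a.steps] == \
               [s.sequence_hash for s in b.steps]
        assert [s.total for s in a.steps] == [s.total for s in b.steps]

    def test_target_chain_never_mutated(self):
        sched = Schedule(phases=((100, 3),))
        rec = run(HashOracle(), "ASNTW", 10, schedule=sched, seed=2)
        assert rec.target_sequence == "ASNTW"
        assert len(rec.final_sequence) == 10

    def test_oracle_failure_aborts_with_partial_record(self):
        class FlakyOracle:
            def __init__(self):
                self.calls = 0

            def predict(self, binder, target, residue_index=None):
                self.calls += 1
                if self.calls > 20:
                    raise RuntimeError("backend down")
                return HashOracle().predict(binder, target, residue_index)

        with pytest.raises(OracleError) as exc:
            run(FlakyOracle(), "ASNTW", 10,
                schedule=Schedule(phases=((100, 1),)), seed=2)
        assert exc.value.step == 19
        assert len(exc.value.trajectory.steps) == 19

    def test_planted_optimum_recovered(self):
        oracle = PlantedOracle("LEIKALEQ")
        rec = run(oracle, "ASNTW", 8,
                  schedule=Schedule(phases=((400, 2), (600, 1))), seed=1)
        assert rec.best_sequence == "LEIKALEQ"

    def test_acceptance_rate_decays_with_temperature(self):
        sched = Schedule(phases=((400, 1),), t0=0.05, half_life=100.0)
        rec = run(HashOracle(), "ASNTW", 12, schedule=sched, seed=6)
        first = np.mean([s.accepted for s in rec.steps[:100]])
        last = np.mean([s.accepted for s in rec.steps[-100:]])
        assert first >= last
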