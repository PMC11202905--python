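"""NHEJ state machine, contact joining, classification and the driver."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_break_end
from dsbdyn import (
    DamageConfig,
    MotionParams,
    Nucleus,
    RepairKinetics,
    RepairState,
    SimulationConfig,
    attempt_joins,
    classify_join,
    run_repair_simulation,
    step_repair_states,
)
from dsbdyn.repair import run_annihilation_oracle, survival_time_grid


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        dose_gy=0.5,
        t_max_s=600.0,
        dt_s=1.0,
        motion=MotionParams(alpha=0.5, k_alpha=20.0, dt=1.0, v=16.0, mu0=0.001, mu1=0.016),
        nucleus=Nucleus(radius=2000.0),
        kinetics=RepairKinetics(mode="minimal"),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestStepRepairStates:
    def test_zero_rates_frozen(self):
        ends = [make_break_end(i, [0, 0, 0], state=RepairState.NAKED) for i in range(5)]
        step_repair_states(ends, 1.0, RepairKinetics(rate_ku=0.0, rate_pkcs=0.0), seed=0)
        assert all(e.repair_state == RepairState.NAKED for e in ends)

    def test_ligated_absorbing(self):
        end = make_break_end(0, [0, 0, 0], state=RepairState.LIGATED)
        step_repair_states([end], 1.0, RepairKinetics(rate_ku=100.0), seed=0)
        assert end.repair_state == RepairState.LIGATED

    def test_waiting_time_mean(self):
        """Empirical naked->ku waiting time ~ 1/k within 3 SE (1e4 ends)."""
        k, dt = 0.05, 1.0
        kin = RepairKinetics(rate_ku=k, rate_pkcs=0.0)
        ends = [make_break_end(i, [0, 0, 0], state=RepairState.NAKED) for i in range(10_000)]
        rng = np.random.default_rng(3)
        waits = np.full(len(ends), -1.0)
        for step in range(1, 400):
            step_repair_states(ends, dt, kin, rng)
            for i, e in enumerate(ends):
                if waits[i] < 0 and e.repair_state == RepairState.KU_BOUND:
                    waits[i] = step * dt
        waits = waits[waits > 0]
        # discretized exponential: mean = dt / (1 - exp(-k dt))
        expected = dt / (1.0 - math.exp(-k * dt))
        se = expected / math.sqrt(waits.size)
        assert abs(waits.mean() - expected) < 3.5 * se

    def test_small_dt_first_order_probability(self):
        k, dt = 0.5, 1e-3
        kin = RepairKinetics(rate_ku=k, rate_pkcs=0.0)
        ends = [make_break_end(i, [0, 0, 0], state=RepairState.NAKED) for i in range(200_000)]
        step_repair_states(ends, dt, kin, seed=5)
        frac = np.mean([e.repair_state == RepairState.KU_BOUND for e in ends])
        assert frac == pytest.approx(k * dt, rel=0.2)

    def test_minimal_mode_immediately_eligible(self):
        ends = [make_break_end(0, [0, 0, 0], state=RepairState.NAKED)]
        step_repair_states(ends, 1.0, RepairKinetics(mode="minimal"), seed=0)
        assert ends[0].repair_state == RepairState.PKCS_BOUND


class TestAttemptJoins:
    def test_contact_within_radius_joins(self):
        a = make_break_end(0, [0, 0, 0])
        b = make_break_end(1, [0, 0, 12.5])
        events = attempt_joins([a, b], 25.0, time=3.0)
        assert len(events) == 1
        assert events[0].time == 3.0
        assert a.repair_state == RepairState.LIGATED and b.joined_to == 0

    def test_out_of_range_no_event(self):
        a = make_break_end(0, [0, 0, 0])
        b = make_break_end(1, [0, 0, 50.0])
        assert attempt_joins([a, b], 25.0, time=0.0) == []

    def test_ineligible_states_excluded(self):
        a = make_break_end(0, [0, 0, 0], state=RepairState.KU_BOUND)
        b = make_break_end(1, [0, 0, 1.0])
        assert attempt_joins([a, b], 25.0, time=0.0) == []

    def test_greedy_near_optimal_vs_bruteforce(self):
        """Tight 6-end clusters: greedy pairing always joins the globally
        closest pair, leaves no joinable pair unmatched, and its total
        distance is near the exhaustive minimum-weight perfect matching."""

        def all_pairings(items):
            if not items:
                yield []
                return
            a = items[0]
            for k in range(1, len(items)):
                for rest in all_pairings(items[1:k] + items[k + 1:]):
                    yield [(a, items[k])] + rest

        rng = np.random.default_rng(17)
        ratios = []
        for _ in range(150):
            vec = rng.standard_normal((6, 3))
            vec /= np.linalg.norm(vec, axis=1, keepdims=True)
            pos = vec * (10.0 * rng.random(6)[:, None] ** (1 / 3))
            ends = [make_break_end(i, pos[i], chrom_id=i) for i in range(6)]
            events = attempt_joins(ends, 25.0, time=0.0)
            assert len(events) == 3  # maximal: everything joinable is joined
            greedy_pairs = {tuple(sorted((e.end_a, e.end_b))) for e in events}
            dist = {
                (i, j): float(np.linalg.norm(pos[i] - pos[j]))
                for i, j in itertools.combinations(range(6), 2)
            }
            closest = min(dist, key=dist.get)
            assert closest in greedy_pairs
            best = min(
                sum(dist[tuple(sorted(p))] for p in m)
                for m in all_pairings(list(range(6)))
            )
            greedy_total = sum(dist[p] for p in greedy_pairs)
            ratios.append(greedy_total / best)
        assert np.mean(ratios) < 1.15
        assert max(ratios) < 1.8

    def test_deterministic_tie_break(self):
        # three colinear eligible ends, equal spacing: two candidate pairs at
        # distance 10 ((0,1) and (0,2)); the lexicographically smaller id
        # pair (0,1) wins the tie deterministically
        ends = [
            make_break_end(2, [0, 0, 0], chrom_id=0),
            make_break_end(0, [0, 0, 10.0], chrom_id=1),
            make_break_end(1, [0, 0, 20.0], chrom_id=2),
        ]
        events = attempt_joins(ends, 25.0, time=0.0)
        assert len(events) == 1
        assert (events[0].end_a, events[0].end_b) == (0, 1)


class TestClassifyJoin:
    def test_partners_correct(self):
        a = make_break_end(0, [0, 0, 0], centromere=True)
        b = make_break_end(1, [0, 0, 0], centromere=True)
        category, dic = classify_join(a, b)
        assert category == "correct" and not dic

    def test_interchromosomal_both_centric_is_dicentric(self):
        a = make_break_end(0, [0, 0, 0], chrom_id=1, centromere=True)
        b = make_break_end(2, [0, 0, 0], chrom_id=2, centromere=True)
        category, dic = classify_join(a, b)
        assert category == "inter_misrepair" and dic

    def test_acentric_partner_no_dicentric(self):
        a = make_break_end(0, [0, 0, 0], chrom_id=1, centromere=True)
        b = make_break_end(2, [0, 0, 0], chrom_id=2, centromere=False)
        category, dic = classify_join(a, b)
        assert category == "inter_misrepair" and not dic

    def test_same_chromosome_not_partner_intra(self):
        a = make_break_end(0, [0, 0, 0], chrom_id=1, centromere=True)
        b = make_break_end(2, [0, 0, 0], chrom_id=1, centromere=True)
        category, dic = classify_join(a, b)
        assert category == "intra_misrepair" and dic


class TestRunRepairSimulation:
    def test_zero_dsbs_survival_one_with_warning(self):
        cfg = small_config(dose_gy=0.0)
        with pytest.warns(UserWarning):
            res = run_repair_simulation(cfg, seed=0)
        assert res.n_dsb == 0 and res.events == []
        assert np.all(res.survival == 1.0)

    def test_colocated_pair_joins_correctly(self):
        """Two ends of one DSB, immediately eligible, capture > offset."""
        cfg = small_config(
            dose_gy=1.0 / 35.0,  # mean one DSB; seed chosen to realize >= 1
            t_max_s=20.0,
            motion=MotionParams(alpha=0.5, k_alpha=1.0, dt=1.0, mu0=0.0),
        )
        res = run_repair_simulation(cfg, seed=12)
        assert res.n_dsb >= 1
        assert len(res.events) == res.n_dsb
        assert all(ev.category == "correct" for ev in res.events)
        assert all(ev.time == 1.0 for ev in res.events)
        assert res.survival[-1] == 0.0

    def test_survival_monotone_and_bounded(self):
        res = run_repair_simulation(small_config(), seed=21)
        assert res.survival[0] == 1.0
        assert np.all(np.diff(res.survival) <= 1e-12)
        assert np.all((res.survival >= 0) & (res.survival <= 1))

    def test_end_conservation(self):
        """Every event consumes exactly two ends; no end joins twice."""
        res = run_repair_simulation(small_config(dose_gy=2.0), seed=22)
        joined = [e for ev in res.events for e in (ev.end_a, ev.end_b)]
        assert len(joined) == len(set(joined))
        n_ligated = int(np.sum(res.final_states == int(RepairState.LIGATED)))
        assert n_ligated == 2 * len(res.events)
        assert n_ligated % 2 == 0

    def test_seed_determinism(self):
        a = run_repair_simulation(small_config(), seed=33)
        b = run_repair_simulation(small_config(), seed=33)
        np.testing.assert_array_equal(a.survival, b.survival)
        assert a.events == b.events
        c = run_repair_simulation(small_config(), seed=34)
        assert a.events != c.events

    def test_survival_grid_log_spaced(self):
        grid = survival_time_grid(1.0, 1000.0, 32)
        assert grid[0] == 0.0
        assert grid[1] == pytest.approx(1.0)
        assert grid[-1] == pytest.approx(1000.0)
        ratios = grid[2:] / grid[1:-1]
        np.testing.assert_allclose(ratios, ratios[0])


class TestAnnihilationOracle:
    def test_survival_monotone_from_one(self):
        res = run_annihilation_oracle(n_ends=200, n_steps=200, seed=1)
        assert res.survival[0] == 1.0
        assert np.all(np.diff(res.survival) <= 1e-12)

    def test_deterministic(self):
        a = run_annihilation_oracle(n_ends=100, n_steps=50, seed=5)
        b = run_annihilation_oracle(n_ends=100, n_steps=50, seed=5)
        np.testing.assert_array_equal(a.survival, b.survival)
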