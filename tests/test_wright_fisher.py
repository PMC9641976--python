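import math

import numpy as np
import pandas as pd
import pytest

from karyodyn import (
    FitnessParams,
    KaryoGenotype,
    PopulationState,
    SimConfig,
    deterministic_run,
    gamete_pools,
    run,
    run_replicates,
    step,
    ys_share,
)
from karyodyn.observations import OBSERVED_FEMALE_COUNTS, OBSERVED_FEMALE_FREQS
from karyodyn.wright_fisher import _zygote_distribution, initial_state

G = KaryoGenotype


class TestGametePools:
    def test_single_fertile_xy_male(self):
        state = PopulationState(0, {}, {G(1, 1, 0): 1})
        _, sperm = gamete_pools(state, FitnessParams())
        # fitness 1 x 0.5 X sperm: the X class carries weight 0.5
        assert sperm[G(1, 0, 0)] == pytest.approx(0.5)
        assert sperm[G(0, 1, 0)] == pytest.approx(0.5)

    def test_xx_female_contributes_nothing(self):
        state = PopulationState(0, {G(2, 0, 0): 1}, {})
        egg, sperm = gamete_pools(state, FitnessParams())
        assert egg == {}
        assert sperm == {}

    def test_one_xxy_female_one_xy_male_zero_costs(self):
        state = PopulationState(0, {G(2, 1, 0): 1}, {G(1, 1, 0): 1})
        egg, sperm = gamete_pools(state, FitnessParams(s=0.0, y=0.0))
        assert egg == pytest.approx({G(1, 0, 0): 0.5, G(1, 1, 0): 0.5})
        assert sperm == pytest.approx({G(1, 0, 0): 0.5, G(0, 1, 0): 0.5})

    def test_fitness_weights_the_pool(self):
        # XXY^S females (fitness 1 - 0.5s) vs XXY females (fitness 1 - 0.5y):
        # with y=1, h'=0.5 the XXY contribution is halved relative to XXY^S at s=0
        state = PopulationState(0, {G(2, 0, 1): 1, G(2, 1, 0): 1}, {})
        egg, _ = gamete_pools(state, FitnessParams(s=0.0, y=1.0))
        # XXY^S weight 1 -> {X: .5, XY^S: .5}; XXY weight .5 -> {X: .25, XY: .25}
        assert egg[G(1, 0, 1)] == pytest.approx(0.5 / 1.5)
        assert egg[G(1, 1, 0)] == pytest.approx(0.25 / 1.5)


class TestStep:
    def test_deterministic_pools_make_xxy_daughters(self):
        # XXYY mothers give only XY eggs; X sperm then makes every zygote XXY
        egg = {G(1, 1, 0): 1.0}
        sperm = {G(1, 0, 0): 1.0}
        zygotes = _zygote_distribution(egg, sperm)
        assert zygotes == {G(2, 1, 0): 1.0}

    def test_preserves_population_size(self):
        config = SimConfig(population_size=64, generations=1, seed=5)
        rng = np.random.default_rng(5)
        state = initial_state(config, rng)
        nxt = step(state, config, rng)
        assert nxt.size == 64
        assert nxt.generation == 1

    def test_reproducible_under_seed(self):
        config = SimConfig(population_size=50, generations=1, seed=5)
        state = initial_state(config, np.random.default_rng(1))
        a = step(state, config, np.random.default_rng(42))
        b = step(state, config, np.random.default_rng(42))
        assert a == b

    def test_empty_pool_means_extinction(self):
        state = PopulationState(0, {G(2, 0, 0): 10}, {G(1, 1, 0): 10})
        config = SimConfig(population_size=20)
        nxt = step(state, config, np.random.default_rng(0))
        assert nxt.extinct
        assert nxt.generation == 1

    def test_neutralized_fitness_sampling_is_unbiased(self, monkeypatch):
        # force every karyotype to fitness 1: the offspring genotype
        # distribution must then equal the zygote distribution exactly
        import karyodyn.wright_fisher as wf

        monkeypatch.setattr(wf, "female_fitness", lambda g, p: 1.0)
        monkeypatch.setattr(wf, "male_fitness", lambda g, p: 1.0)
        config = SimConfig(population_size=100, generations=1, seed=9)
        state = initial_state(config, np.random.default_rng(9))
        egg, sperm = wf.gamete_pools(state, config.params)
        zygotes = _zygote_distribution(egg, sperm)
        acc: dict = {}
        reps = 600
        for r in range(reps):
            nxt = wf.step(state, config, np.random.default_rng(r))
            for d in (nxt.females, nxt.males):
                for g, c in d.items():
                    acc[g] = acc.get(g, 0) + c
        total = sum(acc.values())
        for g, p in zygotes.items():
            se = math.sqrt(p * (1 - p) / total)
            assert acc.get(g, 0) / total == pytest.approx(p, abs=4 * se + 1e-9)


class TestYsShare:
    def test_observed_female_counts(self):
        # 48 females carry 63 Y-type chromosomes of which 33 are Y^S
        assert ys_share(OBSERVED_FEMALE_COUNTS) == pytest.approx(33 / 63)

    def test_all_full_y(self):
        assert ys_share({G(1, 1, 0): 7}) == 0.0

    def test_all_truncated(self):
        assert ys_share({G(2, 0, 1): 3}) == 1.0

    def test_undefined_without_ytypes(self):
        assert math.isnan(ys_share({G(2, 0, 0): 5}))


class TestRun:
    def test_no_ys_cannot_arise_de_novo(self):
        config = SimConfig(
            population_size=60,
            generations=30,
            params=FitnessParams(),
            initial_female_dist={G(2, 1, 0): 1.0},
            initial_male_dist={G(1, 1, 0): 1.0},
            seed=2,
        )
        trajectory = run(config)
        assert not trajectory.extinct
        assert np.all(trajectory.ys_shares == 0.0)

    def test_equal_costs_lose_ys_deterministically(self):
        config = SimConfig(
            generations=100, params=FitnessParams(s=0.5, y=0.5), seed=0
        )
        det = deterministic_run(config)
        shares = det.ys_shares
        assert np.all(np.diff(shares) < 0)  # strictly decreasing
        assert shares[-1] < 1e-3

    def test_trajectory_length_and_generation0(self):
        config = SimConfig(population_size=100, generations=10, seed=3)
        trajectory = run(config)
        assert trajectory.n_generations == 10
        assert sum(trajectory.female_freqs[0].values()) == pytest.approx(1.0)
        assert set(trajectory.female_freqs[0]) <= set(OBSERVED_FEMALE_FREQS)

    def test_replicates_are_independent_and_reproducible(self):
        config = SimConfig(generations=5, seed=17, replicates=3)
        a = run_replicates(config)
        b = run_replicates(config)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.ys_shares, tb.ys_shares, equal_nan=True)
        assert not np.array_equal(a[0].ys_shares, a[1].ys_shares, equal_nan=True)


class TestDeterministicOracle:
    def test_one_generation_by_hand_summation(self):
        """Spreadsheet-style recomputation of generation 1 from the observed
        initial distributions under zero female costs, using literal gamete
        tables and fitness values written out by hand."""
        egg_tables = {
            G(2, 1, 0): {G(1, 0, 0): 0.5, G(1, 1, 0): 0.5},
            G(2, 0, 1): {G(1, 0, 0): 0.5, G(1, 0, 1): 0.5},
            G(2, 2, 0): {G(1, 1, 0): 1.0},
            G(2, 0, 2): {G(1, 0, 1): 1.0},
            G(2, 1, 1): {G(1, 1, 0): 0.5, G(1, 0, 1): 0.5},
        }
        sperm_tables = {
            G(1, 1, 0): {G(1, 0, 0): 0.5, G(0, 1, 0): 0.5},
            G(1, 0, 1): {G(1, 0, 0): 0.5, G(0, 0, 1): 0.5},
            G(1, 2, 0): {G(1, 0, 0): 1 / 6, G(0, 2, 0): 1 / 6, G(1, 1, 0): 1 / 3, G(0, 1, 0): 1 / 3},
            G(1, 0, 2): {G(1, 0, 0): 1 / 6, G(0, 0, 2): 1 / 6, G(1, 0, 1): 1 / 3, G(0, 0, 1): 1 / 3},
            G(1, 1, 1): {g: 1 / 6 for g in (G(1, 0, 0), G(0, 1, 0), G(0, 0, 1), G(1, 1, 0), G(1, 0, 1), G(0, 1, 1))},
        }
        female_w = {g: 1.0 for g in egg_tables}  # zero costs
        male_w = {G(1, 1, 0): 1.0, G(1, 0, 1): 0.0, G(1, 2, 0): 1.0, G(1, 0, 2): 0.0, G(1, 1, 1): 1.0}
        f0 = {G(2, 1, 0): 0.375, G(2, 0, 1): 0.3125, G(2, 2, 0): 0.0625, G(2, 0, 2): 0.125, G(2, 1, 1): 0.125}
        m0 = {G(1, 1, 0): 0.24, G(1, 0, 1): 0.18, G(1, 2, 0): 0.16, G(1, 0, 2): 0.14, G(1, 1, 1): 0.26}
        m0 = {g: p / sum(m0.values()) for g, p in m0.items()}

        def pool(freqs, weights, tables):
            out: dict = {}
            for g, p in freqs.items():
                if p * weights[g] == 0:
                    continue
                for gam, q in tables[g].items():
                    out[gam] = out.get(gam, 0.0) + p * weights[g] * q
            tot = sum(out.values())
            return {g: v / tot for g, v in out.items()}

        egg = pool(f0, female_w, egg_tables)
        sperm = pool(m0, male_w, sperm_tables)
        expected: dict = {}
        for e, pe in egg.items():
            for s, ps in sperm.items():
                z = e + s
                expected[z] = expected.get(z, 0.0) + pe * ps

        config = SimConfig(generations=1, params=FitnessParams(s=0.0, y=0.0))
        det = deterministic_run(config)
        got = {}
        f_tot = sum(p for g, p in expected.items() if g.n_x == 2)
        for g, p in det.female_freqs[1].items():
            got[g] = p * f_tot
        m_tot = sum(p for g, p in expected.items() if g.n_x == 1)
        for g, p in det.male_freqs[1].items():
            got[g] = p * m_tot
        assert set(got) == set(expected)
        for g in expected:
            assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_ys_share_strictly_decreases_with_equal_costs_and_sterile_ys(self):
        det = deterministic_run(
            SimConfig(generations=50, params=FitnessParams(s=0.3, y=0.3))
        )
        assert np.all(np.diff(det.ys_shares) < 0)

    def test_extinction_flagged_when_no_fit_females(self):
        # cost 1 kills every Y-bearing female: the egg pool empties immediately
        config = SimConfig(
            generations=10,
            params=FitnessParams(s=1.0, y=1.0, h=1.0, h_prime=1.0),
        )
        det = deterministic_run(config)
        assert det.extinct
        assert det.extinction_generation == 1


class TestTrajectorySerialization:
    def test_round_trip_lossless(self):
        config = SimConfig(generations=8, params=FitnessParams(s=0.2, y=0.6), seed=21)
        trajectory = run(config)
        long = trajectory.to_frame()
        summary = trajectory.summary_frame()
        back = type(trajectory).from_frames(long, summary)
        assert np.array_equal(back.ys_shares, trajectory.ys_shares, equal_nan=True)
        assert back.female_freqs == trajectory.female_freqs
        assert back.male_freqs == trajectory.male_freqs

    def test_round_trip_through_tsv_text(self, tmp_path):
        trajectory = run(SimConfig(generations=5, seed=4))
        p1, p2 = tmp_path / "long.tsv", tmp_path / "summary.tsv"
        trajectory.to_frame().to_csv(p1, sep="\t", index=False)
        trajectory.summary_frame().to_csv(p2, sep="\t", index=False)
        back = type(trajectory).from_frames(
            pd.read_csv(p1, sep="\t", float_precision="round_trip"),
            pd.read_csv(p2, sep="\t", float_precision="round_trip"),
        )
        assert np.array_equal(back.ys_shares, trajectory.ys_shares, equal_nan=True)
        assert back.female_freqs == trajectory.female_freqs


class TestSimConfig:
    def test_yaml_round_trip(self):
        config = SimConfig(
            population_size=40,
            generations=12,
            params=FitnessParams(s=0.1, y=0.7, m3=0.2),
            seed=99,
            replicates=4,
        )
        back = SimConfig.from_yaml(config.to_yaml())
        assert back == config

    def test_default_initial_distributions_normalized(self):
        config = SimConfig()
        assert sum(config.initial_female_dist.values()) == pytest.approx(1.0)
        assert sum(config.initial_male_dist.values()) == pytest.approx(1.0)

    def test_rejects_wrong_sex_in_initial_dist(self):
        with pytest.raises(ValueError):
            SimConfig(initial_female_dist={G(1, 1, 0): 1.0})
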