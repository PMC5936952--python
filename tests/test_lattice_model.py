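"""Cellular-automaton dynamics: tissue construction, circuits, stepping."""

import numpy as np
import pytest

from afloc import lattice_model as lm


class TestModelConfig:
    def test_defaults_are_the_working_parameters(self):
        cfg = lm.ModelConfig()
        assert (cfg.L, cfg.nu, cfg.tau, cfg.T_pace) == (200, 0.2, 50, 220)
        assert cfg.delta == 0.0 and cfg.dt_ms == 3.0

    @pytest.mark.parametrize(
        "kw",
        [
            {"L": 5},
            {"nu": 1.5},
            {"delta": -0.1},
            {"epsilon": 2.0},
            {"tau": 0},
            {"T_pace": 40},  # must exceed tau
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(lm.ConfigurationError):
            lm.ModelConfig(**kw)


class TestBuildTissue:
    def test_degenerate_bernoulli_limits(self):
        cfg = lm.ModelConfig(L=10, nu=1.0, delta=0.0)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        assert t.transverse_up.all() and t.transverse_up.size == 100
        assert not t.dysfunctional.any()

    def test_nu_zero_decouples_fibres(self):
        cfg = lm.ModelConfig(L=20, nu=0.0, T_pace=60)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        assert not t.transverse_up.any()
        state = lm.empty_state(cfg)
        state[7, 10] = lm.EXCITED
        for step_i in range(30):
            state = lm.step(t, state, step_i, pacing=False)
            rows = np.nonzero((state > 0).any(axis=1))[0]
            assert list(rows) in ([], [7])  # activity never leaves fibre 7

    def test_coupling_fraction_matches_nu(self):
        # mean over 10 seeds within 3 binomial SD of nu
        cfg = lm.ModelConfig(L=200, nu=0.2)
        fracs = [
            lm.build_tissue(cfg, np.random.default_rng(s)).transverse_up.mean()
            for s in range(10)
        ]
        sd = np.sqrt(0.2 * 0.8 / (10 * 200 * 200))
        assert abs(np.mean(fracs) - 0.2) < 3 * sd

    def test_deterministic_given_seed(self):
        cfg = lm.ModelConfig(seed=7)
        a, b = lm.build_tissue(cfg), lm.build_tissue(cfg)
        assert np.array_equal(a.transverse_up, b.transverse_up)


class TestInsertCircuit:
    def test_default_path_length_is_60(self, default_config):
        t = lm.build_tissue(default_config, np.random.default_rng(0))
        circ = lm.insert_circuit(t, (50, 30))
        assert circ.path_length == 60

    def test_footprint_two_rows_by_thirty_columns(self, default_config):
        t = lm.build_tissue(default_config, np.random.default_rng(0))
        circ = lm.insert_circuit(t, (50, 30))
        fp = circ.footprint(200)
        assert len(fp) == 60
        assert {r for r, _ in fp} == {50, 51}
        assert {c for _, c in fp} == set(range(30, 60))

    def test_perimeter_traced_on_lattice(self, default_config):
        # brute-force: the circulation path visits 60 distinct cells and
        # consecutive cells (cyclically) are lattice neighbours
        t = lm.build_tissue(default_config, np.random.default_rng(0))
        circ = lm.insert_circuit(t, (50, 30))
        path = lm.circuit_path(circ, 200)
        assert len(path) == len(set(path)) == 60
        for (r1, c1), (r2, c2) in zip(path, path[1:] + path[:1]):
            assert abs(r1 - r2) % 200 + abs(c1 - c2) == 1

    def test_idempotent(self, default_config):
        t = lm.build_tissue(default_config, np.random.default_rng(0))
        lm.insert_circuit(t, (50, 30))
        before = t.transverse_up.copy()
        lm.insert_circuit(t, (50, 30))
        assert np.array_equal(before, t.transverse_up)

    def test_anchor_too_close_to_boundary_rejected(self, default_config):
        t = lm.build_tissue(default_config, np.random.default_rng(0))
        with pytest.raises(lm.PlacementError):
            lm.insert_circuit(t, (50, 180))


class TestSeedingAndCirculation:
    def test_single_excited_cell_after_seeding(self, default_config):
        t = lm.build_tissue(default_config, np.random.default_rng(1))
        circ = lm.insert_circuit(t, (100, 85))
        state = lm.seed_circuit_excitation(t, circ)
        assert lm.count_active(state) == 1

    def test_circuit_reexcites_with_period_60(self, default_config):
        # brute-force oracle: the seeded head cell re-fires every 60 steps
        t = lm.build_tissue(default_config, np.random.default_rng(1))
        circ = lm.insert_circuit(t, (100, 85))
        state = lm.seed_circuit_excitation(t, circ)
        head = lm.circuit_path(circ, 200)[-1]
        fires = []
        for step_i in range(240):
            state = lm.step(t, state, step_i, pacing=False)
            if state[head] == lm.EXCITED:
                fires.append(step_i + 1)
        assert fires == [60, 120, 180, 240]

    def test_unsustainable_circuit_dies_in_uniform_tissue(self):
        # tau=70 > path length 60: the lap is blocked by refractory
        # tissue; in isotropic tissue the escaped wave sweeps once and
        # annihilates (heterogeneous tissue can form secondary circuits
        # around the carved obstacle, so nu=1 isolates the block)
        cfg = lm.ModelConfig(nu=1.0, tau=70, T_pace=220)
        t = lm.build_tissue(cfg, np.random.default_rng(1))
        circ = lm.insert_circuit(t, (100, 85))
        with pytest.warns(UserWarning):
            state = lm.seed_circuit_excitation(t, circ)
        head = lm.circuit_path(circ, 200)[-1]
        refires = 0
        for step_i in range(500):
            state = lm.step(t, state, step_i, pacing=False)
            refires += state[head] == lm.EXCITED
        assert refires == 0  # circulation never completes a lap
        assert lm.count_active(state) == 0  # transient wave annihilated

    def test_unsustainable_circuit_fails_initialization(self):
        cfg = lm.ModelConfig(nu=1.0, tau=70)
        t = lm.build_tissue(cfg, np.random.default_rng(1))
        with pytest.warns(UserWarning):
            circ = lm.insert_circuit(t, (100, 85))
            with pytest.raises(lm.InitializationError):
                lm.initialize_af(t, circ, rng=np.random.default_rng(1), max_steps=1200)


class TestStep:
    def test_excitation_spreads_to_coupled_neighbours(self):
        cfg = lm.ModelConfig(L=11, nu=1.0, T_pace=60)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        state = lm.empty_state(cfg)
        state[5, 5] = lm.EXCITED
        new = lm.step(t, state, 0, pacing=False)
        excited = {(r, c) for r, c in zip(*np.nonzero(new == lm.EXCITED))}
        assert excited == {(4, 5), (6, 5), (5, 4), (5, 6)}
        assert new[5, 5] == cfg.tau + 1  # now refractory

    def test_refractory_cell_not_reexcited(self):
        cfg = lm.ModelConfig(L=11, nu=1.0, T_pace=60)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        state = lm.empty_state(cfg)
        state[5, 5] = lm.EXCITED
        state[5, 6] = 10  # refractory
        new = lm.step(t, state, 0, pacing=False)
        assert new[5, 6] == 9  # counts down, not excited

    def test_dysfunctional_cell_with_certain_failure_never_excites(self):
        cfg = lm.ModelConfig(L=11, nu=1.0, delta=1.0, epsilon=1.0, T_pace=60)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        assert t.dysfunctional.all()
        state = lm.empty_state(cfg)
        state[5, 5] = lm.EXCITED
        new = lm.step(t, state, 0, np.random.default_rng(0), pacing=False)
        assert lm.count_active(new) == 0

    def test_refractory_cycle_length(self):
        # a cell excited at t cannot be excited again before t + tau + 1
        cfg = lm.ModelConfig(L=12, nu=1.0, tau=6, T_pace=40)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        state = lm.empty_state(cfg)
        state[3, 3] = lm.EXCITED
        clock = [state[3, 3]]
        for step_i in range(10):
            state = lm.step(t, state, step_i, pacing=False)
            clock.append(int(state[3, 3]))
        # excited -> tau+1, 6, 5, 4, 3, 2, then resting
        assert clock == [1, 7, 6, 5, 4, 3, 2, 0, 0, 0, 0]


class TestPacemakerAndFibrillation:
    def test_plane_wave_speed_one_column_per_step(self):
        cfg = lm.ModelConfig(nu=1.0)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        sim = lm.Simulation(t, rng=np.random.default_rng(0), pacing=True)
        for target in (1, 57, 133):
            while sim.t < target:
                sim.step()
            cols = np.nonzero((sim.state == lm.EXCITED).any(axis=0))[0]
            assert list(cols) == [target]
            assert lm.count_active(sim.state) == 200  # one full column

    def test_fibrillation_threshold_strict(self, default_config):
        state = lm.empty_state(default_config)
        state.ravel()[:220] = lm.EXCITED
        assert lm.count_active(state) == 220
        assert not lm.is_fibrillating(state, default_config)
        state.ravel()[220] = lm.EXCITED
        assert lm.is_fibrillating(state, default_config)

    def test_initialize_af_reaches_fibrillation(self, fibrillating_sim, default_config):
        sim, _, t_ready = fibrillating_sim
        assert t_ready < 2 * default_config.L + default_config.T_pace
        assert lm.is_fibrillating(sim.state, default_config)

    def test_ectopic_beats_skip_refractory(self):
        cfg = lm.ModelConfig(L=20, nu=1.0, tau=8, T_pace=100)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        lm.insert_ectopic(t, lm.EctopicSpec(position=(10, 10), period=5))
        sim = lm.Simulation(t, rng=np.random.default_rng(0), pacing=False)
        fires = []
        for _ in range(20):
            sim.step()
            if sim.state[10, 10] == lm.EXCITED:
                fires.append(sim.t)
        # fires at t=5; refractory until t=13, so the t=10 beat is
        # skipped and the next taken beat is t=15
        assert fires == [5, 15]


class TestSnapshots:
    def test_round_trip_preserves_replay(self, tmp_path):
        cfg = lm.ModelConfig(L=40, nu=0.3, T_pace=100)
        t = lm.build_tissue(cfg, np.random.default_rng(0))
        sim = lm.Simulation(t, rng=np.random.default_rng(0))
        sim.step(17)
        path = tmp_path / "snap.npz"
        lm.save_snapshot(path, sim)
        sim2 = lm.load_snapshot(path)
        assert sim2.t == 17 and sim2.config == cfg
        sim.step(5)
        sim2.step(5)
        assert np.array_equal(sim.state, sim2.state)


class TestSymmetries:
    def test_row_translation_equivariance(self, default_config):
        """Shifting tissue and circuit by k rows shifts the dynamics."""
        k = 37
        rng_a = np.random.default_rng(5)
        t_a = lm.build_tissue(default_config, rng_a)
        circ_a = lm.insert_circuit(t_a, (60, 40))
        state_a = lm.seed_circuit_excitation(t_a, circ_a)

        t_b = lm.Tissue(
            config=default_config,
            transverse_up=np.roll(t_a.transverse_up, k, axis=0),
            dysfunctional=np.roll(t_a.dysfunctional, k, axis=0),
        )
        circ_b = lm.CircuitSpec(anchor=((60 + k) % 200, 40))
        state_b = lm.seed_circuit_excitation(t_b, circ_b)
        assert np.array_equal(np.roll(state_a, k, axis=0), state_b)
        for step_i in range(120):
            state_a = lm.step(t_a, state_a, step_i, pacing=False)
            state_b = lm.step(t_b, state_b, step_i, pacing=False)
        assert np.array_equal(np.roll(state_a, k, axis=0), state_b)

    def test_no_reexcitation_within_refractory_period(self, default_config):
        """State-machine soundness on a random fibrillating tissue: no
        cell fires twice within tau + 1 steps."""
        rng = np.random.default_rng(3)
        t = lm.build_tissue(default_config, rng)
        circ = lm.insert_circuit(t, (20, 100))
        state = lm.seed_circuit_excitation(t, circ)
        tau = default_config.tau
        last_fire = np.full(state.shape, -(tau + 2))
        for step_i in range(250):
            state = lm.step(t, state, step_i, pacing=True)
            fired = state == lm.EXCITED
            gaps = (step_i + 1) - last_fire[fired]
            assert (gaps >= tau + 1).all()
            last_fire[fired] = step_i + 1
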