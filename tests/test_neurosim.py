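import numpy as np
import pytest
from scipy.signal import periodogram

from pursuitdecode import neurosim, protocol


class TestSourceSpace:
    def test_construction_contract(self):
        space = neurosim.make_source_space(500, seed=1)
        assert space.n_dipoles == 500
        assert set(np.unique(space.regions)) == set(neurosim.REGIONS)
        assert np.allclose(np.linalg.norm(space.orientations, axis=1), 1.0)

    def test_determinism(self):
        a = neurosim.make_source_space(200, seed=3)
        b = neurosim.make_source_space(200, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.regions, b.regions)

    def test_degenerate_all_irrelevant(self):
        fractions = {r: 0.0 for r in neurosim.REGIONS}
        fractions["irrelevant"] = 1.0
        space = neurosim.make_source_space(60, region_fractions=fractions, seed=0)
        assert np.all(space.regions == "irrelevant")

    def test_fractions_must_sum_to_one(self):
        bad = dict(neurosim.DEFAULT_REGION_FRACTIONS)
        bad["V1V2"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            neurosim.make_source_space(100, region_fractions=bad, seed=0)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            neurosim.make_source_space(10, seed=0)


class TestForwardModel:
    def test_inverse_square_distance_decay(self):
        # dipoles at the head centre: doubling the helmet radius doubles every
        # source-sensor distance, so every gain drops fourfold
        rng = np.random.default_rng(0)
        ori = rng.standard_normal((40, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        space = neurosim.SourceSpace(
            positions=np.zeros((40, 3)), orientations=ori,
            regions=np.array(["irrelevant"] * 40), seed=0,
        )
        near = neurosim.make_forward_model(space, 32, seed=2, helmet_radius=110.0)
        far = neurosim.make_forward_model(space, 32, seed=2, helmet_radius=220.0)
        assert np.allclose(np.linalg.norm(far.G, axis=0),
                           np.linalg.norm(near.G, axis=0) / 4.0)

    def test_determinism_and_extra_columns(self, small_space):
        a = neurosim.make_forward_model(small_space, 24, seed=7)
        b = neurosim.make_forward_model(small_space, 24, seed=7)
        assert np.array_equal(a.G, b.G)
        assert a.G_extra.shape == (24, 9)
        # heart columns (indices 6-8) must couple despite the distance
        assert np.all(np.linalg.norm(a.G_extra[:, 6:9], axis=0) > 0)

    def test_too_few_sensors(self, small_space):
        with pytest.raises(ValueError):
            neurosim.make_forward_model(small_space, 5, seed=0)


@pytest.fixture()
def schedule():
    return protocol.make_trial_schedule("overt_0.5", 1, seed=0)[0]


class TestSimulateCurrents:
    def test_gating_table(self, small_space, small_spec):
        """Populations whose function a task lacks carry no task-locked component."""
        for task in protocol.TASKS:
            traj = protocol.task_trajectory(task)
            sched = protocol.make_trial_schedule(task, 1, seed=0)[0]
            truth = neurosim.simulate_currents(
                small_space, small_spec, sched, traj, evoked_amp=0.0, noise_sd=0.0, seed=0
            )
            active_fns = protocol.task_functions(task)
            for pop, idx in small_spec.members.items():
                fn = small_spec.POP_FUNCTION[pop]
                others = [p for p, f in small_spec.POP_FUNCTION.items()
                          if f in active_fns and p != pop]
                only = np.setdiff1d(idx, np.concatenate(
                    [small_spec.members[p] for p in others]) if others else [])
                if fn not in active_fns and only.size:
                    assert np.all(truth.currents[only] == 0.0)

    def test_control_motor_population_silent(self, small_space, small_spec):
        traj = protocol.task_trajectory("control")
        sched = protocol.make_trial_schedule("control", 1, seed=1)[0]
        truth = neurosim.simulate_currents(
            small_space, small_spec, sched, traj, noise_sd=5.0, seed=3
        )
        motor_only = np.setdiff1d(
            small_spec.members["motor"],
            np.concatenate([small_spec.members["visual"], small_spec.members["attention"]]),
        )
        t = np.linspace(-0.4, 4.0, truth.currents.shape[1])
        pos = np.where(t >= 0, np.sin(2 * np.pi * 0.5 * t), 0.0)
        rs = [abs(np.corrcoef(truth.currents[i], pos)[0, 1]) for i in motor_only[:20]]
        assert np.mean(rs) < 0.1

    def test_precentral_overt_exceeds_covert(self, small_space, small_spec):
        """Motor gating makes precentral currents larger under overt pursuit."""
        means = {}
        for task in ("overt_0.5", "covert_0.5"):
            traj = protocol.task_trajectory(task)
            sched = protocol.make_trial_schedule(task, 1, seed=0)[0]
            truth = neurosim.simulate_currents(
                small_space, small_spec, sched, traj, noise_sd=5.0, seed=11
            )
            idx = small_space.region_indices("PreCC")
            means[task] = np.abs(truth.currents[idx]).mean()
        assert means["overt_0.5"] > means["covert_0.5"]

    def test_pure_evoked_superposition(self, small_space, small_spec, schedule):
        traj = protocol.task_trajectory("overt_0.5")
        zero_gains = {p: {t: 0.0 for t in protocol.TASKS} for p in small_spec.members}
        spec0 = neurosim.SubpopulationSpec(
            members=small_spec.members, gains=zero_gains, mix=small_spec.mix
        )
        truth = neurosim.simulate_currents(
            small_space, spec0, schedule, traj, evoked_amp=1.0, noise_sd=0.0, seed=0
        )
        vis = spec0.members["visual"]
        non_vis = np.setdiff1d(np.arange(small_space.n_dipoles), vis)
        assert np.all(truth.currents[non_vis] == 0.0)
        peak_times = np.argmax(np.abs(truth.currents[vis]), axis=1)
        t = np.linspace(-0.4, 4.0, truth.currents.shape[1])
        assert np.allclose(t[peak_times], 0.1, atol=1e-3)

    def test_excessive_lag_rejected(self, small_space, small_spec, schedule):
        bad = neurosim.SubpopulationSpec(
            members=small_spec.members, gains=small_spec.gains,
            mix=small_spec.mix, response_lag=5.0,
        )
        with pytest.raises(ValueError, match="lag"):
            neurosim.simulate_currents(
                small_space, bad, schedule, protocol.task_trajectory("overt_0.5")
            )


class TestArtifacts:
    def _run(self, task, seed=0, **kw):
        traj = protocol.task_trajectory(task)
        sched = protocol.make_trial_schedule(task, 1, seed=seed)[0]
        return neurosim.simulate_artifacts(sched, traj, task, seed=seed, **kw), traj

    def test_overt_eye_dipole_tracks_target(self):
        (extra, eye), traj = self._run("overt_0.5", seed=1)
        t = np.linspace(-0.4, 4.0, extra.shape[1])
        pos = np.where(t >= 0, traj.amplitude * np.sin(2 * np.pi * 0.5 * t), 0.0)
        assert np.corrcoef(extra[0], pos)[0, 1] > 0.9

    def test_covert_eye_dipole_uncorrelated(self):
        rs = []
        for seed in range(5):
            (extra, eye), traj = self._run("covert_0.5", seed=seed)
            t = np.linspace(-0.4, 4.0, extra.shape[1])
            pos = np.where(t >= 0, traj.amplitude * np.sin(2 * np.pi * 0.5 * t), 0.0)
            rs.append(abs(np.corrcoef(extra[0], pos)[0, 1]))
        assert np.mean(rs) < 0.2

    def test_cardiac_fundamental_dominates(self):
        (extra, _), _ = self._run("control", heart_rate=1.2, seed=3)
        f, pxx = periodogram(extra[6], fs=1000.0)
        peak = f[np.argmax(pxx[1:]) + 1]
        assert peak == pytest.approx(1.2, abs=0.15)

    def test_heart_rate_bounds(self):
        with pytest.raises(ValueError):
            self._run("control", heart_rate=5.0)


class TestSensorsAndRejection:
    def test_forward_linearity(self, small_space, small_forward):
        n = small_space.n_dipoles
        truth = neurosim.TrialTruth(
            currents=np.zeros((n, 50)), extra=np.zeros((9, 50)),
            eye_position=np.zeros(50), task="control",
        )
        assert np.all(neurosim.synthesize_sensors(small_forward, truth, 0.0) == 0.0)

        rng = np.random.default_rng(0)
        truth.currents = rng.standard_normal((n, 50))
        b1 = neurosim.synthesize_sensors(small_forward, truth, 0.0)
        truth.currents = 2 * truth.currents
        b2 = neurosim.synthesize_sensors(small_forward, truth, 0.0)
        assert np.allclose(b2, 2 * b1)

    def test_unit_current_reads_out_lead_field_column(self, small_space, small_forward):
        n = small_space.n_dipoles
        currents = np.zeros((n, 3))
        currents[17, 1] = 1.0
        truth = neurosim.TrialTruth(
            currents=currents, extra=np.zeros((9, 3)),
            eye_position=np.zeros(3), task="control",
        )
        B = neurosim.synthesize_sensors(small_forward, truth, 0.0)
        assert np.allclose(B[:, 1], small_forward.G[:, 17])
        assert np.all(B[:, [0, 2]] == 0)

    def test_dimension_mismatch(self, small_forward):
        truth = neurosim.TrialTruth(
            currents=np.zeros((3, 5)), extra=np.zeros((9, 5)),
            eye_position=np.zeros(5), task="control",
        )
        with pytest.raises(ValueError):
            neurosim.synthesize_sensors(small_forward, truth, 0.0)

    def test_rejection_spares_clean_trials(self):
        data = np.random.default_rng(0).uniform(-1, 1, size=(6, 4, 100))
        trials = neurosim.TrialSet(data=data, fs=1000.0, tasks=np.array(["control"] * 6))
        out = neurosim.reject_trials(trials, recordable_range=10.0)
        assert out.retention_rate == 1.0

    def test_injected_spike_rejects_exactly_that_trial(self):
        data = np.random.default_rng(0).uniform(-1, 1, size=(6, 4, 100))
        data[2, :, 50] = 10.0  # full-range spike on every channel
        trials = neurosim.TrialSet(data=data, fs=1000.0, tasks=np.array(["control"] * 6))
        out = neurosim.reject_trials(trials, recordable_range=10.0)
        assert out.retained.tolist() == [True, True, False, True, True, True]
        assert out.retained_data().shape[0] == 5

    def test_default_threshold_is_095(self):
        import inspect

        sig = inspect.signature(neurosim.reject_trials)
        assert sig.parameters["threshold_fraction"].default == 0.95

    def test_invalid_range(self):
        trials = neurosim.TrialSet(
            data=np.zeros((2, 2, 10)), fs=1000.0, tasks=np.array(["control"] * 2)
        )
        with pytest.raises(ValueError):
            neurosim.reject_trials(trials, recordable_range=0.0)


def test_full_task_simulation_deterministic(small_space, small_spec, small_forward):
    a = neurosim.simulate_task("covert_0.8", small_space, small_spec, small_forward,
                               n_trials=3, seed=9)
    b = neurosim.simulate_task("covert_0.8", small_space, small_spec, small_forward,
                               n_trials=3, seed=9)
    assert np.array_equal(a.trials.data, b.trials.data)
    assert a.trials.data.shape == (3, 32, 4401)
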