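import numpy as np
import pandas as pd
import pytest

from landcarbon import stsm
from landcarbon.pools import N_POOLS
from landcarbon.stsm import (DIST_CLEARCUT, DIST_FIRE, FOREST_BASE,
                             POST_FIRE_SHRUBLAND, LandscapeState,
                             TransitionDefinition, apply_transitions,
                             assign_fire_severity, bootstrap_future_rates,
                             postfire_recovery, schedule_reforestation,
                             schedule_transitions)


def make_state(shape=(10, 10), cls=FOREST_BASE, age=80):
    r, c = shape
    return LandscapeState(
        state_class=np.full(shape, cls, dtype=np.int32),
        age=np.full(shape, age, dtype=np.int32),
        time_since_transition=np.zeros(shape, dtype=np.int32),
        last_disturbance=np.zeros(shape, dtype=np.int8),
        pools=np.zeros(shape + (N_POOLS,)))


class TestScheduling:
    def test_probability_zero_no_transitions(self, rng):
        state = make_state()
        d = TransitionDefinition("t", None, mode="probability",
                                 probability=0.0)
        out = schedule_transitions(state, [d], None, rng)
        assert len(out["t"]) == 0

    def test_event_raster_exact_count(self, rng):
        state = make_state()
        mask = np.zeros((10, 10), dtype=bool)
        mask[:3, :4] = True
        d = TransitionDefinition("t", None, mode="events")
        out = schedule_transitions(state, [d], {"t": mask}, rng)
        assert len(out["t"]) == 12

    def test_probability_binomial_oracle(self, rng):
        state = make_state(shape=(1000, 1000))
        p = 0.05
        d = TransitionDefinition("t", None, mode="probability", probability=p)
        out = schedule_transitions(state, [d], None, rng)
        n = state.n_cells
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(len(out["t"]) / n - p) < 4 * sigma

    def test_target_area_truncated_with_warning(self, rng, caplog):
        state = make_state(shape=(3, 3))
        d = TransitionDefinition("t", None, mode="target_area")
        with caplog.at_level("WARNING", logger="landcarbon.stsm"):
            out = schedule_transitions(state, [d], {"t": 100}, rng)
        assert len(out["t"]) == 9
        assert "truncated" in caplog.text

    def test_protected_cells_excluded(self, rng):
        state = make_state()
        state.protected[:, :5] = True
        d = TransitionDefinition("t", None, mode="probability",
                                 probability=1.0)
        out = schedule_transitions(state, [d], None, rng)
        cols = out["t"] % 10
        assert (cols >= 5).all()

    def test_min_age_respected(self, rng):
        state = make_state(age=10)
        d = TransitionDefinition("t", None, mode="probability",
                                 probability=1.0, min_age=50)
        out = schedule_transitions(state, [d], None, rng)
        assert len(out["t"]) == 0

    def test_seed_determinism(self):
        state = make_state(shape=(50, 50))
        d = TransitionDefinition("t", None, mode="probability",
                                 probability=0.3)
        a = schedule_transitions(state, [d], None,
                                 np.random.default_rng(7))["t"]
        b = schedule_transitions(state, [d], None,
                                 np.random.default_rng(7))["t"]
        assert (a == b).all()


class TestFireSeverity:
    def test_all_high(self, rng):
        out = assign_fire_severity(np.arange(100), (1.0, 0.0, 0.0), rng)
        assert len(out["fire_high"]) == 100
        assert len(out["fire_medium"]) == 0

    def test_multinomial_oracle(self, rng):
        n = 300_000
        out = assign_fire_severity(np.arange(n),
                                   (1 / 3, 1 / 3, 1 / 3), rng)
        sigma = np.sqrt((1 / 3) * (2 / 3) / n)
        for key in out:
            assert abs(len(out[key]) / n - 1 / 3) < 4 * sigma

    def test_empty_mask(self, rng):
        out = assign_fire_severity(np.array([], dtype=int),
                                   (0.5, 0.3, 0.2), rng)
        assert all(len(v) == 0 for v in out.values())

    def test_missing_stratum_split_rejected(self, rng):
        with pytest.raises(KeyError):
            assign_fire_severity(np.arange(4), {0: (1, 0, 0)}, rng,
                                 stratum=np.array([0, 0, 1, 1]))


class TestApplyTransitions:
    def test_clearcut_resets_age_keeps_class(self):
        state = make_state(age=80)
        d = TransitionDefinition("clearcut", "clearcut", mode="events",
                                 age_reset=True,
                                 sets_last_disturbance=DIST_CLEARCUT)
        new, work = apply_transitions(state, {"clearcut": np.array([0])}, [d])
        assert new.state_class.ravel()[0] == FOREST_BASE
        assert new.age.ravel()[0] == 0
        assert new.last_disturbance.ravel()[0] == DIST_CLEARCUT
        assert work == [("clearcut", pytest.approx(np.array([0])))]

    def test_high_severity_fire_converts_and_remembers(self):
        state = make_state()
        d = TransitionDefinition("fire_high", "fire_high",
                                 destination=POST_FIRE_SHRUBLAND,
                                 mode="events", age_reset=True,
                                 sets_last_disturbance=DIST_FIRE)
        new, _ = apply_transitions(state, {"fire_high": np.array([3])}, [d])
        assert new.state_class.ravel()[3] == POST_FIRE_SHRUBLAND
        assert new.species_memory.ravel()[3] == FOREST_BASE
        assert new.age.ravel()[3] == 0

    def test_selection_harvest_keeps_age(self):
        state = make_state(age=80)
        d = TransitionDefinition("sel", "selection_harvest", mode="events")
        new, _ = apply_transitions(state, {"sel": np.array([1])}, [d])
        assert new.age.ravel()[1] == 80

    def test_conversion_freezes_cell(self):
        state = make_state()
        d = TransitionDefinition("urb", "urbanization",
                                 destination=stsm.DEVELOPED_LOW,
                                 mode="events")
        new, _ = apply_transitions(state, {"urb": np.array([5])}, [d])
        assert new.state_class.ravel()[5] == stsm.DEVELOPED_LOW
        assert new.frozen.ravel()[5]

    def test_class_conservation(self, rng):
        state = make_state(shape=(20, 20))
        d = TransitionDefinition("fire_high", "fire_high",
                                 destination=POST_FIRE_SHRUBLAND,
                                 mode="events", age_reset=True)
        idx = rng.choice(400, size=50, replace=False)
        new, _ = apply_transitions(state, {"fire_high": idx}, [d])
        assert new.state_class.size == 400
        assert (np.isin(new.state_class,
                        [FOREST_BASE, POST_FIRE_SHRUBLAND])).all()

    def test_first_assignment_wins(self):
        state = make_state()
        d1 = TransitionDefinition("a", "clearcut", mode="events",
                                  age_reset=True)
        d2 = TransitionDefinition("b", "selection_harvest", mode="events")
        new, work = apply_transitions(
            state, {"a": np.array([0]), "b": np.array([0])}, [d1, d2])
        assert [w[0] for w in work] == ["clearcut"]


class TestPostfireRecovery:
    def _shrub_state(self, n):
        side = int(np.sqrt(n))
        state = make_state(shape=(side, side), cls=POST_FIRE_SHRUBLAND)
        state.species_memory[:] = FOREST_BASE + 2
        return state

    def test_zero_probability(self, rng):
        state = self._shrub_state(10_000)
        new, idx = postfire_recovery(state, rng, probability=0.0)
        assert len(idx) == 0

    def test_binomial_oracle_printed_rate(self, rng):
        n = 1_000_000
        state = self._shrub_state(n)
        new, idx = postfire_recovery(state, rng)   # default 0.064
        p = stsm.POSTFIRE_RECOVERY_PROBABILITY
        sigma = np.sqrt(p * (1 - p) / state.n_cells)
        assert abs(len(idx) / state.n_cells - p) < 4 * sigma
        assert (new.state_class.ravel()[idx] == FOREST_BASE + 2).all()
        assert (new.age.ravel()[idx] == 0).all()

    def test_mean_residence_time_geometric(self):
        # expected residence ~ 1/p years
        p = stsm.POSTFIRE_RECOVERY_PROBABILITY
        rng = np.random.default_rng(5)
        state = self._shrub_state(40_000)
        remaining = np.ones(state.n_cells, dtype=bool)
        total_years = 0.0
        for _ in range(200):
            total_years += remaining.sum()
            _, idx = postfire_recovery(state, rng, probability=p)
            keep = np.ones(state.n_cells, dtype=bool)
            keep[idx] = False
            sc = state.state_class.ravel()
            sc[idx] = stsm.GRASSLAND   # leave the shrub class
            remaining &= keep
        mean_residence = total_years / state.n_cells
        assert mean_residence == pytest.approx(1 / p, rel=0.05)


class TestBootstrap:
    def test_single_year_history_constant(self, rng):
        hist = pd.DataFrame({"year": [2001], "transition": ["fire"],
                             "value": [42.0]})
        out = bootstrap_future_rates(hist, [2030, 2031, 2032], rng)
        assert (out["value"] == 42.0).all()

    def test_support_containment(self, rng):
        hist = pd.DataFrame({"year": range(2001, 2011),
                             "transition": "fire",
                             "value": np.arange(10.0)})
        out = bootstrap_future_rates(hist, list(range(2030, 2060)), rng)
        assert set(out["value"]).issubset(set(hist["value"]))

    def test_mean_within_4_sigma(self):
        rng = np.random.default_rng(11)
        values = np.arange(20.0)
        hist = pd.DataFrame({"year": range(2000, 2020),
                             "transition": "fire", "value": values})
        out = bootstrap_future_rates(hist, list(range(10_000)), rng)
        sigma = values.std() / np.sqrt(len(out))
        assert abs(out["value"].mean() - values.mean()) < 4 * sigma

    def test_empty_history_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_future_rates(pd.DataFrame(columns=["year", "value"]),
                                   [2030], rng)


class TestReforestation:
    def test_zero_area(self, rng):
        state = make_state(cls=stsm.GRASSLAND)
        plan = schedule_reforestation(state, np.ones((10, 10), bool),
                                      2030, 2050, 0, rng)
        assert sum(len(v) for v in plan.values()) == 0

    def test_counting_and_even_spread(self, rng):
        state = make_state(shape=(40, 40), cls=stsm.GRASSLAND)
        plan = schedule_reforestation(state, np.ones((40, 40), bool),
                                      2030, 2039, 100, rng)
        counts = [len(v) for v in plan.values()]
        assert sum(counts) == 100
        assert max(counts) - min(counts) <= 1

    def test_containment_and_truncation(self, rng, caplog):
        state = make_state(cls=stsm.GRASSLAND)
        mask = np.zeros((10, 10), bool)
        mask[0, :5] = True
        with caplog.at_level("WARNING", logger="landcarbon.stsm"):
            plan = schedule_reforestation(state, mask, 2030, 2031, 50, rng)
        chosen = np.concatenate(list(plan.values()))
        assert len(chosen) == 5
        assert set(chosen).issubset(set(np.nonzero(mask.ravel())[0]))
        assert "truncated" in caplog.text


class TestInvariants:
    def test_severity_split_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TransitionDefinition("x", None, severity_split=(0.5, 0.2, 0.2))

    def test_default_defs_well_formed(self, matrices):
        defs = stsm.default_transition_defs()
        names = [d.name for d in defs]
        assert len(names) == len(set(names))
        for d in defs:
            if d.transition_type is not None:
                assert d.transition_type in matrices.types
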