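import numpy as np
import pytest

from hrdcc import (
    StudyConfig,
    generate_animal_profiles,
    generate_biomarkers,
    generate_schedule,
    generate_trajectories,
    simulate_study,
    synthesize_events,
)
from hrdcc.simulate import (
    Episode,
    TruePopulationState,
    draw_episode_windows,
    inject_episodes,
)


def _pure_state(pop="cd4_t_cells", viability=1.0):
    lymph = {"nk_cells": 0.0, "gd_t_cells": 0.0, "cd4_t_cells": 0.0,
             "cd8_t_cells": 0.0, "b_cells": 0.0, "dn_lymphocytes": 0.0}
    lymph[pop] = 1.0
    return TruePopulationState(
        "cowX", 120, "blood",
        {"granulocytes": 0.0, "monocytes_macrophages": 0.0, "lymphocytes": 1.0},
        {"eosinophils": 0.0, "immature_granulocytes": 0.0, "neutrophils": 1.0},
        {"cM": 1.0, "intM": 0.0, "ncM": 0.0},
        lymph, {"cd45neg_other": 0.0}, viability)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSchedule:
    def test_visit_count_without_dropout(self):
        days = generate_schedule(300, 100, 0.0, _rng())
        assert len(days) == 57  # day 1 + 28 twice-weekly + 28 weekly
        assert np.all(np.diff(days) > 0)

    def test_density_twice_weekly_then_weekly(self):
        days = generate_schedule(300, 100, 0.0, _rng())
        early = [d for d in days if d <= 100]
        late = [d for d in days if d > 100]
        assert len(early) / (100 / 7) == pytest.approx(2.0, abs=0.15)
        assert len(late) / (200 / 7) == pytest.approx(1.0, abs=0.05)

    def test_full_dropout_empties_schedule(self):
        assert len(generate_schedule(300, 100, 1.0, _rng())) == 0

    def test_short_lactation_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(90, 100, 0.0, _rng())

    def test_default_dropout_gives_about_55_visits(self):
        config = StudyConfig()
        rng = _rng(4)
        counts = [len(generate_schedule(int(rng.integers(291, 306)),
                                        config.twice_weekly_until,
                                        config.dropout_prob, rng))
                  for _ in range(300)]
        assert np.mean(counts) == pytest.approx(55.0, abs=1.5)


class TestProfiles:
    def test_named_cows_carry_printed_cd4_baselines(self):
        profiles = {p.animal_id: p for p in
                    generate_animal_profiles(StudyConfig(), _rng())}
        assert profiles["cow1"].blood_cd4_mean == pytest.approx(0.347)
        assert profiles["cow1"].blood_cd4_visit_sd == pytest.approx(0.029)
        assert profiles["cow6"].blood_cd4_mean == pytest.approx(0.197)
        assert profiles["cow6"].blood_cd4_visit_sd == pytest.approx(0.026)

    def test_zero_animal_effect_means_zero_offsets(self):
        config = StudyConfig(animal_effect_sd=0.0)
        for p in generate_animal_profiles(config, _rng()):
            assert all(v == 0.0 for v in p.offsets.values())

    def test_negative_spread_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(animal_effect_sd=-0.1)


class TestTrajectories:
    def test_zero_volatility_is_deterministic_mean_curve(self):
        config = StudyConfig(n_animals=1)
        profiles = generate_animal_profiles(config, _rng(1))
        sched = generate_schedule(300, 100, 0.0, _rng())
        a = generate_trajectories(profiles[0], sched, "milk", config.trajectory,
                                  _rng(1), volatility=0.0)
        b = generate_trajectories(profiles[0], sched, "milk", config.trajectory,
                                  _rng(99), volatility=0.0)
        for sa, sb in zip(a, b):
            assert sa.lymph_subsets == sb.lymph_subsets
            assert sa.main == sb.main

    def test_milk_gdt_declines_over_lactation(self):
        config = StudyConfig(n_animals=1)
        early, late = [], []
        for seed in range(20):
            study = simulate_study(config, seed=seed)
            for st in study.states.values():
                if st.matrix != "milk":
                    continue
                frac = st.lymph_subsets["gd_t_cells"]
                (early if st.dim <= 50 else late).append(
                    frac if st.dim <= 50 or st.dim >= 251 else None)
        early = [x for x in early if x is not None]
        late = [x for x in late if x is not None]
        assert np.mean(early) > np.mean(late)

    def test_milk_cd4_rises_and_noise_levels_out(self):
        config = StudyConfig(n_animals=1)
        study = simulate_study(config, seed=0, volatility=0.0)
        milk = sorted((s for s in study.states.values() if s.matrix == "milk"),
                      key=lambda s: s.dim)
        cd4 = [s.lymph_subsets["cd4_t_cells"] for s in milk]
        assert cd4[-1] > cd4[0]
        # noisy runs: early granulocyte spread exceeds late spread
        spreads = {"early": [], "late": []}
        for seed in range(15):
            st = simulate_study(config, seed=seed)
            for s in st.states.values():
                if s.matrix == "milk":
                    key = "early" if s.dim <= 100 else ("late" if s.dim > 200 else None)
                    if key:
                        spreads[key].append(s.main["granulocytes"])
        assert np.std(spreads["early"]) > np.std(spreads["late"])

    def test_blood_cd4_visit_spread_matches_configured(self):
        config = StudyConfig(n_animals=1)
        profiles = generate_animal_profiles(config, _rng(1))
        sched = generate_schedule(300, 100, 0.0, _rng())
        states = generate_trajectories(profiles[0], sched, "blood",
                                       config.trajectory, _rng(7))
        cd4 = [s.lymph_subsets["cd4_t_cells"] for s in states]
        observed = np.std(cd4, ddof=1)
        assert abs(observed - profiles[0].blood_cd4_visit_sd) \
            < 0.30 * profiles[0].blood_cd4_visit_sd

    def test_terminal_fractions_sum_to_one(self):
        study = simulate_study(StudyConfig(n_animals=2), seed=3)
        for st in study.states.values():
            assert sum(st.terminal_fractions().values()) == pytest.approx(1.0, abs=1e-9)


class TestEpisodes:
    def test_zero_rate_means_no_episodes(self):
        eps = draw_episode_windows("c", 300, 0.0, (10, 22), _rng())
        assert eps == []

    def test_overlapping_windows_merge(self):
        eps = draw_episode_windows("c", 300, 0.0, (10, 22), _rng(),
                                   forced=[(50, 70), (60, 90), (200, 210)])
        assert [(e.start, e.end) for e in eps] == [(50, 90), (200, 210)]

    def test_forced_episode_elevates_haptoglobin_only_inside(self):
        config = StudyConfig(n_animals=1)
        study = simulate_study(config, seed=2,
                               forced_episodes={"cow1": [(75, 96)]})
        hp = study.biomarkers[study.biomarkers.analyte == "haptoglobin"]
        inside = hp[(hp.dim >= 75) & (hp.dim <= 96)]
        outside = hp[(hp.dim > 110)]
        assert (inside.value > config.haptoglobin_threshold).all()
        assert inside.value.min() > outside.value.max()

    def test_gdt_shifts_down_and_immature_untouched(self):
        config = StudyConfig(n_animals=1)
        base = simulate_study(config, seed=6)
        shifted = simulate_study(config, seed=6,
                                 forced_episodes={"cow1": [(120, 160)]})
        for sid, st in shifted.states.items():
            if st.matrix != "milk" or not (120 <= st.dim <= 160):
                continue
            ref = base.states[sid]
            assert st.lymph_subsets["gd_t_cells"] < ref.lymph_subsets["gd_t_cells"]
            assert st.lymph_subsets["cd4_t_cells"] > ref.lymph_subsets["cd4_t_cells"]
            assert st.gran_subsets["immature_granulocytes"] == pytest.approx(
                ref.gran_subsets["immature_granulocytes"])

    def test_zero_shift_leaves_states_unchanged(self):
        config = StudyConfig(n_animals=1)
        profiles = generate_animal_profiles(config, _rng(1))
        sched = generate_schedule(300, 100, 0.0, _rng())
        states = generate_trajectories(profiles[0], sched, "milk",
                                       config.trajectory, _rng(3))
        before = [dict(s.lymph_subsets) for s in states]
        inject_episodes(states, [Episode("cow1", 75, 96)], 0.0, 0.0)
        for st, prev in zip(states, before):
            assert st.lymph_subsets == pytest.approx(prev)


class TestBiomarkers:
    def test_negative_energy_balance_markers_decay(self):
        config = StudyConfig(n_animals=1)
        means_early, means_mid = [], []
        for seed in range(20):
            study = simulate_study(config, seed=seed)
            nefa = study.biomarkers[study.biomarkers.analyte == "NEFA"]
            means_early.append(nefa[nefa.dim <= 50].value.mean())
            means_mid.append(nefa[(nefa.dim > 100) & (nefa.dim <= 150)].value.mean())
        assert np.mean(means_early) > np.mean(means_mid)

    def test_flat_series_at_infinite_decay(self):
        config = StudyConfig(n_animals=1)
        for bp in config.biomarkers.values():
            bp.decay_tau = 1e-9
            bp.noise_cv = 0.0
        profiles = generate_animal_profiles(config, _rng(1))
        bio = generate_biomarkers(profiles[0], np.arange(10, 100, 7), [],
                                  config, _rng())
        for analyte, bp in config.biomarkers.items():
            vals = bio[bio.analyte == analyte].value
            assert vals.to_numpy() == pytest.approx(bp.baseline, rel=1e-6)

    def test_negative_baseline_rejected(self):
        config = StudyConfig()
        with pytest.raises(ValueError):
            config.biomarkers["NEFA"].baseline = -1.0
            StudyConfig(biomarkers=config.biomarkers)

    def test_healthy_lactation_stays_below_episode_threshold(self):
        config = StudyConfig(n_animals=1)
        config.episodes.rate_per_lactation = 0.0
        study = simulate_study(config, seed=8)
        hp = study.biomarkers[(study.biomarkers.analyte == "haptoglobin")
                              & (study.biomarkers.dim > 20)]
        assert (hp.value <= config.haptoglobin_threshold).all()


class TestEventSynthesis:
    def test_single_population_with_no_nuisance(self):
        config = StudyConfig(n_animals=1, debris_fraction=0.0,
                             doublet_fraction=0.0)
        em = synthesize_events(_pure_state(), config, _rng(), n_events=5_000)
        assert set(em.truth_labels) == {"cd4_t_cells"}

    def test_label_counts_follow_binomial_bound(self, small_study):
        sid = small_study.samples[small_study.samples.matrix == "blood"
                                  ].sample_id.iloc[0]
        st = small_study.states[sid]
        config = StudyConfig(n_animals=1)
        em = synthesize_events(st, config, _rng(12), n_events=100_000)
        fractions = st.terminal_fractions()
        live_scale = (1 - config.debris_fraction - config.doublet_fraction) \
            * st.viability
        for pop, frac in fractions.items():
            expected = frac * live_scale
            observed = np.mean(em.truth_labels == pop)
            bound = 4 * np.sqrt(expected * (1 - expected) / em.n_events)
            assert abs(observed - expected) <= max(bound, 1e-4)

    def test_reproducible_given_seed(self, small_study):
        a = small_study.events_for(small_study.samples.sample_id.iloc[0])
        b = small_study.events_for(small_study.samples.sample_id.iloc[0])
        assert (a.data.to_numpy() == b.data.to_numpy()).all()
        assert (a.truth_labels == b.truth_labels).all()

    def test_milk_panck_missing_before_dim_50(self, small_study):
        early = small_study.samples[(small_study.samples.matrix == "milk")
                                    & (small_study.samples.dim < 50)].iloc[0]
        late = small_study.samples[(small_study.samples.matrix == "milk")
                                   & (small_study.samples.dim >= 50)].iloc[0]
        assert "panCK" not in small_study.events_for(early.sample_id).channels
        assert "panCK" in small_study.events_for(late.sample_id).channels

    def test_event_proportion_calibration(self, small_study):
        """Across many samples, empirical label proportions track the
        latent fractions with mean absolute error < 0.5 points."""
        config = small_study.config
        errs = []
        for sid in small_study.samples.sample_id.iloc[:100]:
            st = small_study.states[sid]
            em = small_study.events_for(sid, n_events=10_000)
            live_scale = (1 - config.debris_fraction - config.doublet_fraction) \
                * st.viability
            for pop, frac in st.terminal_fractions().items():
                observed = np.mean(em.truth_labels == pop)
                errs.append(abs(observed - frac * live_scale))
        assert np.mean(errs) < 0.005
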