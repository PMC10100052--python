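"""Synthetic generators: determinism, distributional contracts, sampler validity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from settlemate import (
    GridRaster,
    SimulationConfig,
    choice_probabilities,
    gen_choice_events,
    gen_landscape,
    gen_male_pattern,
    gen_nests,
    gen_playbacks,
    make_scene,
)
from settlemate.ppm import PointPattern
from settlemate.synth import resolve_beta0, sample_points_from_surface


class TestDeterminism:
    def test_same_seed_same_landscape(self):
        cfg = SimulationConfig(seed=11)
        a = gen_landscape(cfg)
        b = gen_landscape(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_same_seed_same_scene(self, small_config):
        s1 = make_scene(small_config)
        s2 = make_scene(small_config)
        pd.testing.assert_frame_equal(s1.nests, s2.nests)
        np.testing.assert_array_equal(s1.males.x, s2.males.x)
        assert [e.chosen for e in s1.events] == [e.chosen for e in s2.events]

    def test_different_seeds_differ(self):
        a = gen_landscape(SimulationConfig(seed=1))
        b = gen_landscape(SimulationConfig(seed=2))
        assert not np.array_equal(a.values, b.values)


class TestLandscape:
    def test_no_hotspots_gives_constant_surface(self):
        r = gen_landscape(SimulationConfig(seed=0, hotspot_count=0))
        assert np.all(r.values == r.values.flat[0])
        assert np.all(r.values > 0)

    def test_widening_hotspots_flattens_the_surface(self):
        # coefficient of variation -> 0 as the hotspot scale grows
        cvs = []
        for scale in (50.0, 500.0, 5000.0):
            r = gen_landscape(SimulationConfig(seed=3, hotspot_scale=scale))
            cvs.append(r.values.std() / r.values.mean())
        assert cvs[0] > cvs[1] > cvs[2]
        assert cvs[2] < 0.05

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, window=(0.0, 100.0))


class TestNests:
    def test_zero_rate_gives_empty_table(self):
        t = gen_nests(SimulationConfig(seed=4, nests_per_year=0.0))
        assert len(t) == 0

    def test_two_level_surface_sampling_proportions(self):
        # surface 1 on the left half, 3 on the right: expect 75% right
        vals = np.ones((10, 10))
        vals[:, 5:] = 3.0
        surf = GridRaster(0, 0, 10, vals)
        rng = np.random.default_rng(5)
        pts = sample_points_from_surface(surf, 10_000, rng)
        frac = np.mean(pts[:, 0] >= 50.0)
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_all_nests_inside_window(self):
        cfg = SimulationConfig(seed=6)
        t = gen_nests(cfg)
        assert cfg.win.contains(t["x"].to_numpy(), t["y"].to_numpy()).all()

    def test_yearly_counts_are_poisson_distributed(self):
        cfg = SimulationConfig(seed=7, n_years=200, nests_per_year=6.0)
        t = gen_nests(cfg)
        counts = t.groupby("year").size().reindex(
            range(cfg.first_year, cfg.first_year + 200), fill_value=0
        )
        # index of dispersion ~ chi2(n-1)/(n-1) under Poisson
        disp = counts.var(ddof=1) / counts.mean()
        n = len(counts)
        lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1) / (n - 1)
        assert lo < disp < hi


class TestMalePattern:
    @pytest.fixture
    def flat_covs(self):
        vals = np.ones((50, 50))
        return GridRaster(0, 0, 10, vals * 2.0), GridRaster(0, 0, 10, vals * 0.5)

    def test_homogeneous_mean_count_matches_poisson_mean(self, flat_covs):
        # beta_hab = beta_prox = 0, beta0 = ln(50/|W|) -> E[N] = 50
        hab, prox = flat_covs
        cfg = SimulationConfig(
            seed=8, window=(500.0, 500.0), true_beta=(np.log(50 / 250_000.0), 0.0, 0.0)
        )
        counts = [
            gen_male_pattern(cfg, hab, prox, rng=np.random.default_rng([8, i])).n
            for i in range(500)
        ]
        assert np.mean(counts) == pytest.approx(50.0, abs=1.0)
        # dispersion of counts consistent with Poisson at the 1% level
        disp = np.var(counts, ddof=1) / np.mean(counts)
        lo, hi = stats.chi2.ppf([0.005, 0.995], 499) / 499
        assert lo < disp < hi

    def test_attraction_pulls_males_toward_playbacks(self, small_config):
        scene = make_scene(small_config, with_choices=False)
        mids = scene.playbacks[["ax", "ay"]].to_numpy()
        mids = (mids + scene.playbacks[["bx", "by"]].to_numpy()) / 2

        def mean_nearest(cfg_beta, key):
            cfg = SimulationConfig(
                seed=small_config.seed,
                window=small_config.window,
                true_beta=cfg_beta,
                expected_males=60.0,
            )
            dists = []
            for i in range(20):
                pat = gen_male_pattern(
                    cfg, scene.hab, scene.prox_all, rng=np.random.default_rng([key, i])
                )
                if pat.n:
                    xy = np.column_stack([pat.x, pat.y])
                    d = np.linalg.norm(xy[:, None] - mids[None], axis=2).min(axis=1)
                    dists.append(d.mean())
            return np.mean(dists)

        attracted = mean_nearest((None, 0.0, 4.0), 101)
        ignored = mean_nearest((None, 0.0, 0.0), 102)
        assert attracted < ignored

    def test_all_points_inside_window(self, small_scene):
        win = small_scene.config.win
        assert win.contains(small_scene.males.x, small_scene.males.y).all()

    def test_expected_count_calibration(self, flat_covs):
        hab, prox = flat_covs
        cfg = SimulationConfig(seed=9, window=(500.0, 500.0), expected_males=25.0)
        b0, bh, bp = resolve_beta0(cfg, hab, prox)
        total = (10.0**2) * np.exp(b0 + bh * hab.values + bp * prox.values).sum()
        assert total == pytest.approx(25.0, rel=1e-9)

    def test_misaligned_rasters_rejected(self, flat_covs):
        hab, _ = flat_covs
        prox = GridRaster(0, 0, 10, np.ones((40, 50)))
        with pytest.raises(ValueError):
            gen_male_pattern(SimulationConfig(seed=0), hab, prox)


class TestChoiceEvents:
    @pytest.fixture
    def fixed_scene(self):
        """Five males on a flat surface with distinct spacings."""
        cfg = SimulationConfig(seed=10, window=(500.0, 500.0), presence_prob=1.0)
        hab = GridRaster(0, 0, 10, np.ones((50, 50)) * 3.0)
        males = PointPattern(
            "S1", 2020, cfg.win,
            [100.0, 150.0, 300.0, 420.0, 120.0],
            [100.0, 140.0, 300.0, 100.0, 380.0],
            [f"M{i}" for i in range(5)],
        )
        return cfg, hab, males

    def test_null_exponents_choose_uniformly(self, fixed_scene):
        cfg, hab, males = fixed_scene
        cfg = SimulationConfig(
            seed=10, window=(500.0, 500.0), presence_prob=1.0, true_alpha=(0.0, 0.0)
        )
        events = gen_choice_events(cfg, males, hab, n_events=10_000)
        counts = np.bincount([e.chosen for e in events], minlength=5)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_single_candidate_always_chosen(self):
        cfg = SimulationConfig(seed=11, window=(500.0, 500.0))
        hab = GridRaster(0, 0, 10, np.ones((50, 50)))
        males = PointPattern("S1", 2020, cfg.win, [250.0], [250.0], ["M0"])
        events = gen_choice_events(cfg, males, hab, n_events=50)
        assert all(e.chosen == 0 and e.n_candidates == 1 for e in events)

    def test_extreme_habitat_exponent_is_a_softmax_limit(self, fixed_scene):
        cfg, _, males = fixed_scene
        vals = np.ones((50, 50))
        vals[:, 25:] = 2.0  # males 2 and 3 sit in the high half (x >= 250)
        hab = GridRaster(0, 0, 10, vals)
        cfg = SimulationConfig(
            seed=12, window=(500.0, 500.0), presence_prob=1.0, true_alpha=(30.0, 0.0)
        )
        events = gen_choice_events(cfg, males, hab, n_events=1000)
        frac_high = np.mean([e.chosen in (2, 3) for e in events])
        assert frac_high > 0.99

    def test_sampler_frequencies_match_choice_probabilities(self, fixed_scene):
        cfg, hab, males = fixed_scene
        events = gen_choice_events(cfg, males, hab, n_events=20_000)
        p_model = choice_probabilities(events[0], *cfg.true_alpha)
        counts = np.bincount([e.chosen for e in events], minlength=5)
        assert stats.chisquare(counts, f_exp=p_model * len(events)).pvalue > 0.01

    def test_no_males_is_an_error(self):
        cfg = SimulationConfig(seed=13)
        hab = GridRaster(0, 0, 10, np.ones((100, 100)))
        males = PointPattern("S1", 2020, cfg.win, [], [])
        with pytest.raises(ValueError):
            gen_choice_events(cfg, males, hab)


def test_playback_speakers_flank_midpoints():
    cfg = SimulationConfig(seed=14)
    pb = gen_playbacks(cfg)
    np.testing.assert_allclose(pb["bx"] - pb["ax"], cfg.speaker_spacing)
    assert set(pb["song_rate_class"]) == {"high", "low"}


def test_scene_covariates_share_one_grid(small_scene):
    assert small_scene.hab.aligned_with(small_scene.prox_all)
    if small_scene.prox_low is not None:
        assert small_scene.hab.aligned_with(small_scene.prox_low)
    assert np.all(small_scene.hab.values > 0)
    assert small_scene.prox_all.values.max() <= 1.0
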