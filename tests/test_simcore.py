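"""Interaction kernel, edge correction, fitness and the stepping engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rangesim.landscape import build_grid, make_schedule
from rangesim.simcore import (
    Individual,
    SimParams,
    choose_mate,
    clipped_interaction_area,
    competition_load,
    disperse,
    fitness,
    interaction_strength,
    kernel_max,
    reproduce,
    run,
)

RECT = (0.0, 0.0, 20.0, 20.0)


class TestKernel:
    def test_kernel_max_closed_form(self):
        assert kernel_max(1.0) == pytest.approx(1 / (2 * math.pi))
        assert kernel_max(0.5) == pytest.approx(1 / (2 * math.pi * 0.25))

    @given(st.floats(min_value=0.05, max_value=10.0))
    def test_normalization_identity(self, sigma):
        assert kernel_max(sigma) * 2 * math.pi * sigma**2 == pytest.approx(1.0)

    def test_kernel_values(self):
        sigma = 0.7
        m = kernel_max(sigma)
        assert interaction_strength(0.0, sigma) == pytest.approx(m)
        assert interaction_strength(3 * sigma, sigma) == 0.0
        assert interaction_strength(4 * sigma, sigma) == 0.0
        assert interaction_strength(sigma, sigma) == pytest.approx(m * math.exp(-0.5))

    def test_kernel_monotone_decreasing_to_cutoff(self):
        sigma = 0.5
        d = np.linspace(0, 3 * sigma - 1e-9, 200)
        v = interaction_strength(d, sigma)
        assert np.all(np.diff(v) < 0)
        assert np.all(v >= 0)

    def test_kernel_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            kernel_max(0.0)
        with pytest.raises(ValueError):
            interaction_strength(-0.1, 1.0)


class TestClippedArea:
    def test_symmetry_cases(self):
        R = 1.5
        full = math.pi * R * R
        assert clipped_interaction_area(10, 10, R, RECT) == pytest.approx(full)
        assert clipped_interaction_area(0, 0, R, RECT) == pytest.approx(full / 4)
        assert clipped_interaction_area(0, 10, R, RECT) == pytest.approx(full / 2)
        assert clipped_interaction_area(10, 20, R, RECT) == pytest.approx(full / 2)

    def test_monte_carlo_oracle(self, rng):
        # 20 random configurations vs disc-point rejection sampling, 0.5%
        R = 1.5
        n = 400_000
        for _ in range(20):
            x = rng.uniform(0, 20)
            y = rng.uniform(0, 20)
            theta = rng.uniform(0, 2 * math.pi, n)
            r = R * np.sqrt(rng.uniform(0, 1, n))
            px, py = x + r * np.cos(theta), y + r * np.sin(theta)
            inside = (px >= 0) & (px <= 20) & (py >= 0) & (py <= 20)
            mc = math.pi * R * R * inside.mean()
            exact = clipped_interaction_area(x, y, R, RECT)
            assert exact == pytest.approx(mc, rel=5e-3, abs=5e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            clipped_interaction_area(0, 0, 1.0, (0, 0, 0, 5))
        with pytest.raises(ValueError, match="radius"):
            clipped_interaction_area(1, 1, 0.0, RECT)
        with pytest.raises(ValueError, match="outside"):
            clipped_interaction_area(-1, 1, 1.0, RECT)


class TestFitness:
    def test_no_competition_full_habitat(self):
        p = SimParams()
        assert fitness(0.0, 1.0, p) == 1.0

    def test_spatial_competition_constant(self):
        p = SimParams(K=5, L=4)
        assert p.lambda_fec == 0.25
        assert p.rho == pytest.approx(0.25 / 6.25)  # lambda/((1+lambda)K)

    def test_contracted_habitat_reduces_survival(self):
        for mode in ("scaled", "printed"):
            p = SimParams(habitat_mode=mode)
            assert fitness(3.0, 0.1, p) < fitness(3.0, 1.0, p)

    def test_printed_form_matches_equation(self):
        p = SimParams(habitat_mode="printed")
        C, h = 4.0, 0.5
        assert fitness(C, h, p) == pytest.approx(1 / (1 + p.rho * C / h))

    def test_scaled_form_matches_equation(self):
        p = SimParams(habitat_mode="scaled")
        C, h = 4.0, 0.5
        assert fitness(C, h, p) == pytest.approx(h / (1 + p.rho * C))

    @given(
        C=st.floats(min_value=0, max_value=1e4),
        h=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_survival_is_a_probability(self, C, h):
        for mode in ("scaled", "printed"):
            w = fitness(C, h, SimParams(habitat_mode=mode))
            assert 0.0 <= w <= 1.0

    def test_nonpositive_habitat_rejected(self):
        with pytest.raises(ValueError):
            fitness(1.0, 0.0, SimParams())


class TestCompetitionLoad:
    def test_isolated_individual(self):
        p = SimParams()
        focal = Individual(0, 10, 10)
        assert competition_load(focal, [focal], p, RECT) == 0.0

    def test_single_neighbor_at_zero_distance(self):
        p = SimParams()
        focal = Individual(0, 10, 10)
        other = Individual(1, 10, 10)
        C = competition_load(focal, [focal, other], p, RECT)
        assert C == pytest.approx(kernel_max(p.sigma))

    def test_corner_area_correction_quadruples_load(self):
        p = SimParams()
        focal = Individual(0, 0, 0)
        other = Individual(1, 0, 0)
        C = competition_load(focal, [focal, other], p, RECT)
        assert C == pytest.approx(4 * kernel_max(p.sigma))


class TestMatingAndDispersal:
    def test_single_candidate_always_chosen(self, rng):
        p = SimParams()
        focal = Individual(0, 10, 10)
        cand = Individual(1, 10.3, 10)
        far = Individual(2, 18, 18)
        for _ in range(10):
            assert choose_mate(focal, [focal, cand, far], p, rng) is cand

    def test_no_candidates_in_range(self, rng):
        p = SimParams()  # 3 sigma = 1.5
        focal = Individual(0, 10, 10)
        far = Individual(1, 12, 10)
        assert choose_mate(focal, [focal, far], p, rng) is None

    def test_mate_odds_follow_kernel_ratio(self, rng):
        p = SimParams(sigma=0.5)
        focal = Individual(0, 10, 10)
        near = Individual(1, 10 + p.sigma, 10)
        mid = Individual(2, 10 - 2 * p.sigma, 10)
        picks = [choose_mate(focal, [focal, near, mid], p, rng).id for _ in range(4000)]
        frac_near = np.mean(np.asarray(picks) == 1)
        expected = math.exp(-0.5) / (math.exp(-0.5) + math.exp(-2.0))
        se = math.sqrt(expected * (1 - expected) / 4000)
        assert frac_near == pytest.approx(expected, abs=4 * se)

    def test_self_mating_rejected(self, rng):
        p = SimParams()
        focal = Individual(0, 10, 10)
        with pytest.raises(ValueError, match="self-incompatible"):
            reproduce(focal, focal, p, rng)

    def test_poisson_offspring_mean(self, rng):
        p = SimParams(L=4)
        focal, mate = Individual(0, 5, 5), Individual(1, 5.2, 5)
        n = 0
        draws = 20_000
        for _ in range(draws):
            n += len(reproduce(focal, mate, p, rng, id_start=100))
        se = math.sqrt(0.25 / draws)
        assert n / draws == pytest.approx(0.25, abs=3 * se)
        # tallies incremented symmetrically for both parents
        assert focal.offspring_count == mate.offspring_count == n

    def test_zero_draw_leaves_tallies(self, stub_rng_factory):
        p = SimParams()
        focal, mate = Individual(0, 5, 5), Individual(1, 5.2, 5)
        kids = reproduce(focal, mate, p, stub_rng_factory(poisson=0))
        assert kids == [] and focal.offspring_count == 0

    def test_dispersal_zero_displacement(self, stub_rng_factory):
        p = SimParams()
        kid = Individual(3, 5, 5, age=0)
        out = disperse(kid, p, RECT, stub_rng_factory(normal=0.0))
        assert (out.x, out.y) == (5, 5)

    def test_dispersal_absorbing_boundary(self, stub_rng_factory):
        p = SimParams(sigma=1.0)
        kid = Individual(3, 0.2, 5, age=0)
        assert disperse(kid, p, RECT, stub_rng_factory(normal=-0.5)) is None

    def test_only_newborns_disperse(self, rng):
        p = SimParams()
        adult = Individual(3, 5, 5, age=2)
        with pytest.raises(ValueError, match="age 0"):
            disperse(adult, p, RECT, rng)

    def test_dispersal_moments(self, rng):
        p = SimParams(sigma=0.5)
        dx = []
        for _ in range(5000):
            kid = Individual(0, 10, 10, age=0)
            out = disperse(kid, p, RECT, rng)
            if out is not None:
                dx.append(out.x - 10)
        dx = np.asarray(dx)
        assert dx.mean() == pytest.approx(0.0, abs=4 * 0.5 / math.sqrt(len(dx)))
        assert dx.std() == pytest.approx(0.5, rel=0.05)


class TestEngine:
    def test_empty_population_stays_empty(self):
        # carrying capacity rounds to zero founders
        p = SimParams(K=0.01, burn_in=5, post_run=5)
        res = run(p, make_schedule("none", 2, 2, start=5), build_grid(2, 2), seed=1)
        assert res.extinct and res.final_n == 0
        assert res.timeseries.n.iloc[0] == 0

    def test_demographic_equilibrium_band(self):
        # uncontracted grid: long-run N within 15% of K * n_cells and mean
        # age within 25% of L
        p = SimParams(K=5, L=4, burn_in=150, post_run=100)
        res = run(p, make_schedule("none", 10, 10, start=150), build_grid(10, 10), seed=2)
        ts = res.timeseries
        tail = ts[ts.t > 100]
        assert tail.n.mean() == pytest.approx(500, rel=0.15)
        assert tail.mean_age.mean() == pytest.approx(4.0, rel=0.25)

    def test_seeded_determinism(self):
        p = SimParams(burn_in=40, post_run=20, genetics_lead=30)
        sch = make_schedule("shrinkage", 8, 8, n_events=2, interval=10, start=40)
        g = build_grid(8, 8)
        from rangesim.pipeline import build_sampling_plan

        plan = build_sampling_plan(p, sch)
        r1 = run(p, sch, g, seed=9, plan=plan)
        r2 = run(p, sch, g, seed=9, plan=plan)
        r3 = run(p, sch, g, seed=10, plan=plan)
        assert r1.timeseries.equals(r2.timeseries)
        assert not r1.timeseries.equals(r3.timeseries)

    def test_mismatched_grid_rejected(self):
        p = SimParams()
        with pytest.raises(ValueError, match="dimensions"):
            run(p, make_schedule("none", 10, 10), build_grid(8, 8), seed=1)
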