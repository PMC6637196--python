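"""Unit and property tests of the per-generation lattice update."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from gridpop.model_core import (
    DEAD,
    HET,
    HOM,
    WILD,
    GenerationStats,
    InvalidParameterError,
    PopulationCollapseError,
    PopulationGrid,
    SimulationParams,
    _batch_sample_parents,
    apply_de_novo,
    apply_mortality,
    mendelian_offspring,
    neighborhood_size,
    sample_parent_pair,
    sigma_from_neighborhood,
    step_generation,
)


def mixed_params(side, **kw):
    kw.setdefault("n_n", min(50, side * side))
    kw.setdefault("init_het_fraction", 0.3)
    return SimulationParams(N=side * side, **kw)


class TestSigmaFromNeighborhood:
    @pytest.mark.parametrize(
        "n_n, d, expected",
        [
            (4 * math.pi, 1.0, 1.0),
            (150.0, 1.0, 3.4549),  # sqrt(150 / 4pi)
            (250000.0, 1.0, 141.047),
        ],
    )
    def test_values(self, n_n, d, expected):
        assert sigma_from_neighborhood(n_n, d) == pytest.approx(expected, rel=1e-4)

    def test_round_trip_with_neighborhood_size(self):
        for n_n in (3.0, 150.0, 1e6):
            assert neighborhood_size(sigma_from_neighborhood(n_n)) == pytest.approx(
                n_n, rel=1e-12
            )

    @pytest.mark.parametrize("n_n, d", [(0.0, 1.0), (-5.0, 1.0), (150.0, 0.0)])
    def test_invalid(self, n_n, d):
        with pytest.raises(InvalidParameterError):
            sigma_from_neighborhood(n_n, d)


class TestSimulationParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(s_het=-1.5),
            dict(s_hom=-2.0),
            dict(mu=1.5),
            dict(mu=-0.1),
            dict(init_het_fraction=0.1, init_copies=5),  # both initializers
            dict(init_het_fraction=None),  # neither initializer
            dict(init_het_fraction=2.0),
            dict(n_n=1e9),  # exceeds N
            dict(sigma=-1.0),
        ],
    )
    def test_constraint_violations(self, kw):
        base = dict(N=400, n_n=100.0, init_het_fraction=0.1)
        base.update(kw)
        with pytest.raises(InvalidParameterError):
            SimulationParams(**base)

    def test_boundary_selection_coefficients_allowed(self):
        p = SimulationParams(N=400, n_n=100.0, s_het=-1.0, s_hom=-1.0, init_copies=1)
        assert p.death_probabilities[1] == 1.0

    def test_kernel_resolution(self):
        p = SimulationParams(N=10000, n_n=150.0, init_het_fraction=0.1)
        assert p.kernel_sigma == pytest.approx(math.sqrt(150 / (4 * math.pi)))
        assert not p.is_panmictic
        explicit = SimulationParams(N=10000, n_n=150.0, sigma=7.0, init_het_fraction=0.1)
        assert explicit.kernel_sigma == 7.0  # explicit sigma wins over n_n
        pan = SimulationParams(N=10000, panmictic=True, init_het_fraction=0.1)
        assert pan.is_panmictic and pan.kernel_sigma >= pan.side

    def test_effective_census_is_square(self):
        p = SimulationParams(N=10, panmictic=True, init_copies=1)
        assert p.side == 3 and p.n_effective == 9

    @pytest.mark.parametrize(
        "s_het, s_hom, expected",
        [
            (0.0, 0.0, (0.0, 0.0, 0.0)),
            (0.02, -1.0, (0.02 / 1.02, 0.0, 1.0)),
            (1.0, 0.0, (0.5, 0.0, 0.5)),
        ],
    )
    def test_death_probabilities(self, s_het, s_hom, expected):
        p = SimulationParams(N=400, panmictic=True, s_het=s_het, s_hom=s_hom, init_copies=1)
        assert p.death_probabilities == pytest.approx(expected)


class TestMortality:
    def test_uniform_fitness_changes_nothing(self, rng):
        p = mixed_params(20)
        grid = PopulationGrid.initialize(p, rng)
        out = apply_mortality(grid, p, rng)
        assert np.array_equal(out.states, grid.states)

    def test_lethal_homozygotes_all_die(self, rng):
        states = rng.choice([0, 1, 2], size=(30, 30), p=[0.5, 0.3, 0.2]).astype(np.int8)
        grid = PopulationGrid(states)
        p = mixed_params(30, s_het=0.03, s_hom=-1.0)
        out = apply_mortality(grid, p, rng)
        assert (out.states[states == int(HOM)] == int(DEAD)).all()
        # heterozygotes are the fittest class and never die here
        assert (out.states[states == int(HET)] == int(HET)).all()

    def test_death_rate_statistics(self, rng):
        # s_het=1, s_hom=0: wild and hom die with probability 1/2
        side = 100
        grid = PopulationGrid(np.zeros((side, side), dtype=np.int8))
        p = mixed_params(side, s_het=1.0, s_hom=0.0)
        out = apply_mortality(grid, p, rng)
        frac = (out.states == int(DEAD)).mean()
        se = math.sqrt(0.25 / side**2)
        assert abs(frac - 0.5) < 4 * se

    def test_rejects_grid_with_dead(self, rng):
        grid = PopulationGrid(np.full((5, 5), int(DEAD), dtype=np.int8))
        with pytest.raises(InvalidParameterError):
            apply_mortality(grid, mixed_params(5), rng)


class TestParentSampling:
    def test_two_survivors_forced(self, rng):
        states = np.full((9, 9), int(DEAD), dtype=np.int8)
        states[1, 1] = int(WILD)
        states[7, 4] = int(HET)
        grid = PopulationGrid(states)
        pair = sample_parent_pair(grid, (0, 0), sigma=1.0, rng=rng, rejection_budget=50)
        assert set(pair) == {(1, 1), (7, 4)}

    def test_collapse_signalled(self, rng):
        states = np.full((5, 5), int(DEAD), dtype=np.int8)
        states[0, 0] = int(WILD)
        with pytest.raises(PopulationCollapseError):
            sample_parent_pair(PopulationGrid(states), (2, 2), 1.0, rng)

    def test_kernel_displacement_scale(self, rng):
        # on a fully live grid the realized displacement per axis is the
        # rounded Gaussian: variance sigma^2 + 1/12 (discretization)
        side, sigma, n = 101, 3.0, 4000
        grid = PopulationGrid(np.zeros((side, side), dtype=np.int8))
        focal = (50, 50)
        disp = []
        for _ in range(n):
            for (r, c) in sample_parent_pair(grid, focal, sigma, rng):
                dr = (r - focal[0] + side // 2) % side - side // 2
                dc = (c - focal[1] + side // 2) % side - side // 2
                disp.extend([dr, dc])
        disp = np.asarray(disp, dtype=float)
        expected_sd = math.sqrt(sigma**2 + 1.0 / 12)
        assert abs(disp.mean()) < 4 * expected_sd / math.sqrt(disp.size)
        assert disp.std() == pytest.approx(expected_sd, rel=0.05)

    def test_torus_isotropy_at_boundary(self, rng):
        # distances sampled from a corner cell match those from the center:
        # wrap-around leaves no edge effects
        side, sigma, n = 51, 4.0, 3000
        grid = PopulationGrid(np.zeros((side, side), dtype=np.int8))

        def distances(focal):
            out = []
            for _ in range(n):
                for (r, c) in sample_parent_pair(grid, focal, sigma, rng):
                    dr = (r - focal[0] + side // 2) % side - side // 2
                    dc = (c - focal[1] + side // 2) % side - side // 2
                    out.append(math.hypot(dr, dc))
            return np.asarray(out)

        stat = sps.ks_2samp(distances((0, 0)), distances((25, 25)))
        assert stat.pvalue > 0.005

    def test_panmictic_limit_matches_uniform_sampling(self, rng):
        # kernel at least as wide as the torus: parent distances are
        # indistinguishable from brute-force uniform draws over the grid
        side = 31
        grid = PopulationGrid(np.zeros((side, side), dtype=np.int8))
        focal = (3, 27)
        kernel_d, uniform_d = [], []
        for _ in range(2000):
            for (r, c) in sample_parent_pair(grid, focal, float(side), rng):
                dr = (r - focal[0] + side // 2) % side - side // 2
                dc = (c - focal[1] + side // 2) % side - side // 2
                kernel_d.append(math.hypot(dr, dc))
            for r, c in rng.integers(0, side, size=(2, 2)):
                dr = (r - focal[0] + side // 2) % side - side // 2
                dc = (c - focal[1] + side // 2) % side - side // 2
                uniform_d.append(math.hypot(dr, dc))
        stat = sps.ks_2samp(np.asarray(kernel_d), np.asarray(uniform_d))
        assert stat.pvalue > 0.005

    def test_remote_survivors_reached_by_escalation(self, rng):
        # everything dead except two cells far outside the nominal kernel range
        side = 41
        states = np.full((side, side), int(DEAD), dtype=np.int8)
        states[20, 38] = int(WILD)
        states[20, 39] = int(HET)
        grid = PopulationGrid(states)
        pair = sample_parent_pair(grid, (20, 0), sigma=0.5, rng=rng, rejection_budget=50)
        assert set(pair) == {(20, 38), (20, 39)}

    def test_batch_never_selects_dead_and_parents_distinct(self, rng):
        states = rng.choice([0, 1, 2], size=(40, 40), p=[0.5, 0.3, 0.2]).astype(np.int8)
        p = mixed_params(40, s_het=0.1, s_hom=-1.0)
        doomed = rng.random(states.size) < p.death_probabilities[states.ravel()]
        alive = ~doomed
        p1 = _batch_sample_parents(alive, 40, 40, p.kernel_sigma, rng)
        p2 = _batch_sample_parents(alive, 40, 40, p.kernel_sigma, rng, taken=p1)
        assert alive[p1].all() and alive[p2].all()
        assert (p1 != p2).all()


class TestMendelianInheritance:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [(WILD, WILD, WILD), (HOM, WILD, HET), (WILD, HOM, HET), (HOM, HOM, HOM)],
    )
    def test_deterministic_crosses(self, g1, g2, expected, rng):
        assert mendelian_offspring(g1, g2, rng) == expected

    def test_het_cross_ratios(self, rng):
        n = 60000
        draws = np.array([int(mendelian_offspring(HET, HET, rng)) for _ in range(n)])
        observed = np.bincount(draws, minlength=3)
        res = sps.chisquare(observed, n * np.array([0.25, 0.5, 0.25]))
        assert res.pvalue > 1e-3

    def test_dead_parent_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            mendelian_offspring(DEAD, WILD, rng)


class TestDeNovoMutation:
    def test_zero_rate_identity(self, rng):
        for g in (WILD, HET, HOM):
            assert apply_de_novo(g, 0.0, rng) == g

    def test_hom_has_no_wild_allele(self, rng):
        assert all(apply_de_novo(HOM, 0.9, rng) == HOM for _ in range(50))

    def test_per_allele_independence(self, rng):
        # WILD with mu=0.5 enumerates to 1/4 : 1/2 : 1/4
        n = 40000
        draws = np.array([int(apply_de_novo(WILD, 0.5, rng)) for _ in range(n)])
        observed = np.bincount(draws, minlength=3)
        res = sps.chisquare(observed, n * np.array([0.25, 0.5, 0.25]))
        assert res.pvalue > 1e-3

    def test_invalid_rate(self, rng):
        with pytest.raises(InvalidParameterError):
            apply_de_novo(WILD, 1.5, rng)


class TestStepGeneration:
    @pytest.mark.parametrize("panmictic", [True, False])
    def test_wild_type_closure(self, panmictic, rng):
        side = 20
        p = mixed_params(side, mu=0.0) if not panmictic else SimulationParams(
            N=side * side, panmictic=True, init_het_fraction=0.3
        )
        grid = PopulationGrid(np.zeros((side, side), dtype=np.int8))
        out, stats = step_generation(grid, p, rng)
        assert stats.n_wild == side * side and stats.allele_frequency == 0.0

    @pytest.mark.parametrize("panmictic", [True, False])
    def test_variant_closure(self, panmictic, rng):
        side = 20
        kw = dict(s_hom=0.0, mu=0.0, init_het_fraction=0.3)
        p = SimulationParams(N=side * side, panmictic=True, **kw) if panmictic else mixed_params(side, s_hom=0.0, mu=0.0)
        grid = PopulationGrid(np.full((side, side), int(HOM), dtype=np.int8))
        out, stats = step_generation(grid, p, rng)
        assert stats.n_hom == side * side and stats.allele_frequency == 1.0

    @pytest.mark.parametrize("panmictic", [True, False])
    def test_census_conservation_and_no_dead(self, panmictic, rng):
        side = 25
        p = (
            SimulationParams(N=side * side, panmictic=True, s_het=0.5, s_hom=-1.0, init_het_fraction=0.4)
            if panmictic
            else mixed_params(side, s_het=0.5, s_hom=-1.0, init_het_fraction=0.4)
        )
        grid = PopulationGrid.initialize(p, rng)
        for _ in range(10):
            grid, stats = step_generation(grid, p, rng)
            assert stats.n == side * side
            assert not grid.has_dead

    def test_neutral_single_step_martingale(self, rng):
        # with s = mu = 0 the expected allele frequency is conserved
        side = 30
        p = mixed_params(side, n_n=60.0, mu=0.0)
        base = PopulationGrid.initialize(p, np.random.default_rng(5))
        p0 = GenerationStats.from_grid(base).allele_frequency
        reps = 1000
        freqs = np.empty(reps)
        for i in range(reps):
            _, stats = step_generation(base, p, rng)
            freqs[i] = stats.allele_frequency
        se = freqs.std(ddof=1) / math.sqrt(reps)
        assert abs(freqs.mean() - p0) < 3 * se

    def test_de_novo_mutation_feeds_variants(self, rng):
        side = 40
        p = SimulationParams(N=side * side, panmictic=True, mu=0.01, init_het_fraction=0.0)
        grid = PopulationGrid(np.zeros((side, side), dtype=np.int8))
        _, stats = step_generation(grid, p, rng)
        # expected 2*N*mu = 32 new variant alleles
        assert 10 <= stats.n_het + 2 * stats.n_hom <= 70

    def test_rejects_grid_with_dead(self, rng):
        grid = PopulationGrid(np.full((5, 5), int(DEAD), dtype=np.int8))
        with pytest.raises(InvalidParameterError):
            step_generation(grid, mixed_params(5), rng)

    @pytest.mark.parametrize("panmictic", [True, False])
    def test_deterministic_under_fixed_seed(self, panmictic):
        side = 15
        p = (
            SimulationParams(N=side * side, panmictic=True, s_het=0.2, s_hom=-1.0, init_het_fraction=0.3)
            if panmictic
            else mixed_params(side, s_het=0.2, s_hom=-1.0)
        )
        grid = PopulationGrid.initialize(p, np.random.default_rng(3))
        a, _ = step_generation(grid, p, np.random.default_rng(11))
        b, _ = step_generation(grid, p, np.random.default_rng(11))
        assert np.array_equal(a.states, b.states)
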