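"""Binning/coverage metrics, objective, and the design genetic algorithm."""

import numpy as np
import pytest

from rbslib import design as dz
from rbslib.degenerate import DegenerateSequence, design_space_size


class TestBins:
    @pytest.mark.parametrize(
        "r_min, r_max, W, expected",
        [
            (1, 100000, 0.30, 17),
            (1, 100, 0.5, 4),
            (1, 10, 1.0, 1),
            (1, 10, 5.0, 1),
        ],
    )
    def test_total_bins(self, r_min, r_max, W, expected):
        assert dz.total_bins(r_min, r_max, W) == expected

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            dz.total_bins(100, 1, 0.3)
        with pytest.raises(ValueError):
            dz.total_bins(1, 100, 0.0)

    def test_grid_centers_log_spaced(self):
        g = dz.BinGrid(1.0, 100000.0, 0.30)
        assert g.B_total == 17
        c = g.centers
        assert c[0] == pytest.approx(10 ** 0.15)
        assert np.allclose(np.diff(np.log10(c)), 0.30)


class TestCoverage:
    def test_no_rates_no_coverage(self):
        assert dz.coverage([], dz.BinGrid(1, 100, 0.5)) == 0.0

    def test_centers_fill_their_own_bins(self):
        g = dz.BinGrid(1, 100000, 0.30)
        assert dz.coverage(list(g.centers), g) == 1.0

    def test_single_rate_against_interval_oracle(self):
        """One rate fills exactly the bins whose window [y/10^W, y*10^W]
        contains it, checked by direct interval comparison."""
        g = dz.BinGrid(1.0, 1000.0, 1.0)  # 3 bins
        assert g.B_total == 3
        for r in (0.5, 1.1, 10 ** 0.5, 40.0, 999.0, 31623.0):
            expected = [
                i for i, y in enumerate(g.centers)
                if y / 10 ** g.W <= r <= y * 10 ** g.W
            ]
            assert list(np.nonzero(g.filled_mask([r]))[0]) == expected

    def test_window_boundaries_inclusive(self):
        g = dz.BinGrid(1.0, 100.0, 0.5)
        y = g.centers[0]
        assert g.filled_mask([y * 10 ** g.W])[0]
        assert g.filled_mask([y / 10 ** g.W])[0]

    def test_one_rate_can_fill_adjacent_overlapping_bins(self):
        g = dz.BinGrid(1.0, 100.0, 0.5)
        # a rate at a bin edge lies inside both neighboring windows
        assert g.filled_mask([10.0]).sum() >= 2


class TestObjective:
    @pytest.mark.parametrize(
        "C, n, expected",
        [(1.0, 17, 0.66), (0.0, 1, -0.02), (1.0, 1, 0.98), (0.5, 10, 0.30)],
    )
    def test_values(self, C, n, expected):
        assert dz.objective(C, n) == pytest.approx(expected)

    def test_maximum_is_full_coverage_one_variant_per_bin(self):
        B = dz.total_bins(1, 100000, 0.30)
        assert dz.objective(1.0, B) == pytest.approx(1 - 0.02 * B)
        assert dz.objective(1.0, B) <= 1 - 0.02 * 1

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            dz.objective(1.5, 3)
        with pytest.raises(ValueError):
            dz.objective(0.5, 0)


def test_full_degenerate_rbs_design_space():
    assert design_space_size(35) == 16 ** 35


class TestOperatorSchedule:
    def test_schedule_sums_to_one(self):
        assert sum(dz.OPERATOR_SCHEDULE.values()) == pytest.approx(1.0)

    def test_all_operators_drawable(self):
        rng = np.random.default_rng(0)
        seen = {dz.draw_operator(rng) for _ in range(5000)}
        assert seen == set(dz.OPERATOR_SCHEDULE)


def _toy_spec(toy_problem, seed, **overrides):
    kw = dict(
        mode="search", r_min=toy_problem.r_min, r_max=toy_problem.r_max,
        resolution_W=toy_problem.W, rbs_length=toy_problem.length,
        population_size=100, max_iterations=500, stagnation_limit=50,
        seed=seed,
    )
    kw.update(overrides)
    return dz.DesignSpec(**kw)


class TestOptimize:
    def test_deterministic_under_fixed_seed(self, toy_problem):
        runs = []
        for _ in range(2):
            sols = dz.optimize(_toy_spec(toy_problem, seed=4),
                               rate_fn=toy_problem.rate_fn,
                               rng=np.random.default_rng(4))
            runs.append([(s.dseq.letters, s.objective_F, s.n_variants)
                         for s in sols])
        assert runs[0] == runs[1]

    def test_best_objective_non_decreasing_across_generations(self, toy_problem):
        trace = []
        dz.optimize(_toy_spec(toy_problem, seed=9, max_iterations=60),
                    rate_fn=toy_problem.rate_fn, rng=np.random.default_rng(9),
                    progress=lambda gen, best: trace.append(best))
        assert len(trace) > 1
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_returns_top_five_with_reproducible_audit(self, toy_problem):
        sols = dz.optimize(_toy_spec(toy_problem, seed=1),
                           rate_fn=toy_problem.rate_fn,
                           rng=np.random.default_rng(1))
        assert len(sols) == 5
        grid = dz.BinGrid(toy_problem.r_min, toy_problem.r_max, toy_problem.W)
        for s in sols:
            # stored C, N, F must be recomputable from the sequence alone
            rates, _ = toy_problem.rate_fn(s.dseq)
            C = dz.coverage(list(rates.values()), grid)
            assert s.coverage_C == pytest.approx(C)
            assert s.n_variants == s.dseq.count_variants()
            assert s.objective_F == pytest.approx(
                dz.objective(C, s.n_variants))
        Fs = [s.objective_F for s in sols]
        assert Fs == sorted(Fs, reverse=True)

    def test_finds_exhaustive_optimum_on_toy_problem(self, toy_problem,
                                                     toy_problem_brute_force):
        best_F, _ = toy_problem_brute_force
        hits = 0
        for seed in range(3):
            sols = dz.optimize(_toy_spec(toy_problem, seed=seed),
                               rate_fn=toy_problem.rate_fn,
                               rng=np.random.default_rng(seed))
            hits += sols[0].objective_F >= best_F - 1e-9
        assert hits == 3

    def test_zoom_is_reparameterized_search(self, toy_problem):
        """Zoom mode shares the search code path: identical seed and rate
        window give identical solutions."""
        a = dz.optimize(_toy_spec(toy_problem, seed=2, mode="search"),
                        rate_fn=toy_problem.rate_fn, rng=np.random.default_rng(2))
        b = dz.optimize(_toy_spec(toy_problem, seed=2, mode="zoom"),
                        rate_fn=toy_problem.rate_fn, rng=np.random.default_rng(2))
        assert [s.dseq.letters for s in a] == [s.dseq.letters for s in b]


class TestGenomeEditing:
    @pytest.mark.parametrize(
        "candidate, wild, max_window, ok, window",
        [
            ("AAAA", "AAAA", 4, True, (0, 0)),
            ("AAANAAAAAA" * 3 + "AAACA", "A" * 35, 10, False, (3, 34)),
            ("AAAAAAAAAARNSWKAAAAA", "A" * 20, 6, True, (10, 15)),
            ("CAAA", "AAAA", 1, True, (0, 1)),
        ],
    )
    def test_feasibility_window(self, candidate, wild, max_window, ok, window):
        got_ok, got_window = dz.genome_edit_feasible(candidate, wild, max_window)
        assert got_ok is ok
        assert got_window == window

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dz.genome_edit_feasible("AAA", "AAAA", 3)

    def test_optimize_returns_only_feasible_candidates(self, toy_problem):
        wild = "ACG"
        spec = _toy_spec(toy_problem, seed=5, mode="genome_edit",
                         wild_type_rbs=wild, max_window=2, max_iterations=80)
        sols = dz.optimize(spec, rate_fn=toy_problem.rate_fn,
                           rng=np.random.default_rng(5))
        for s in sols:
            ok, window = dz.genome_edit_feasible(s.dseq, wild, 2)
            assert ok
            assert s.window == window

    def test_spec_requires_wild_type(self):
        with pytest.raises(ValueError, match="wild_type_rbs"):
            dz.DesignSpec(mode="genome_edit", r_min=1, r_max=10,
                          resolution_W=0.5)


class TestMultiDimCoverage:
    def test_one_dimension_reduces_to_coverage(self):
        g = dz.BinGrid(1, 1000, 0.4)
        rates = [2.0, 50.0, 900.0]
        assert dz.multi_dim_coverage([(r,) for r in rates], [g]) == \
            pytest.approx(dz.coverage(rates, g))

    def test_cartesian_product_of_centers_fills_everything(self):
        gs = [dz.BinGrid(1, 100, 0.5), dz.BinGrid(1, 1000, 1.0)]
        tuples = [(a, b) for a in gs[0].centers for b in gs[1].centers]
        assert dz.multi_dim_coverage(tuples, gs) == 1.0

    def test_identical_tuples_match_cell_scan_oracle(self):
        gs = [dz.BinGrid(1, 100, 0.5), dz.BinGrid(1, 100, 0.5),
              dz.BinGrid(1, 1000, 1.0)]
        t = (3.0, 40.0, 11.0)
        # direct cell-by-cell scan
        filled = 0
        total = 0
        for i, yi in enumerate(gs[0].centers):
            for j, yj in enumerate(gs[1].centers):
                for k, yk in enumerate(gs[2].centers):
                    total += 1
                    ok = all(
                        y / 10 ** g.W <= r <= y * 10 ** g.W
                        for g, y, r in zip(gs, (yi, yj, yk), t)
                    )
                    filled += ok
        assert dz.multi_dim_coverage([t, t, t], gs) == pytest.approx(filled / total)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dz.multi_dim_coverage([(1.0, 2.0)], [dz.BinGrid(1, 10, 0.5)])


class TestMonteCarloCoverage:
    def _setup(self, toy_problem):
        genes = [DegenerateSequence("RY"), DegenerateSequence("SW")]
        grids = [dz.BinGrid(toy_problem.r_min, toy_problem.r_max, 0.4)] * 2
        fns = [lambda v: toy_problem.rate(v + "A"),
               lambda v: toy_problem.rate(v + "C")]
        return genes, grids, fns

    def test_exhaustive_sampling_equals_exact_coverage(self, toy_problem):
        genes, grids, fns = self._setup(toy_problem)
        exact_tuples = [
            (fns[0](a), fns[1](b))
            for a in genes[0].expand() for b in genes[1].expand()
        ]
        exact = dz.multi_dim_coverage(exact_tuples, grids)
        mean, sd = dz.monte_carlo_coverage(
            genes, None, grids, n_clones=400, replicates=3,
            model=None, engine=None, rng=np.random.default_rng(0),
            rate_fns=fns)
        # 400 uniform draws over 16 combinations see every combination
        assert mean == pytest.approx(exact)
        assert sd == pytest.approx(0.0)

    def test_mean_coverage_non_decreasing_in_clone_count(self, toy_problem):
        genes, grids, fns = self._setup(toy_problem)
        means = []
        for n in (1, 4, 16, 64):
            m, _ = dz.monte_carlo_coverage(
                genes, None, grids, n_clones=n, replicates=8,
                model=None, engine=None, rng=np.random.default_rng(12),
                rate_fns=fns)
            means.append(m)
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_zero_clones_rejected(self, toy_problem):
        genes, grids, fns = self._setup(toy_problem)
        with pytest.raises(ValueError):
            dz.monte_carlo_coverage(genes, None, grids, n_clones=0,
                                    replicates=1, model=None, engine=None,
                                    rng=np.random.default_rng(0), rate_fns=fns)
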