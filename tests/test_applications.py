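"""SEAMAP applications: FCCs, response curves, sweeps, landscapes, zoom."""

import numpy as np
import pytest

from rbslib import kinetics as kn
from rbslib.applications import (
    SEAMAP,
    InductionModel,
    evolutionary_landscape,
    fcc,
    precursor_sweep,
    response_curve,
    synthetic_crt_contexts,
    zoom_target,
)
from rbslib.biophysics import RibosomeModel, ToyEngine
from rbslib.kinetics import PathwayVariant, Reaction, ReactionNetwork

REF = kn.REFERENCE_TRANSLATION_RATES


def test_seamap_predicts_reference_productivity_exactly(seamap):
    assert seamap.predict(PathwayVariant(REF)) == pytest.approx(196.0, rel=1e-9)


def test_parameter_hash_traceability(seamap, network, true_params):
    again = SEAMAP(network=network, params=dict(true_params))
    assert seamap.parameter_hash == again.parameter_hash
    other = SEAMAP(network=network,
                   params=kn.default_parameters(network))
    assert other.parameter_hash != seamap.parameter_hash


class TestFCC:
    def test_proportional_control_limit(self):
        """In a linear single-enzyme regime (irreversible product release,
        fixed substrate) flux is exactly proportional to enzyme level, so
        the flux control coefficient is 1."""
        net = ReactionNetwork(
            reactions=(
                Reaction("R01", "CrtE", "CrtE.1", ("CrtE", "S"), ("CrtE:S",),
                         "bind"),
                Reaction("R02", "CrtE", "CrtE.1", ("CrtE:S",), ("CrtE", "P"),
                         "release"),
            ),
            boundary_species=frozenset({"S"}),
            product_species="P",
        )
        params = {"kf_R01": 8.0, "kr_R01": 3.0, "kf_R02": 5.0, "kr_R02": 0.0}
        sm = SEAMAP(network=net, params=params)
        c = fcc(sm, PathwayVariant(REF), "CrtE")
        assert c == pytest.approx(1.0, abs=0.01)

    def test_near_zero_at_interior_axis_maximum(self, network):
        """Along one enzyme's axis, the FCC vanishes at an interior
        productivity maximum (sequestration makes excess enzyme harmful)."""
        from scipy.optimize import minimize_scalar

        p = kn.default_parameters(network)
        p["kr_R24"] = 300.0   # product rebinds CrtI
        p["kr_R17"] = 100.0
        p["kf_R14"] = 200.0   # CrtB sequesters GGPP
        sm = SEAMAP(network=network, params=p, sim_rtol=1e-8, sim_atol=1e-11)

        def neg_prod(log_eB):
            return -sm.predict_ratios((1.0, float(10 ** log_eB), 1.0))

        sol = minimize_scalar(neg_prod, bounds=(-1.5, 1.5), method="bounded",
                              options={"xatol": 1e-6})
        e_star = 10 ** sol.x
        v = PathwayVariant((REF[0], REF[1] * e_star, REF[2]))
        assert abs(fcc(sm, v, "CrtB", rel_step=0.01)) < 0.02

    def test_step_halving_convergence(self, seamap):
        v = PathwayVariant(REF)
        a = fcc(seamap, v, "CrtE", rel_step=0.02)
        b = fcc(seamap, v, "CrtE", rel_step=0.01)
        assert abs(a - b) / abs(b) < 0.01

    def test_summation_band_in_proportional_regime(self):
        """In the proportional-control regime of a linear synthetic chain
        (one enzyme strongly limiting), the three FCCs sum into [0, 1.05].
        Exact summation to 1 is a steady-state theorem; the 7-h batch
        endpoint deviates slightly, and substantially so away from this
        regime (see the methods note)."""
        rx = []
        for rid1, rid2, enz, sub, prod in (
            ("R01", "R02", "CrtE", "S", "M1"),
            ("R03", "R04", "CrtB", "M1", "M2"),
            ("R05", "R06", "CrtI", "M2", "P"),
        ):
            rx.append(Reaction(rid1, enz, enz + ".1", (enz, sub),
                               (enz + ":" + sub,), "bind"))
            rx.append(Reaction(rid2, enz, enz + ".1", (enz + ":" + sub,),
                               (enz, prod), "release"))
        net = ReactionNetwork(reactions=tuple(rx),
                              boundary_species=frozenset({"S"}),
                              product_species="P")
        params = {}
        for r in rx:
            params[r.kf_id] = 10.0 if r.kind == "bind" else 8.0
            params[r.kr_id] = 2.0 if r.kind == "bind" else 0.0
        sm = SEAMAP(network=net, params=params,
                    sim_rtol=1e-8, sim_atol=1e-11)
        limited = PathwayVariant((REF[0] * 0.1, REF[1], REF[2]))
        total = sum(fcc(sm, limited, e) for e in ("CrtE", "CrtB", "CrtI"))
        assert 0.0 <= total <= 1.05

    def test_unknown_enzyme_rejected(self, seamap):
        with pytest.raises(ValueError):
            fcc(seamap, PathwayVariant(REF), "Idi2")


class TestResponseCurve:
    def test_flat_induction_gives_constant_productivity(self, seamap):
        ind = InductionModel(basal=1.0, max=1.0, K=10.0, n=2.0)
        df = response_curve(seamap, PathwayVariant(REF), ind,
                            np.linspace(0, 100, 5))
        prods = df["productivity_ug_gDCW_h"]
        assert prods.max() - prods.min() <= 1e-9 * prods.max()

    def test_hill_multiplier_monotone_and_bounded(self):
        ind = InductionModel(basal=0.05, max=3.0, K=50.0, n=2.0)
        grid = np.linspace(0, 500, 30)
        m = [ind.multiplier(x) for x in grid]
        assert all(b >= a for a, b in zip(m, m[1:]))
        assert all(0.05 <= x <= 3.0 for x in m)

    def test_translation_scaling_equals_transcription_shift(self, seamap):
        """A variant with lambda-fold translation rates traces the same
        curve as the original shifted by 1/lambda in transcription."""
        lam = 4.0
        v1 = PathwayVariant(REF)
        v2 = PathwayVariant(tuple(lam * r for r in REF))
        for m in (0.4, 1.0, 2.4):
            a = seamap.predict(PathwayVariant(
                v1.translation_rates, transcription_multiplier=m * lam))
            b = seamap.predict(PathwayVariant(
                v2.translation_rates, transcription_multiplier=m))
            assert a == pytest.approx(b, rel=1e-9)

    def test_sequestration_makes_response_non_monotone(self, network):
        """With strong product rebinding, raising transcription beyond the
        optimum lowers productivity (intermediates get sequestered as
        enzyme complexes)."""
        p = kn.default_parameters(network)
        p["kr_R24"] = 300.0
        p["kr_R17"] = 100.0
        p["kf_R14"] = 200.0
        sm = SEAMAP(network=network, params=p, sim_rtol=1e-6, sim_atol=1e-9)
        ind = InductionModel(basal=0.2, max=60.0, K=40.0, n=2.0)
        df = response_curve(sm, PathwayVariant(REF), ind,
                            np.linspace(0, 400, 15))
        prods = df["productivity_ug_gDCW_h"].to_numpy()
        peak = prods.argmax()
        assert 0 < peak < len(prods) - 1
        assert prods[-1] < prods[peak] * 0.9


class TestPrecursorSweep:
    def test_unit_supply_is_baseline(self, seamap):
        df = precursor_sweep(seamap, PathwayVariant(REF),
                             np.array([1.0, 2.0]))
        assert df.loc[0, "fold_improvement"] == pytest.approx(1.0)
        assert df.loc[0, "productivity_ug_gDCW_h"] == pytest.approx(196.0,
                                                                    rel=1e-6)

    def test_supply_response_rises_then_saturates_and_turns_over(self, network):
        """Sub-saturating precursor increases raise productivity; large
        excesses lower it again, because high IPP outcompetes free-GPP
        release at IspA and starves CrtE's entry step (a steady-state
        property of the canonical decomposition, see the methods note)."""
        p = {k: (v if k.startswith("kf_") else 0.0)
             for k, v in kn.default_parameters(network).items()}
        sm = SEAMAP(network=network, params=p, sim_rtol=1e-6, sim_atol=1e-9)
        df = precursor_sweep(sm, PathwayVariant(REF),
                             np.array([0.25, 0.5, 1.0, 2.0, 4.0, 16.0]))
        prods = df["productivity_ug_gDCW_h"].to_numpy()
        assert all(b >= a - 1e-9 for a, b in zip(prods[:5], prods[1:5]))
        assert prods[5] < prods[4]

    def test_balanced_pathway_gains_more_than_terminal_bottleneck(self, seamap):
        """Once the enzymes' FCCs are near zero, control has shifted
        upstream: raising precursor supply helps the balanced variant more
        than one bottlenecked at the terminal (precursor-independent)
        enzyme."""
        balanced = PathwayVariant(tuple(5 * np.array(REF)))
        bottleneck = PathwayVariant((REF[0], REF[1], REF[2] / 100))
        assert fcc(seamap, bottleneck, "CrtI") > 0.9
        assert abs(fcc(seamap, balanced, "CrtI")) < 0.1
        folds = {}
        for name, v in (("balanced", balanced), ("bottleneck", bottleneck)):
            df = precursor_sweep(seamap, v, np.array([1.0, 5.0]))
            folds[name] = df.loc[1, "fold_improvement"]
        assert folds["balanced"] > folds["bottleneck"]

    def test_non_positive_supply_rejected(self, seamap):
        with pytest.raises(ValueError):
            precursor_sweep(seamap, PathwayVariant(REF), np.array([0.0]))


@pytest.fixture(scope="module")
def landscape_setup():
    model = RibosomeModel()
    engine = ToyEngine()
    contexts, rbss = synthetic_crt_contexts(seed=5)
    return model, engine, contexts, rbss


class TestEvolutionaryLandscape:
    def test_zero_mutations_leave_productivity_unchanged(self, seamap,
                                                         landscape_setup):
        model, engine, contexts, rbss = landscape_setup
        res = evolutionary_landscape(seamap, contexts, rbss, 0, 50, model,
                                     engine, np.random.default_rng(0))
        assert np.all(res.ratios == 1.0)

    def test_deterministic_under_fixed_seed(self, seamap, landscape_setup):
        model, engine, contexts, rbss = landscape_setup
        runs = [
            evolutionary_landscape(seamap, contexts, rbss, 2, 60, model,
                                   engine, np.random.default_rng(11))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].ratios, runs[1].ratios)
        h0, e0 = runs[0].histogram()
        h1, e1 = runs[1].histogram()
        assert np.array_equal(h0, h1) and np.array_equal(e0, e1)

    def test_ratios_positive_and_hash_stamped(self, seamap, landscape_setup):
        model, engine, contexts, rbss = landscape_setup
        res = evolutionary_landscape(seamap, contexts, rbss, 1, 80, model,
                                     engine, np.random.default_rng(2))
        assert np.all(res.ratios >= 0.0)
        assert res.parameter_hash == seamap.parameter_hash
        assert 0.0 <= res.fraction_decreased <= 1.0


class TestZoomTarget:
    def test_window_contains_grid_optimum(self, seamap):
        """The returned windows must contain the dense-grid argmax."""
        axes = [np.logspace(np.log10(r / 4), np.log10(r * 4), 6) for r in REF]
        grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
        prods = [seamap.predict(PathwayVariant(tuple(row))) for row in grid]
        best = grid[int(np.argmax(prods))]
        windows = zoom_target(seamap, REF, expansion_factor=4.0,
                              grid_points=6)
        for gene, value in zip(("crtE", "crtB", "crtI"), best):
            lo, hi = windows[gene]
            assert lo <= value <= hi

    def test_windows_are_valid_rate_ranges(self, seamap):
        windows = zoom_target(seamap, REF, expansion_factor=5.0,
                              grid_points=5)
        for lo, hi in windows.values():
            assert 0.10 <= lo < hi <= 5e6

    def test_repeated_zoom_converges(self, seamap):
        """Applying zoom twice on a fixed map shrinks or stabilizes the
        per-gene windows."""
        w1 = zoom_target(seamap, REF, expansion_factor=5.0, grid_points=5)
        center = tuple(np.sqrt(lo * hi) for lo, hi in w1.values())
        w2 = zoom_target(seamap, center, expansion_factor=2.0, grid_points=5)
        for gene in w1:
            span1 = w1[gene][1] / w1[gene][0]
            span2 = w2[gene][1] / w2[gene][0]
            assert span2 <= span1 * 1.001


def test_synthetic_contexts_are_valid(model):
    contexts, rbss = synthetic_crt_contexts(seed=3)
    assert len(contexts) == len(rbss) == 3
    for ctx, rbs in zip(contexts, rbss):
        assert ctx.cds.startswith("AUG")
        assert len(rbs) == 35
        assert ctx.rbs == rbs
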