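"""Speciation models, simulator, likelihood and model comparison."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from biomespec import (
    FitResult,
    GridConfig,
    PhyloDataset,
    SpeciationModel,
    compare_models,
    default_grid_for,
    fit_model,
    lambda_at,
    quasse_loglik,
    resolve_polytomies,
    simulate_tree,
)
from biomespec.fitting import degenerate_start
from biomespec.quasse import (GridError, _Propagator, brownian_loglik,
                              constant_bd_loglik)
from biomespec.speciation import CompleteExtinctionError

from conftest import assert_binary, tip_depths


def sigmoid_model(**kw):
    base = dict(shape="sigmoid", lambda0=0.17, lambda1=0.018, xmid=4.61,
                steepness=2.0, mu=0.01, sigma2=0.05)
    base.update(kw)
    return SpeciationModel(**base)


class TestLambdaAt:
    def test_equal_plateaus_collapse_to_constant(self):
        m = sigmoid_model(lambda1=0.17)
        x = np.linspace(-2, 12, 50)
        np.testing.assert_allclose(m.lambda_at(x), 0.17)

    def test_sigmoid_midpoint_is_average_of_plateaus(self):
        m = sigmoid_model()
        assert m.lambda_at(4.61) == pytest.approx((0.17 + 0.018) / 2)

    def test_steep_sigmoid_reaches_plateaus(self):
        """Specialists speciate near lambda0, generalists near lambda1."""
        m = sigmoid_model(steepness=20.0)
        assert m.lambda_at(1.0) == pytest.approx(0.17, abs=1e-4)
        assert m.lambda_at(8.0) == pytest.approx(0.018, abs=1e-4)

    def test_linear_clamped_at_zero(self):
        m = SpeciationModel(shape="linear", lambda0=0.1, slope=-0.05,
                            mu=0.0, sigma2=0.01)
        assert m.lambda_at(10.0) == 0.0
        assert m.lambda_at(0.0) == pytest.approx(0.1)

    def test_modal_peaks_at_mode(self):
        m = SpeciationModel(shape="modal", lambda0=0.2, lambda1=0.05,
                            xmid=3.0, width=1.0, mu=0.0, sigma2=0.01)
        assert m.lambda_at(3.0) == pytest.approx(0.2)
        assert m.lambda_at(30.0) == pytest.approx(0.05)

    def test_parameter_counts_follow_shape_and_drift(self):
        assert SpeciationModel(shape="constant", lambda0=0.1).n_params == 3
        assert SpeciationModel(shape="linear", lambda0=0.1,
                               slope=0.0).n_params == 4
        assert sigmoid_model().n_params == 6
        assert sigmoid_model(with_drift=True, drift=0.1).n_params == 7


class TestSimulateTree:
    def test_zero_diffusion_keeps_root_trait(self):
        m = SpeciationModel(shape="constant", lambda0=0.3, mu=0.0, sigma2=0.0)
        ds = simulate_tree(m, x0=2.5, n_tips=15, seed=1)
        assert (ds.traits == 2.5).all()

    def test_tips_are_contemporaneous(self):
        m = SpeciationModel(shape="constant", lambda0=0.3, mu=0.05,
                            sigma2=0.02)
        ds = simulate_tree(m, x0=2.0, n_tips=25, seed=3)
        depths = list(tip_depths(ds.tree).values())
        assert max(depths) - min(depths) < 1e-6

    def test_yule_mean_tip_count(self):
        """Pure birth: E[tips] after time T is exp(lambda*T)."""
        lam, T = 0.1, 15.0
        m = SpeciationModel(shape="constant", lambda0=lam, mu=0.0,
                            sigma2=0.0)
        counts = []
        for seed in range(80):
            ds = simulate_tree(m, x0=1.0, stop_time=T, dt=0.02, seed=seed)
            counts.append(ds.n_tips)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert mean == pytest.approx(np.exp(lam * T), abs=3 * se + 0.15)

    def test_decreasing_sigmoid_enriches_low_trait_tips(self):
        """Speciation favoring specialists drags the tip-trait mean down
        relative to a neutral constant-rate control."""
        sig = sigmoid_model(steepness=3.0, mu=0.0, sigma2=0.4)
        flat = SpeciationModel(shape="constant", lambda0=0.1, mu=0.0,
                               sigma2=0.4)
        sig_means, flat_means = [], []
        for seed in range(12):
            sig_means.append(
                simulate_tree(sig, x0=4.61, n_tips=40, seed=seed).traits.mean()
            )
            flat_means.append(
                simulate_tree(flat, x0=4.61, n_tips=40, seed=seed).traits.mean()
            )
        assert np.mean(sig_means) < np.mean(flat_means)

    def test_complete_extinction_is_flagged(self):
        m = SpeciationModel(shape="constant", lambda0=0.01, mu=2.0,
                            sigma2=0.0)
        with pytest.raises(CompleteExtinctionError):
            simulate_tree(m, x0=1.0, stop_time=50.0, seed=0)

    def test_requires_exactly_one_stop_rule(self):
        m = SpeciationModel(shape="constant", lambda0=0.1)
        with pytest.raises(ValueError):
            simulate_tree(m, x0=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_tree(m, x0=1.0, stop_time=5.0, n_tips=5, seed=0)


class TestQuasseLoglik:
    def test_factorizes_for_trait_independent_rates(
        self, small_constant_dataset
    ):
        """Constant rates: grid lnL = birth-death lnL + Brownian lnL."""
        model, ds = small_constant_dataset
        grid = GridConfig(x_lo=-4, x_hi=12, n_points=256, dt=0.02)
        ll = quasse_loglik(ds, model, grid)
        closed = (
            constant_bd_loglik(ds.tree, model.lambda0, model.mu)
            + brownian_loglik(ds.tree, ds.traits, model.sigma2,
                              tip_sd=grid.tip_sd)
        )
        assert ll == pytest.approx(closed, abs=1e-3)

    def test_factorizes_with_drift(self, small_constant_dataset):
        model, ds = small_constant_dataset
        drifted = SpeciationModel(shape="constant", lambda0=model.lambda0,
                                  mu=model.mu, sigma2=model.sigma2,
                                  drift=0.08, with_drift=True)
        grid = GridConfig(x_lo=-4, x_hi=12, n_points=256, dt=0.02)
        ll = quasse_loglik(ds, drifted, grid)
        closed = (
            constant_bd_loglik(ds.tree, model.lambda0, model.mu)
            + brownian_loglik(ds.tree, ds.traits, model.sigma2, drift=0.08,
                              tip_sd=grid.tip_sd)
        )
        assert ll == pytest.approx(closed, abs=1e-3)

    def test_sigmoid_degeneracy_equals_constant(self, small_constant_dataset):
        model, ds = small_constant_dataset
        grid = GridConfig(x_lo=-4, x_hi=12, n_points=128, dt=0.1)
        flat_sig = sigmoid_model(lambda0=model.lambda0, lambda1=model.lambda0,
                                 mu=model.mu, sigma2=model.sigma2)
        assert quasse_loglik(ds, flat_sig, grid) == pytest.approx(
            quasse_loglik(ds, model, grid), abs=1e-9
        )

    def test_three_tip_tree_matches_fine_grid_reference(self):
        tree = dendropy.Tree.get(
            data="((a:1.0,b:1.0):0.5,c:1.5);", schema="newick"
        )
        ds = PhyloDataset(tree=tree,
                          traits=pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
        m = sigmoid_model(sigma2=0.2)
        coarse = quasse_loglik(ds, m, GridConfig(-5, 9, 256, dt=0.02))
        fine = quasse_loglik(ds, m, GridConfig(-5, 9, 1024, dt=0.0025))
        assert coarse == pytest.approx(fine, abs=1e-4)

    def test_grid_refinement_converged_at_default(
        self, small_constant_dataset
    ):
        """Doubling resolution and halving the step moves lnL < 1e-2."""
        _, ds = small_constant_dataset
        m = sigmoid_model(sigma2=0.1)
        base = default_grid_for(ds)
        refined = GridConfig(base.x_lo, base.x_hi, base.n_points * 2,
                             dt=base.dt / 2, tip_sd=base.tip_sd)
        a = quasse_loglik(ds, m, base)
        b = quasse_loglik(ds, m, refined)
        assert abs(a - b) < 1e-2

    def test_extinction_probability_stays_in_unit_interval(self):
        m = sigmoid_model(mu=0.1, sigma2=0.3)
        grid = GridConfig(-5, 12, 128, dt=0.1)
        prop = _Propagator(m, grid)
        E = np.zeros(grid.n_points)
        D = np.exp(-0.5 * (grid.x - 3.0) ** 2)
        for _ in range(10):
            E, D, _ = prop.propagate(E, D, 5.0)
            assert (E >= 0).all() and (E <= 1).all()

    def test_narrow_grid_raises_helpful_error(self, small_constant_dataset):
        model, ds = small_constant_dataset
        lo = float(ds.traits.min()) - 1.2
        hi = float(ds.traits.max()) + 1.2
        with pytest.raises(GridError, match="widen"):
            quasse_loglik(ds, sigmoid_model(sigma2=0.8),
                          GridConfig(lo, hi, 64, dt=0.2))

    def test_polytomies_rejected(self):
        tree = dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick")
        ds = PhyloDataset(tree=tree,
                          traits=pd.Series({"a": 1.0, "b": 1.0, "c": 1.0}))
        with pytest.raises(ValueError, match="binary"):
            quasse_loglik(ds, sigmoid_model(), GridConfig(-4, 6, 64, dt=0.2))


class TestFitting:
    def test_constant_rate_recovery(self):
        """lambda is recovered within 25% on a moderate tree."""
        m = SpeciationModel(shape="constant", lambda0=0.15, mu=0.03,
                            sigma2=0.05)
        from biomespec import generate_phylo_dataset

        hits = 0
        for seed in (11, 23, 35):
            ds = generate_phylo_dataset(m, x0=3.0, n_tips=80, seed=seed)
            grid = default_grid_for(ds, n_points=64, dt=0.4)
            fit = fit_model(ds, "constant", grid=grid, maxiter=30, n_starts=1)
            assert fit.converged
            hits += abs(fit.params["lambda0"] - 0.15) / 0.15 < 0.25
        assert hits >= 2

    def test_refit_is_deterministic(self, small_constant_dataset):
        model, ds = small_constant_dataset
        grid = default_grid_for(ds, n_points=64, dt=0.4)
        a = fit_model(ds, "constant", grid=grid, maxiter=10, n_starts=1)
        b = fit_model(ds, "constant", grid=grid, maxiter=10, n_starts=1)
        assert a.params == b.params and a.lnL == b.lnL

    def test_nested_sigmoid_never_scores_below_constant(
        self, small_constant_dataset
    ):
        model, ds = small_constant_dataset
        grid = default_grid_for(ds, n_points=64, dt=0.4)
        fc = fit_model(ds, "constant", grid=grid, maxiter=20, n_starts=1)
        fs = fit_model(
            ds, "sigmoid", grid=grid, maxiter=20, n_starts=1,
            extra_starts=[degenerate_start("sigmoid", False, fc.params)],
        )
        assert fs.lnL >= fc.lnL - 1e-6


class TestCompareModels:
    @staticmethod
    def fr(label, n, lnL, shape="sigmoid"):
        return FitResult(shape=shape, with_drift=False, params={},
                         lnL=lnL, n_params=n, converged=True)

    def test_aic_arithmetic(self):
        assert self.fr("m", 3, -1076.8).aic == pytest.approx(2159.6)

    def test_equal_likelihood_extra_parameter_is_a_tie(self):
        a = FitResult("sigmoid", False, {}, -100.0, 6, True)
        b = FitResult("sigmoid", True, {}, -100.0, 7, True)
        cmp = compare_models([[a, b]])
        row = cmp.per_tree.set_index("model").loc["sigmoid+drift"]
        assert row["delta_aic"] == pytest.approx(2.0)
        assert bool(row["tie"])

    def test_nonconverged_fits_are_excluded(self):
        good = FitResult("constant", False, {}, -50.0, 3, True)
        bad = FitResult("sigmoid", False, {}, -np.inf, 6, False)
        other = FitResult("linear", False, {}, -51.0, 4, True)
        cmp = compare_models([[good, bad, other]])
        assert set(cmp.per_tree["model"]) == {"constant", "linear"}

    def test_tree_without_two_usable_fits_is_dropped(self):
        good = FitResult("constant", False, {}, -50.0, 3, True)
        bad = FitResult("sigmoid", False, {}, -np.inf, 6, False)
        other = FitResult("linear", False, {}, -51.0, 4, True)
        cmp = compare_models([[good, bad], [good, other]])
        assert cmp.dropped_trees == [0]
        assert cmp.per_tree["tree"].unique().tolist() == [1]


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self):
        t = dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")
        out = resolve_polytomies(t, n_resolutions=3, seed=0)
        for r in out:
            assert r.as_string(schema="newick") == t.as_string(schema="newick")

    def test_star_tree_fully_resolved(self):
        k = 6
        star = dendropy.Tree.get(
            data="(" + ",".join(f"t{i}:1.0" for i in range(k)) + ");",
            schema="newick",
        )
        out = resolve_polytomies(star, n_resolutions=5, seed=1)
        for r in out:
            assert_binary(r)
            internal = sum(
                1 for n in r.preorder_node_iter() if not n.is_leaf()
            )
            assert internal == k - 1

    def test_tip_depths_conserved(self, polytomy_tree):
        before = tip_depths(polytomy_tree)
        for r in resolve_polytomies(polytomy_tree, n_resolutions=10, seed=2):
            assert_binary(r)
            after = tip_depths(r)
            for tip, d in before.items():
                assert after[tip] == pytest.approx(d, abs=1e-9)

    def test_resolutions_vary_across_draws(self, polytomy_tree):
        out = resolve_polytomies(polytomy_tree, n_resolutions=8, seed=3)
        topologies = {r.as_string(schema="newick") for r in out}
        assert len(topologies) > 1
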