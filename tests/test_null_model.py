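"""Richness-constrained null model: engine, oracle, p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from biomespec import (
    RichnessMarginals,
    analytic_null_bsi,
    empirical_pvalue,
    run_null_analysis,
    simulate_null,
)
from conftest import make_presence


def brute_force_poisson_binomial(p):
    """Enumerate all occupancy patterns; independent check of the convolution."""
    B = len(p)
    pmf = np.zeros(B + 1)
    for pattern in itertools.product([0, 1], repeat=B):
        prob = 1.0
        for b, hit in enumerate(pattern):
            prob *= p[b] if hit else 1.0 - p[b]
        pmf[sum(pattern)] += prob
    return pmf


def enumerate_null(counts, n_species):
    """Exhaustive enumeration of all richness-constrained placements.

    Returns the exact expectations of the per-replicate BSI percentage
    vector and per-biome specialist percentage vector.
    """
    B = len(counts)
    choices = [
        list(itertools.combinations(range(n_species), c)) for c in counts
    ]
    bsi_pct = np.zeros(B)
    spec_pct = np.zeros(B)
    n_outcomes = 0
    for assign in itertools.product(*choices):
        occ = np.zeros((n_species, B), dtype=bool)
        for b, sp_set in enumerate(assign):
            occ[list(sp_set), b] = True
        K = occ.sum(axis=1)
        occupied = (K >= 1).sum()
        for k in range(1, B + 1):
            bsi_pct[k - 1] += (K == k).sum() / occupied * 100.0
        for b in range(B):
            if counts[b]:
                spec_pct[b] += (occ[:, b] & (K == 1)).sum() / counts[b] * 100.0
        n_outcomes += 1
    return bsi_pct / n_outcomes, spec_pct / n_outcomes


class TestSimulateNull:
    def test_column_sums_conserved_in_every_replicate(self):
        m = RichnessMarginals((3, 5, 2, 0, 1, 4, 2, 1, 3, 2), 8)
        ens = simulate_null(m, n_reps=200, seed=1, keep_occupancy=True)
        col_sums = ens.occupancy.sum(axis=1)
        assert (col_sums == np.asarray(m.counts)).all()

    def test_seed_determinism(self, ruminant_marginals):
        a = simulate_null(ruminant_marginals, n_reps=50, seed=9)
        b = simulate_null(ruminant_marginals, n_reps=50, seed=9)
        np.testing.assert_array_equal(a.bsi_percent, b.bsi_percent)
        np.testing.assert_array_equal(a.specialist_percent, b.specialist_percent)

    def test_single_full_biome_gives_all_specialists(self):
        m = RichnessMarginals((5, 0, 0, 0, 0, 0, 0, 0, 0, 0), 5)
        ens = simulate_null(m, n_reps=20, seed=0)
        assert (ens.bsi_percent[:, 0] == 100.0).all()
        assert (ens.specialist_percent[:, 0] == 100.0).all()
        # empty biomes are undefined, not zero
        assert np.isnan(ens.specialist_percent[:, 1]).all()

    def test_two_singleton_biomes_match_enumeration(self):
        """4 equally likely placements: expected BSI=1 share is 50%."""
        m = RichnessMarginals((1, 1), 2, labels=("A", "B"))
        exact_bsi, exact_spec = enumerate_null((1, 1), 2)
        assert exact_bsi[0] == pytest.approx(50.0)
        ens = simulate_null(m, n_reps=20_000, seed=3)
        se = ens.bsi_percent[:, 0].std(ddof=1) / np.sqrt(ens.n_reps)
        assert ens.bsi_percent[:, 0].mean() == pytest.approx(
            exact_bsi[0], abs=max(3 * se, 0.5)
        )

    def test_overfull_biome_rejected(self):
        with pytest.raises(ValueError):
            RichnessMarginals((5, 0, 0, 0, 0, 0, 0, 0, 0, 0), 4)


class TestAnalyticOracle:
    def test_matches_brute_force_enumeration(self):
        m = RichnessMarginals((3, 5, 2, 1, 4), 8,
                              labels=("a", "b", "c", "d", "e"))
        res = analytic_null_bsi(m)
        pmf = brute_force_poisson_binomial(m.occupancy_probabilities)
        np.testing.assert_allclose(
            res["bsi_pmf"], pmf[1:] / (1 - pmf[0]), atol=1e-12
        )

    def test_two_even_biomes(self):
        m = RichnessMarginals((1, 1), 2, labels=("A", "B"))
        res = analytic_null_bsi(m)
        # P(K=1 | K>=1) = 2*0.25 / 0.75
        assert res["bsi_pmf"][0] == pytest.approx(2 / 3)
        assert res["specialist_prob"][0] == pytest.approx(0.5)

    def test_single_biome_specialist_probability_is_one(self):
        m = RichnessMarginals((4, 0), 5, labels=("A", "B"))
        res = analytic_null_bsi(m)
        assert res["specialist_prob"][0] == pytest.approx(1.0)
        assert np.isnan(res["specialist_prob"][1])

    def test_simulated_specialists_agree_with_product_formula(
        self, ruminant_marginals
    ):
        ens = simulate_null(ruminant_marginals, n_reps=2_000, seed=5)
        res = analytic_null_bsi(ruminant_marginals)
        for b in range(10):
            vals = ens.specialist_percent[:, b]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert vals.mean() == pytest.approx(
                res["specialist_prob"][b] * 100, abs=3 * se + 0.05
            )


class TestEmpiricalPValue:
    def test_hand_counted_upper_tail(self):
        pv = empirical_pvalue(4.0, [1, 2, 3, 4, 5], direction="upper")
        assert pv.value == pytest.approx(2 / 5)

    def test_degenerate_ensemble_gives_one_in_both_tails(self):
        pv = empirical_pvalue(7.0, [7.0] * 10)
        assert pv.upper == 1.0 and pv.lower == 1.0

    def test_extreme_observation_displays_below_threshold(self):
        null = np.linspace(0, 1, 10_000)
        pv = empirical_pvalue(2.0, null, direction="upper")
        assert pv.value == 0.0
        assert pv.display == "<0.001"

    def test_auto_direction_picks_tail_by_mean(self):
        null = np.array([1.0, 2.0, 3.0])
        assert empirical_pvalue(3.0, null).direction == "upper"
        assert empirical_pvalue(1.0, null).direction == "lower"

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [])

    def test_superuniform_under_the_null(self):
        """Upper-tail p of a null draw is (super-)uniform."""
        m = RichnessMarginals((3, 6, 2, 4, 1), 10,
                              labels=("a", "b", "c", "d", "e"))
        ens = simulate_null(m, n_reps=400, seed=11)
        obs = simulate_null(m, n_reps=300, seed=12)
        ps = np.array([
            empirical_pvalue(o, ens.bsi_percent[:, 0], "upper").value
            for o in obs.bsi_percent[:, 0]
        ])
        for alpha in (0.1, 0.25, 0.5):
            assert (ps <= alpha).mean() <= alpha + 0.08


class TestRunNullAnalysis:
    def test_clade_filter_matching_all_equals_unfiltered(self):
        rows = {f"s{i}": ["I", "II"] if i % 2 else ["III"] for i in range(12)}
        clade = {f"s{i}": "X" for i in range(12)}
        m = make_presence(rows, clade=clade)
        full = run_null_analysis(m, n_reps=100, seed=4)
        filt = run_null_analysis(m, clade="X", n_reps=100, seed=4)
        pd.testing.assert_frame_equal(full.bsi_table, filt.bsi_table)

    def test_unknown_clade_rejected(self):
        m = make_presence({"a": ["I"]}, clade={"a": "X"})
        with pytest.raises(ValueError):
            run_null_analysis(m, clade="Y", n_reps=10, seed=0)

    def test_summary_shapes_and_sanity(self):
        m = make_presence({"a": ["I"], "b": ["I", "II"], "c": ["II"]})
        res = run_null_analysis(m, n_reps=300, seed=2)
        assert list(res.bsi_table.index) == list(range(1, 11))
        assert (res.bsi_table["p_upper"].dropna() <= 1).all()
        # null mean within observed min-max range
        t = res.bsi_table.dropna()
        assert ((t["null_mean"] >= t["null_min"]) &
                (t["null_mean"] <= t["null_max"])).all()
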