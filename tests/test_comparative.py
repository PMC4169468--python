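"""Gibbs sampler, genetic correlations, HPD intervals, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symbiocomp import comparative, phylo, simulate
from symbiocomp.comparative import (
    ModelSpec,
    PosteriorDraws,
    component_regression_compare,
    convergence_report,
    fit_multiresponse,
    genetic_correlation,
    hpd_interval,
)

from conftest import replicate_trait_table, star_tree


def _draws_from_V(V_s, n=200, V_p=None, traits=("t1", "t2")):
    T = len(traits)
    return PosteriorDraws(
        traits=list(traits), strains=["a", "b"],
        beta=np.zeros((n, T)),
        V_s=np.tile(np.asarray(V_s, float), (n, 1, 1)),
        V_p=None if V_p is None else np.tile(np.asarray(V_p, float), (n, 1, 1)),
        residual_var=np.ones((n, T)),
    )


class TestHPD:
    def test_integer_ramp(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert (lo, hi) == (1.0, 95.0)   # all windows tie; lowest start wins

    def test_identical_samples_zero_width(self):
        lo, hi = hpd_interval(np.full(500, 3.3))
        assert lo == hi == 3.3

    def test_brute_force_windows(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 1.0, 400)
        lo, hi = hpd_interval(x, 0.9)
        xs = np.sort(x)
        m = int(np.ceil(0.9 * 400))
        best = min((xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1])
                   for i in range(400 - m + 1))
        assert (lo, hi) == (best[1], best[2])

    def test_gaussian_close_to_equal_tailed(self):
        x = np.random.default_rng(2).normal(size=40_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(np.quantile(x, 0.025), abs=0.05)
        assert hi == pytest.approx(np.quantile(x, 0.975), abs=0.05)

    def test_validation(self):
        with pytest.raises(ValueError, match="mass"):
            hpd_interval(np.arange(200), 1.5)
        with pytest.raises(ValueError, match="100 samples"):
            hpd_interval(np.arange(10))


class TestGeneticCorrelation:
    def test_constant_draws(self):
        g = genetic_correlation(_draws_from_V([[1.0, 0.5], [0.5, 1.0]]), "t1", "t2")
        assert g.mean == pytest.approx(0.5)
        assert g.hpd_lower == g.hpd_upper == pytest.approx(0.5)

    def test_diagonal_draws(self):
        g = genetic_correlation(_draws_from_V(np.eye(2)), "t1", "t2")
        assert g.mean == pytest.approx(0.0)

    def test_wishart_monte_carlo_oracle(self):
        """Draws from a Wishart centred on correlation 0.75 average to ~0.75."""
        V = np.array([[1.0, 0.75], [0.75, 1.0]])
        df = 200
        rng = np.random.default_rng(3)
        Vd = stats.wishart.rvs(df=df, scale=V / df, size=10_000, random_state=rng)
        draws = PosteriorDraws(traits=["t1", "t2"], strains=["a", "b"],
                               beta=np.zeros((10_000, 2)), V_s=Vd, V_p=None,
                               residual_var=np.ones((10_000, 2)))
        g = genetic_correlation(draws, "t1", "t2")
        assert g.mean == pytest.approx(0.75, abs=0.05)
        assert np.all(np.abs(g.draws) <= 1.0)

    def test_component_lookup_errors(self):
        d = _draws_from_V(np.eye(2))
        with pytest.raises(KeyError):
            genetic_correlation(d, "t1", "t2", component="phylo")
        with pytest.raises(KeyError):
            genetic_correlation(d, "t1", "zz")


class TestConvergenceReport:
    def _draws_from_chain(self, x):
        n = len(x)
        return PosteriorDraws(traits=["t1"], strains=["a", "b"],
                              beta=x[:, None], V_s=np.ones((n, 1, 1)),
                              V_p=None, residual_var=np.ones((n, 1)))

    def test_iid_chain_passes(self):
        x = np.random.default_rng(4).normal(size=4000)
        rep = convergence_report(self._draws_from_chain(x))
        row = rep.set_index("parameter").loc["beta[t1]"]
        assert abs(row["lag1_autocorr"]) < 0.05
        assert row["pass"]

    def test_ar1_chain_fails(self):
        rng = np.random.default_rng(5)
        x = np.zeros(6000)
        for i in range(1, 6000):
            x[i] = 0.5 * x[i - 1] + rng.normal()
        rep = convergence_report(self._draws_from_chain(x)).set_index("parameter")
        assert rep.loc["beta[t1]", "lag1_autocorr"] == pytest.approx(0.5, abs=0.05)
        assert not rep.loc["beta[t1]", "pass"]
        assert not rep.attrs["pass"]

    def test_constant_chain_degenerate(self):
        rep = convergence_report(self._draws_from_chain(np.ones(500)))
        row = rep.set_index("parameter").loc["beta[t1]"]
        assert row["degenerate"] and not row["pass"]


class TestSampler:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="at least one"):
            ModelSpec(traits=("a",), include_strain_effect=False).validate()
        with pytest.raises(ValueError, match="requires"):
            ModelSpec(traits=("a",), include_phylo_effect=True).validate()
        with pytest.raises(ValueError, match="exceed"):
            ModelSpec(traits=("a",), iterations=10, burn_in=10).validate()

    def test_determinism(self):
        eff, _ = simulate.simulate_strain_effects(
            star_tree(8), np.eye(2), np.zeros((2, 2)), seed=1, trait_names=["t1", "t2"])
        tab = replicate_trait_table(eff, 4, 0.5, seed=2)
        spec = ModelSpec(traits=("t1", "t2"), iterations=600, burn_in=100, thin=2, seed=9)
        a = fit_multiresponse(tab, spec)
        b = fit_multiresponse(tab, spec)
        assert np.array_equal(a.V_s, b.V_s)
        assert np.array_equal(a.beta, b.beta)

    def test_all_draws_pd_and_r_bounded(self):
        eff, _ = simulate.simulate_strain_effects(
            star_tree(12), np.array([[1.0, 0.6], [0.6, 1.0]]), np.zeros((2, 2)),
            seed=3, trait_names=["t1", "t2"])
        tab = replicate_trait_table(eff, 6, 0.5, seed=4)
        spec = ModelSpec(traits=("t1", "t2"), iterations=2000, burn_in=400, thin=2, seed=5)
        draws = fit_multiresponse(tab, spec)
        for V in draws.V_s:
            np.linalg.cholesky(V)   # PD or raises
        g = genetic_correlation(draws, "t1", "t2")
        assert np.all(np.abs(g.draws) <= 1.0)

    def test_one_way_anova_method_of_moments_limit(self):
        """Single trait, flat prior, balanced design: posterior strain variance
        tracks the one-way random-effects method-of-moments estimate."""
        rng = np.random.default_rng(6)
        S, m, sig_s, sig_e = 40, 8, 1.0, 0.7
        u = rng.normal(0, sig_s, S)
        y = u[:, None] + rng.normal(0, sig_e, (S, m))
        tab = pd.DataFrame({
            "strain": np.repeat([f"s{i}" for i in range(S)], m),
            "trait": "t1", "value": y.ravel()})
        msb = m * y.mean(1).var(ddof=1)
        msw = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (S * (m - 1))
        mom = (msb - msw) / m
        spec = ModelSpec(traits=("t1",), prior="flat",
                         iterations=4000, burn_in=800, thin=2, seed=7)
        draws = fit_multiresponse(tab, spec)
        post_mean = draws.V_s[:, 0, 0].mean()
        # agree within Monte-Carlo and finite-S error
        assert post_mean == pytest.approx(mom, rel=0.15)

    def test_no_information_case(self):
        tab = pd.DataFrame({
            "strain": [f"s{i}" for i in range(10)] * 2,
            "trait": ["t1"] * 10 + ["t2"] * 10,
            "value": [1.0] * 10 + [2.0] * 10})
        spec = ModelSpec(traits=("t1", "t2"), iterations=2000, burn_in=500,
                         thin=2, seed=8)
        draws = fit_multiresponse(tab, spec)
        assert draws.V_s[:, 0, 0].mean() < 0.05   # concentrates near zero
        g = genetic_correlation(draws, "t1", "t2")
        assert g.hpd_upper - g.hpd_lower > 1.0    # r_g essentially unidentified

    def test_prior_sensitivity(self):
        """PX, IW and flat priors agree on well-identified data (within 0.05)."""
        eff, _ = simulate.simulate_strain_effects(
            star_tree(150), np.array([[1.0, 0.75], [0.75, 1.0]]),
            np.zeros((2, 2)), seed=9, trait_names=["t1", "t2"])
        tab = replicate_trait_table(eff, 6, 0.5, seed=10)
        means = []
        for prior in ("parameter-expanded", "inverse-wishart", "flat"):
            spec = ModelSpec(traits=("t1", "t2"), prior=prior,
                             iterations=2500, burn_in=600, thin=2, seed=11)
            draws = fit_multiresponse(tab, spec)
            means.append(genetic_correlation(draws, "t1", "t2").mean)
        assert max(means) - min(means) < 0.05

    def test_star_tree_phylo_equals_strain_model(self):
        """With A = I the phylogeny-only and strain-only models coincide."""
        eff, _ = simulate.simulate_strain_effects(
            star_tree(19), np.array([[1.0, 0.7], [0.7, 1.0]]), np.zeros((2, 2)),
            seed=12, trait_names=["t1", "t2"])
        tab = replicate_trait_table(eff, 8, 0.5, seed=13)
        A = phylo.shared_ancestry_matrix(star_tree(19))
        sp_s = ModelSpec(traits=("t1", "t2"), iterations=4000, burn_in=1000,
                         thin=3, seed=14)
        sp_p = ModelSpec(traits=("t1", "t2"), include_strain_effect=False,
                         include_phylo_effect=True, A=A,
                         iterations=4000, burn_in=1000, thin=3, seed=15)
        r_s = genetic_correlation(fit_multiresponse(tab, sp_s), "t1", "t2", "strain")
        r_p = genetic_correlation(fit_multiresponse(tab, sp_p), "t1", "t2", "phylo")
        # subsample to near-independence: KS assumes i.i.d. samples
        ks = stats.ks_2samp(r_s.draws[::10], r_p.draws[::10])
        assert ks.pvalue > 0.01

    def test_missing_trait_cells_handled(self):
        eff, _ = simulate.simulate_strain_effects(
            star_tree(12), np.array([[1.0, 0.6], [0.6, 1.0]]), np.zeros((2, 2)),
            seed=16, trait_names=["t1", "t2"])
        tab = replicate_trait_table(eff, 5, 0.5, seed=17)
        dropped = tab[~((tab["trait"] == "t2")
                        & tab["strain"].isin(eff.index[:3]))]
        spec = ModelSpec(traits=("t1", "t2"), iterations=1500, burn_in=400,
                         thin=2, seed=18)
        full = genetic_correlation(fit_multiresponse(tab, spec), "t1", "t2")
        part = genetic_correlation(fit_multiresponse(dropped, spec), "t1", "t2")
        assert abs(full.mean - part.mean) < 0.35   # changes smoothly, no error


class TestComponentRegression:
    def test_identical_components_zero_difference(self):
        V = np.array([[1.0, 0.4], [0.4, 1.0]])
        d = _draws_from_V(V, V_p=V)
        out = component_regression_compare(d, "t1", "t2")
        assert out["mean"] == pytest.approx(0.0, abs=1e-12)
        assert not out["significant"]

    def test_skipped_draw_path(self):
        V = np.array([[1.0, 0.4], [0.4, 1.0]])
        d = _draws_from_V(V, V_p=V)
        d.V_p = d.V_p.copy()
        d.V_p[:40] = 0.0   # zero predictor variance in 40 draws
        out = component_regression_compare(d, "t1", "t2")
        assert out["n_skipped"] == 40
        assert out["n_draws"] == 160
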