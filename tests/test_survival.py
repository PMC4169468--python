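"""Mixed-effect Cox models: oracles, invariants, trait construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symbiocomp import simulate, survival
from symbiocomp.simulate import SimulationConfig
from symbiocomp.survival import (
    CoxFit,
    cox_partial_loglik,
    exclude_day1_deaths,
    fit_cox_mixed,
    likelihood_ratio_test,
    per_vial_protection,
    strain_vs_control_tests,
)


def _records(days, events, strains, vials=None):
    n = len(days)
    return pd.DataFrame({
        "fly_id": [f"f{i}" for i in range(n)],
        "strain": strains,
        "treatment": ["DCV"] * n,
        "vial": vials if vials is not None else [f"v{i}" for i in range(n)],
        "day": days,
        "event": events,
    })


class TestDay1Exclusion:
    def test_counting(self):
        days = [1] * 7 + [2] * 93
        events = [1] * 7 + [1] * 93
        rec = _records(days, events, ["a"] * 100)
        assert len(exclude_day1_deaths(rec)) == 93

    def test_censored_day1_retained_and_identity(self):
        rec = _records([1, 1, 5], [0, 1, 1], ["a"] * 3)
        out = exclude_day1_deaths(rec)
        assert len(out) == 2
        assert (out["day"] == 1).sum() == 1  # the censored record stays
        no_d1 = _records([3, 4], [1, 1], ["a"] * 2)
        assert exclude_day1_deaths(no_d1).equals(no_d1)

    def test_all_day1_deaths_leads_to_no_events_error(self):
        rec = _records([1, 1, 25], [1, 1, 0], ["a", "a", "b"])
        out = exclude_day1_deaths(rec)
        with pytest.raises(ValueError, match="no events"):
            fit_cox_mixed(out, random=None, reference_strain="a")


class TestPartialLikelihoodOracles:
    def _toy(self):
        # 6 observations, no ties, two groups
        return _records(
            days=[2, 3, 5, 7, 11, 13],
            events=[1, 1, 0, 1, 1, 1],
            strains=["trt", "ref", "trt", "ref", "trt", "ref"],
        )

    @staticmethod
    def _hand_loglik(rec, beta):
        """Product of risk-set terms, written out by brute force."""
        x = (rec["strain"] == "trt").to_numpy(float)
        w = np.exp(beta * x)
        day = rec["day"].to_numpy()
        ll = 0.0
        for i in np.where(rec["event"] == 1)[0]:
            risk = day >= day[i]
            ll += beta * x[i] - np.log(w[risk].sum())
        return ll

    def test_matches_hand_computed_product(self):
        rec = self._toy()
        for beta in (-1.0, 0.0, 0.37, 1.4):
            ours = cox_partial_loglik(rec, {"strain[trt]": beta}, reference={"strain": "ref"})
            assert ours == pytest.approx(self._hand_loglik(rec, beta), abs=1e-10)

    def test_maximizer_matches_grid_search(self):
        rec = self._toy()
        fit = fit_cox_mixed(rec, random=None, reference_strain="ref")
        grid = np.linspace(-3, 3, 6001)
        lls = [self._hand_loglik(rec, b) for b in grid]
        assert fit.fixed_effects["strain[trt]"] == pytest.approx(
            grid[int(np.argmax(lls))], abs=1e-3)
        assert fit.log_partial_likelihood == pytest.approx(max(lls), abs=1e-6)

    def test_lifelines_cross_check(self):
        """Fixed-effect fits match an independent Cox implementation to 1e-4."""
        from lifelines import CoxPHFitter

        for seed in range(5):
            cfg = SimulationConfig(n_strains=3, n_vials_per_strain_per_treatment=3,
                                   flies_per_vial=10, vial_frailty_sd=0.0)
            lhr = pd.DataFrame(
                np.random.default_rng(seed).normal(0, 0.5, (3, 3)),
                index=cfg.strain_labels(), columns=list(simulate.TREATMENTS))
            rec = exclude_day1_deaths(
                simulate.simulate_survival(lhr, cfg, seed=seed, treatments=("DCV",)))
            fit = fit_cox_mixed(rec, random=None)
            X = pd.get_dummies(rec["strain"], dtype=float).drop(columns=["w_free"])
            cph = CoxPHFitter().fit(
                pd.concat([X, rec[["day", "event"]]], axis=1), "day", "event")
            for name, val in fit.fixed_effects.items():
                assert val == pytest.approx(cph.params_[name[7:-1]], abs=1e-4)

    def test_monotone_day_relabeling_invariance(self):
        """The partial likelihood is a rank statistic of the event days."""
        rng = np.random.default_rng(5)
        rec = _records(
            days=rng.integers(1, 10, 40), events=rng.integers(0, 2, 40),
            strains=rng.choice(["ref", "trt"], 40))
        rec.loc[0, "event"] = 1
        mapping = {d: int(d**2 + 3) for d in range(0, 11)}   # increasing map
        rec2 = rec.assign(day=rec["day"].map(mapping))
        for beta in (0.0, 0.5):
            a = cox_partial_loglik(rec, {"strain[trt]": beta}, reference={"strain": "ref"})
            b = cox_partial_loglik(rec2, {"strain[trt]": beta}, reference={"strain": "ref"})
            assert a == pytest.approx(b, abs=1e-12)


class TestMixedModel:
    def test_frailty_zero_equals_fixed_effect_fit(self):
        cfg = SimulationConfig(n_strains=3, n_vials_per_strain_per_treatment=4,
                               flies_per_vial=10, vial_frailty_sd=0.0)
        lhr = pd.DataFrame(0.3, index=cfg.strain_labels(), columns=list(simulate.TREATMENTS))
        rec = exclude_day1_deaths(
            simulate.simulate_survival(lhr, cfg, seed=2, treatments=("DCV",)))
        fixed = fit_cox_mixed(rec, random=None)
        mixed0 = fit_cox_mixed(rec, frailty_variance=0.0)
        for name in fixed.fixed_effects.index:
            assert mixed0.fixed_effects[name] == pytest.approx(
                fixed.fixed_effects[name], abs=1e-4)
        assert np.allclose(mixed0.vial_effects, 0.0, atol=1e-6)

    def test_censoring_mass_conservation(self, small_study):
        rec = exclude_day1_deaths(small_study["survival"])
        n_events = (rec["event"] == 1).sum()
        n_cens = (rec["event"] == 0).sum()
        assert n_events + n_cens == len(rec)

    def test_frailty_variance_recovery(self):
        cfg = SimulationConfig(n_strains=2, n_vials_per_strain_per_treatment=40,
                               flies_per_vial=20, vial_frailty_sd=0.5,
                               day1_injury_death_rate=0.0)
        lhr = pd.DataFrame(0.0, index=cfg.strain_labels(), columns=list(simulate.TREATMENTS))
        rec = exclude_day1_deaths(
            simulate.simulate_survival(lhr, cfg, seed=3, treatments=("DCV",)))
        fit = fit_cox_mixed(rec)
        assert 0.05 < fit.frailty_variance < 0.8   # truth 0.25

    def test_hazard_monotonicity_of_protection(self):
        """Higher simulated hazard => strictly lower mean protection trait."""
        means = []
        for log_hr in (-0.6, 0.0, 0.6):
            cfg = SimulationConfig(n_strains=1, n_vials_per_strain_per_treatment=12,
                                   flies_per_vial=20, vial_frailty_sd=0.1)
            lhr = pd.DataFrame({"DCV": [log_hr]}, index=cfg.strain_labels())
            rec = exclude_day1_deaths(
                simulate.simulate_survival(lhr, cfg, seed=8, treatments=("DCV",)))
            fit = fit_cox_mixed(rec)
            prot = per_vial_protection(fit)
            means.append(prot[prot["strain"] == "wSim01"]["value"].mean())
        assert means[0] > means[1] > means[2]


class TestLRT:
    def _two_fits(self):
        cfg = SimulationConfig(n_strains=3, n_vials_per_strain_per_treatment=3,
                               flies_per_vial=10, vial_frailty_sd=0.0)
        lhr = pd.DataFrame(0.4, index=cfg.strain_labels(), columns=list(simulate.TREATMENTS))
        rec = exclude_day1_deaths(
            simulate.simulate_survival(lhr, cfg, seed=4, treatments=("DCV",)))
        full = fit_cox_mixed(rec, fixed_terms=("strain",), random=None)
        reduced = fit_cox_mixed(rec, fixed_terms=(), random=None)
        return full, reduced

    def test_full_vs_reduced(self):
        full, reduced = self._two_fits()
        chi2, df, p = likelihood_ratio_test(full, reduced)
        assert chi2 >= 0
        assert df == 3
        assert p == pytest.approx(stats.chi2.sf(chi2, df))

    def test_identical_models(self):
        full, _ = self._two_fits()
        chi2, df, p = likelihood_ratio_test(full, full)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_non_nested_rejected(self):
        full, reduced = self._two_fits()
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(reduced, full)


class TestProtectionTraits:
    def _fake_fit(self, coefs, vials):
        names = [f"strain[{s}]" for s in coefs]
        return CoxFit(
            fixed_effects=pd.Series(list(coefs.values()), index=names),
            se=pd.Series(1.0, index=names),
            frailty_variance=0.1,
            vial_effects=pd.Series({v: b for v, (_, b) in vials.items()}),
            vial_strain={v: s for v, (s, _) in vials.items()},
            log_partial_likelihood=0.0, integrated_loglik=0.0,
            n_events=1, n_records=1, fixed_terms=("strain",),
        )

    def test_sign_convention(self):
        fit = self._fake_fit({"wX": -0.7}, {"v1": ("wX", 0.0), "v2": ("w_free", 0.0)})
        prot = per_vial_protection(fit).set_index("vial")
        assert prot.loc["v1", "value"] == pytest.approx(0.7)   # protective
        assert prot.loc["v2", "value"] == pytest.approx(0.0)   # reference baseline

    def test_vial_effect_enters(self):
        fit = self._fake_fit({"wX": -0.7}, {"v1": ("wX", 0.2)})
        assert per_vial_protection(fit)["value"].iloc[0] == pytest.approx(0.5)

    def test_recovery_correlation(self):
        """Mean per-vial trait tracks the generating -log HR across strains."""
        cfg = SimulationConfig(n_strains=10, n_vials_per_strain_per_treatment=12,
                               flies_per_vial=20, vial_frailty_sd=0.2)
        rng = np.random.default_rng(6)
        true = pd.Series(rng.normal(0, 0.7, 10), index=cfg.strain_labels())
        lhr = pd.DataFrame({"DCV": -true})
        rec = exclude_day1_deaths(
            simulate.simulate_survival(lhr, cfg, seed=6, treatments=("DCV",)))
        fit = fit_cox_mixed(rec)
        prot = per_vial_protection(fit)
        est = prot.groupby("strain")["value"].mean().drop("w_free")
        r = np.corrcoef(est[true.index], true)[0, 1]
        assert r > 0.9


class TestWaldTests:
    def test_z_and_p(self):
        fit = CoxFit(
            fixed_effects=pd.Series({"strain[a]": 0.0, "strain[b]": -1.96,
                                     "strain[c]": 2.0}),
            se=pd.Series({"strain[a]": 1.0, "strain[b]": 1.0, "strain[c]": np.inf}),
            frailty_variance=0.0, vial_effects=pd.Series(dtype=float), vial_strain={},
            log_partial_likelihood=0.0, integrated_loglik=0.0,
            n_events=1, n_records=1, fixed_terms=("strain",),
        )
        out = strain_vs_control_tests(fit).set_index("strain")
        assert out.loc["a", "p"] == pytest.approx(1.0)
        assert out.loc["b", "p"] == pytest.approx(0.05, abs=1e-3)
        assert out.loc["c", "p"] == 1.0
        assert out.loc["c", "flag"] == "non-identified"
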