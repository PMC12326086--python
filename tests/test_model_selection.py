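"""Transforms, VIF pruning, subset enumeration, LMM fitting and selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_track_df
from flocktrace import model_selection as ms
from flocktrace.errors import DegenerateInputError, ParameterError, SelectionError


class TestTransform:
    def test_sqrt(self):
        assert ms.apply_transform([25.0], "sqrt")[0] == 5.0

    def test_identity(self):
        np.testing.assert_array_equal(ms.apply_transform([3.0, 4.0], "identity"),
                                      [3.0, 4.0])

    def test_negative_sqrt_rejected(self):
        with pytest.raises(ParameterError):
            ms.apply_transform([-1.0], "sqrt")


class TestVif:
    def frame(self, cols):
        return pd.DataFrame(cols)

    def test_exact_collinearity_drops_later_term(self):
        rng = np.random.default_rng(41)
        x1 = rng.normal(size=400)
        d = self.frame({"flight_time": x1, "iteration": 2.0 * x1,
                        "group_size": rng.normal(size=400)})
        kept, removed = ms.vif_prune(d, ["flight_time", "iteration", "group_size"])
        assert "group_size" in kept
        assert removed[0][0] == "iteration"  # later-ordered offender
        assert "flight_time" in kept

    def test_correlated_pair_vif_value(self):
        """r = 0.95 between two predictors gives VIF 1/(1-r^2) ~ 10.26 > 5,
        so one of the pair is removed."""
        rng = np.random.default_rng(43)
        n = 20_000
        x1 = rng.normal(size=n)
        x2 = 0.95 * x1 + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=n)
        d = self.frame({"flight_time": x1, "iteration": x2})
        X, blocks = ms._design_by_term(d, ["flight_time", "iteration"])
        vifs = ms.generalized_vif(X, blocks)
        assert vifs["flight_time"] == pytest.approx(10.26, abs=0.6)
        kept, removed = ms.vif_prune(d, ["flight_time", "iteration"])
        assert len(kept) == 1 and len(removed) == 1

    def test_orthogonal_predictors_all_retained(self):
        rng = np.random.default_rng(47)
        d = self.frame({"flight_time": rng.normal(size=500),
                        "iteration": rng.normal(size=500),
                        "group_size": rng.normal(size=500)})
        kept, removed = ms.vif_prune(d, ["flight_time", "iteration", "group_size"])
        assert set(kept) == {"flight_time", "iteration", "group_size"}
        assert removed == []
        X, blocks = ms._design_by_term(d, kept)
        assert max(ms.generalized_vif(X, blocks).values()) < 1.05

    def test_interaction_not_tested_against_parents(self):
        d = make_track_df(np.random.default_rng(53), n_lofts=1,
                          birds_per_loft=4, n_per_bird=100)
        terms = ["habitat", "iteration", "habitat:iteration"]
        kept, _ = ms.vif_prune(d, terms)
        assert "habitat:iteration" in kept


class TestEnumerate:
    def test_three_mains(self):
        specs = ms.enumerate_subsets(["flight_time", "iteration", "group_size"],
                                     "speed")
        assert len(specs) == 8

    def test_marginality_with_interaction(self):
        specs = ms.enumerate_subsets(["habitat", "flight_time",
                                      "habitat:flight_time"], "speed")
        got = {frozenset(s.fixed_terms) for s in specs}
        assert got == {frozenset(), frozenset({"habitat"}),
                       frozenset({"flight_time"}),
                       frozenset({"habitat", "flight_time"}),
                       frozenset({"habitat", "flight_time", "habitat:flight_time"})}

    def test_single_term(self):
        assert len(ms.enumerate_subsets(["iteration"], "speed")) == 2

    def test_count_matches_closed_form(self):
        """Subset count equals sum over main subsets of 2^(admissible
        interactions)."""
        import itertools
        mains = ["habitat", "flight_time", "iteration", "group_size"]
        ints = ["habitat:flight_time", "habitat:iteration"]
        specs = ms.enumerate_subsets(mains + ints, "speed")
        expect = 0
        for r in range(len(mains) + 1):
            for sub in itertools.combinations(mains, r):
                k = sum(all(p in sub for p in i.split(":")) for i in ints)
                expect += 2 ** k
        assert len(specs) == expect

    def test_spec_rejects_orphan_interaction(self):
        with pytest.raises(ParameterError):
            ms.ModelSpec("speed", ("habitat:flight_time",))


class TestFitLmm:
    def test_noiseless_coefficient_recovery(self):
        rng = np.random.default_rng(59)
        d = make_track_df(rng, resid_sd=0.0, bird_sd=0.5, loft_sd=0.3,
                          speed_effects={"open": 0.0, "wooded": 0.0, "urban": 0.0})
        d["speed"] = d["speed"] + 2.0 * d["flight_time"] / 100.0
        fit = ms.fit_lmm(ms.ModelSpec("speed", ("flight_time",)), d)
        est = fit.coefficients.query("term == 'flight_time'")["estimate"].iloc[0]
        # 0.001 baseline slope from the generator plus the injected 0.02
        assert est == pytest.approx(0.021, abs=1e-6)

    def test_zero_variance_flagged_singular(self):
        # habitat exposure balanced within every bird and residuals demeaned
        # within bird: between-bird variance is exactly zero whatever the
        # fitted habitat coefficients, so the ML estimate sits on the boundary
        rng = np.random.default_rng(61)
        rows = []
        habs = ["open", "wooded", "urban"] * 20
        effects = {"open": 0.0, "wooded": -0.7, "urban": 0.7}
        for loft in "LNR":
            for b in range(6):
                bird = f"{loft}{b}"
                eps = rng.normal(0, 0.5, len(habs))
                eps -= eps.mean()
                for h, e in zip(habs, eps):
                    rows.append(dict(loft_id=loft, bird_id=bird, habitat=h,
                                     speed=17.9 + effects[h] + e))
        d = pd.DataFrame(rows)
        fit = ms.fit_lmm(ms.ModelSpec("speed", ("habitat",)), d)
        assert fit.singular

    def test_intercept_only_r2_zero(self):
        rng = np.random.default_rng(67)
        d = make_track_df(rng)
        fit = ms.fit_lmm(ms.ModelSpec("speed", ()), d)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_within_2se(self):
        """Habitat fixed effects recovered within 2 SE in >=90% of 50
        seeded replicates."""
        rng = np.random.default_rng(71)
        hits, total = 0, 0
        for _ in range(50):
            d = make_track_df(rng, n_lofts=3, birds_per_loft=5, n_per_bird=40)
            fit = ms.fit_lmm(ms.ModelSpec("speed", ("habitat", "flight_time")), d)
            co = fit.coefficients
            for level, truth in (("urban", 0.7), ("wooded", -0.7)):
                row = co[co["coefficient"].str.contains(f"T.{level}", regex=False)]
                est, se = row["estimate"].iloc[0], row["se"].iloc[0]
                total += 1
                hits += abs(est - truth) <= 2 * se
        assert hits / total >= 0.9


class TestSelectBest:
    def fake(self, aic, r2, n_terms):
        terms = tuple(f"t{i}" for i in range(n_terms))
        spec = ms.ModelSpec("speed", terms)
        return ms.ModelFit(spec, aic, r2, 100, False, True, pd.DataFrame())

    def test_delta_aic_window_then_r2(self):
        A = self.fake(100.0, 0.30, 1)
        B = self.fake(101.5, 0.32, 2)
        C = self.fake(103.0, 0.40, 3)
        assert ms.select_best([A, B, C]) is B

    def test_r2_tie_at_5dp_prefers_fewest_terms(self):
        A = self.fake(100.0, 0.300001, 2)
        B = self.fake(101.9, 0.300004, 4)
        assert ms.select_best([A, B]) is A

    def test_single_candidate(self):
        A = self.fake(50.0, 0.1, 1)
        assert ms.select_best([A]) is A

    def test_order_invariance(self):
        fits = [self.fake(100.0 + 0.1 * i, 0.2 + 0.01 * i, i % 4)
                for i in range(10)]
        orderings = [fits, fits[::-1], fits[3:] + fits[:3], fits[7:] + fits[:7]]
        chosen = {id(ms.select_best(list(o))) for o in orderings}
        assert len(chosen) == 1

    def test_all_singular_raises(self):
        A = self.fake(100.0, 0.3, 1)
        A.singular = True
        with pytest.raises(SelectionError):
            ms.select_best([A])


class TestCooks:
    def test_closed_form_matches_leave_one_out(self):
        """Closed-form Cook's distances equal brute-force LOO refits."""
        rng = np.random.default_rng(73)
        n, p = 120, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta = np.array([1.0, 2.0, -1.0])
        y = X @ beta + rng.normal(0, 0.5, n)
        D = ms.cooks_distances(X, y)
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = float((y - X @ bhat) @ (y - X @ bhat)) / (n - p)
        XtX = X.T @ X
        for i in range(n):
            mask = np.arange(n) != i
            bi, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            diff = bhat - bi
            d_brute = float(diff @ XtX @ diff) / (p * s2)
            assert D[i] == pytest.approx(d_brute, abs=1e-8)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(79)
        n = 50
        x = rng.normal(size=n)
        y = x + rng.normal(0, 0.1, n)
        y[17] += 10.0  # 100 sigma shift
        X = np.column_stack([np.ones(n), x])
        D = ms.cooks_distances(X, y)
        assert np.argmax(D) == 17
        assert D[17] > 4 / n
        assert (np.delete(D, 17) <= 4 / n).all()

    def test_refit_no_outliers_unchanged(self):
        rng = np.random.default_rng(83)
        d = make_track_df(rng, n_lofts=2, birds_per_loft=4, n_per_bird=30)
        fit = ms.fit_lmm(ms.ModelSpec("speed", ("habitat",)), d)
        refit, removed = ms.cooks_refit(fit, d, threshold=np.inf)
        assert removed == 0
        assert refit.n_obs == fit.n_obs


class TestLayerIndependence:
    def frame(self, rng, n=1200, n_birds=4, determined=False):
        # n chosen so expected cell counts are ~100: the likelihood-ratio
        # statistic is anti-conservative with small cells
        birds = [f"b{i}" for i in range(n_birds)]
        bird = rng.choice(birds, size=n)
        if determined:
            habs = dict(zip(birds, ["open", "wooded", "urban", "open"]))
            habitat = np.array([habs[b] for b in bird])
        else:
            habitat = rng.choice(["open", "wooded", "urban"], size=n)
        return pd.DataFrame({"bird_id": bird, "habitat": habitat})

    def test_type_i_error_rate(self):
        """With habitat independent of bird, the test rejects at 5% rarely
        (>=94% non-significant over 100 replicates)."""
        rng = np.random.default_rng(90)
        nonsig = 0
        for _ in range(100):
            _, _, p = ms.layer_independence_check(self.frame(rng), "bird_id")
            nonsig += p >= 0.05
        assert nonsig >= 94

    def test_perfect_dependence_detected(self):
        rng = np.random.default_rng(97)
        _, _, p = ms.layer_independence_check(
            self.frame(rng, determined=True), "bird_id")
        assert p < 1e-6

    def test_single_level_errors(self):
        d = pd.DataFrame({"bird_id": ["a", "b"], "habitat": ["open", "open"]})
        with pytest.raises(DegenerateInputError):
            ms.layer_independence_check(d, "bird_id")
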