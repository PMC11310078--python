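"""Propensity fitting, optimal full matching (vs exhaustive enumeration),
balance metrics and pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ctmatch import matching as mat


# ---------------------------------------------------------------------------
# enumeration oracle: all full-matching partitions of a tiny instance
# ---------------------------------------------------------------------------

def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def enumerate_min_full_match(lp_t, lp_c):
    """Minimum total distance over every valid full-matching partition:
    each block has >=1 treated, >=1 control and one side singleton."""
    units = [("t", i) for i in range(len(lp_t))] + [
        ("c", j) for j in range(len(lp_c))
    ]
    best = np.inf
    for part in set_partitions(units):
        ok = True
        cost = 0.0
        for block in part:
            ts = [i for s, i in block if s == "t"]
            cs = [j for s, j in block if s == "c"]
            if not ts or not cs or (len(ts) > 1 and len(cs) > 1):
                ok = False
                break
            cost += sum(
                abs(lp_t[i] - lp_c[j]) for i in ts for j in cs
            )
        if ok and cost < best:
            best = cost
    return best


def fake_model(lp: pd.Series) -> mat.PropensityModel:
    scores = 1 / (1 + np.exp(-lp))
    return mat.PropensityModel([], pd.Series(dtype=float), scores, lp)


def frame(lp_t, lp_c, **extra):
    ids = [f"t{i}" for i in range(len(lp_t))] + [f"c{j}" for j in
                                                 range(len(lp_c))]
    d = pd.DataFrame({
        "tract_id": ids,
        "treated": [True] * len(lp_t) + [False] * len(lp_c),
        "state": "S1",
        "mine_baseline": False,
    })
    lp = pd.Series(list(lp_t) + list(lp_c), index=ids)
    for k, v in extra.items():
        d[k] = v
    return d, fake_model(lp)


class TestFullMatchOracle:
    def test_matches_enumeration_on_random_tiny_instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(60):
            nt = rng.integers(1, 5)
            nc = rng.integers(1, 6)
            lp_t = rng.normal(0, 1, nt)
            lp_c = rng.normal(0, 1, nc)
            d, model = frame(lp_t, lp_c)
            ms = mat.full_match(d, model, exact_keys=())
            oracle = enumerate_min_full_match(lp_t, lp_c)
            assert ms.total_distance == pytest.approx(oracle, abs=1e-9)

    def test_forced_two_subclass_solution(self):
        # treated {0.2, 0.8}, controls {0.1, 0.3, 0.9}: the optimum pairs
        # the first treated with the two nearby controls and the second
        # with the far one, total distance 0.3
        d, model = frame([0.2, 0.8], [0.1, 0.3, 0.9])
        ms = mat.full_match(d, model, exact_keys=())
        assert ms.total_distance == pytest.approx(0.3, abs=1e-9)
        subs = {tuple(sorted(ts)): tuple(sorted(cs)) for ts, cs in
                ms.subclasses}
        assert subs == {("t0",): ("c0", "c1"), ("t1",): ("c2",)}

    def test_identical_multisets_pair_at_zero_distance(self):
        d, model = frame([0.1, 0.5, 0.9], [0.5, 0.1, 0.9])
        ms = mat.full_match(d, model, exact_keys=())
        assert ms.total_distance == pytest.approx(0.0, abs=1e-12)

    def test_att_weights_per_subclass(self):
        d, model = frame([0.5], [0.4, 0.6])
        ms = mat.full_match(d, model, exact_keys=())
        assert ms.weights["t0"] == 1.0
        assert ms.weights["c0"] == pytest.approx(0.5)
        assert ms.weights["c1"] == pytest.approx(0.5)


class TestFullMatchStructure:
    def _landscape_cohort(self, small_landscape):
        from ctmatch import cohorts as coh

        _, tracts, _, _ = small_landscape
        t = tracts.copy()
        t["forest_pct_2000"] = 100 * t["forest_2000_km2"] / t["area_km2"]
        cohort = coh.build_cohort(t, coh.CohortSpec("SPA"))
        data = t[t["tract_id"].isin(cohort.treated_ids + cohort.control_ids)]
        return data.assign(treated=data["tract_id"].isin(cohort.treated_ids))

    def test_exactness_and_weight_calibration(self, small_landscape):
        data = self._landscape_cohort(small_landscape)
        covs = ["travel_time_h", "pop_density", "forest_pct_2000"]
        model = mat.fit_propensity(data, covs)
        ms = mat.full_match(data, model)
        d = data.set_index("tract_id")
        for ts, cs in ms.subclasses:
            strata = {
                (d.loc[u, "state"], bool(d.loc[u, "mine_baseline"]))
                for u in ts + cs
            }
            assert len(strata) == 1  # no subclass spans exact strata
            assert len(ts) >= 1 and len(cs) >= 1
            assert len(ts) == 1 or len(cs) == 1
        w = ms.weights
        matched = d.loc[w.index]
        for _, grp in matched.groupby(["state", "mine_baseline"],
                                      observed=True):
            tmask = grp["treated"]
            assert w[grp.index[tmask]].sum() == pytest.approx(
                w[grp.index[~tmask]].sum(), abs=1e-9
            )

    def test_caliper_drops_far_treated(self):
        d, model = frame([0.0, 50.0], [0.1, 0.2, 0.3])
        ms = mat.full_match(d, model, exact_keys=(), caliper=1.0)
        dropped = dict(ms.dropped)
        assert "t1" in dropped
        assert all(t != "t1" for ts, _ in ms.subclasses for t in ts)

    def test_all_treated_dropped_raises(self):
        d, model = frame([100.0], [0.1, 0.2])
        with pytest.raises(mat.MatchingError):
            mat.full_match(d, model, exact_keys=(), caliper=0.01)

    def test_stratum_without_controls_dropped_and_logged(self):
        d, model = frame([0.2, 0.4], [0.3])
        d.loc[d["tract_id"] == "t1", "state"] = "S2"  # no controls in S2
        ms = mat.full_match(d, model)
        assert ("t1", "stratum lacks controls") in ms.dropped
        assert len(ms.subclasses) == 1

    def test_sparse_solver_agrees_with_dense(self, monkeypatch):
        rng = np.random.default_rng(7)
        lp_t = rng.normal(0.5, 1, 30)
        lp_c = rng.normal(0, 1, 200)
        d, model = frame(lp_t, lp_c)
        dense = mat.full_match(d, model, exact_keys=())
        monkeypatch.setattr(mat, "_SPARSE_EDGE_LIMIT", 100)
        sparse = mat.full_match(d, model, exact_keys=())
        # sparsification is a documented approximation; it must stay close
        assert sparse.total_distance <= dense.total_distance * 1.05 + 1e-6


class TestPropensity:
    def test_two_by_two_closed_form(self):
        # treated: 3 exposed of 4; control: 1 exposed of 4 -> log OR log(9)
        d = pd.DataFrame({
            "tract_id": [f"u{i}" for i in range(8)],
            "treated": [True] * 4 + [False] * 4,
            "x": [1, 1, 1, 0, 1, 0, 0, 0],
        })
        model = mat.fit_propensity(d, ["x"])
        sd = d["x"].std(ddof=0)
        coef_raw = model.coefficients["x"] / sd
        assert coef_raw == pytest.approx(np.log(9.0), rel=1e-4)

    def test_balanced_groups_give_null_slopes(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        d = pd.DataFrame({
            "tract_id": [f"u{i}" for i in range(400)],
            "treated": np.tile([True, False], 200),
            "x": x,
        })
        model = mat.fit_propensity(d, ["x"])
        # z-score of the slope under exchangeability
        assert abs(model.coefficients["x"]) < 2 * 2 / np.sqrt(400)

    def test_scores_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        tr = rng.uniform(size=100) < 1 / (1 + np.exp(-x))
        d = pd.DataFrame({"tract_id": range(100), "treated": tr, "x": x})
        d2 = d.assign(x=5.0 * d["x"] - 3.0)
        s1 = mat.fit_propensity(d, ["x"]).scores
        s2 = mat.fit_propensity(d2, ["x"]).scores
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_perfect_separation_raises(self):
        d = pd.DataFrame({
            "tract_id": range(20),
            "treated": [True] * 10 + [False] * 10,
            "x": list(range(10, 20)) + list(range(10)),
        })
        with pytest.raises(mat.MatchingError, match="separation"):
            mat.fit_propensity(d, ["x"])

    def test_missing_covariates_excluded_listwise(self):
        d = pd.DataFrame({
            "tract_id": [f"u{i}" for i in range(8)],
            "treated": [True] * 4 + [False] * 4,
            "x": [1.0, np.nan, 1, 0, 1, 0, 0, np.nan],
        })
        model = mat.fit_propensity(d, ["x"])
        assert set(model.dropped_missing) == {"u1", "u7"}
        assert len(model.scores) == 6


class TestSMD:
    def test_formula(self):
        v = [2.0, 2.0, 1.0, 1.0]
        t = [True, True, False, False]
        assert mat.standardized_mean_difference(v, t, denom_sd=2.0) == \
            pytest.approx(0.5)

    def test_identical_groups_zero(self):
        v = [1.0, 2.0, 1.0, 2.0]
        t = [True, True, False, False]
        got = mat.standardized_mean_difference(v, t)
        assert got == pytest.approx(0.0)

    def test_weighted_post_match_hand_computation(self):
        # subclass 1: t0 with c0 (w 1); subclass 2: t1 with c1, c2 (w .5)
        v = np.array([3.0, 5.0, 2.0, 4.0, 6.0])
        t = np.array([True, True, False, False, False])
        w = np.array([1.0, 1.0, 1.0, 0.5, 0.5])
        # treated mean 4; control mean (2*1 + 4*.5 + 6*.5)/2 = 3.5
        sd_t = np.std([3.0, 5.0], ddof=1)
        got = mat.standardized_mean_difference(v, t, w, denom_sd=sd_t)
        assert got == pytest.approx(0.5 / sd_t)

    def test_degenerate_denominator_flagged(self):
        v = [1.0, 1.0, 0.0, 2.0]
        t = [True, True, False, False]
        assert np.isnan(mat.standardized_mean_difference(v, t))


class TestPruning:
    def _confounded_data(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        conf = rng.normal(size=n)
        noise_cov = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(conf - 0.5)))
        tr = rng.uniform(size=n) < p
        return pd.DataFrame({
            "tract_id": [f"u{i}" for i in range(n)],
            "treated": tr,
            "conf": conf,
            "noise": noise_cov,
        })

    def test_balanced_input_no_drops(self):
        rng = np.random.default_rng(1)
        n = 800
        d = pd.DataFrame({
            "tract_id": [f"u{i}" for i in range(n)],
            "treated": np.tile([True, False], n // 2),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })
        _, _, report, log = mat.prune_covariates(d, ["a", "b"], exact_keys=())
        assert log == []
        assert (report["smd_after"].abs() < 0.25).all()

    def test_balance_improves_on_confounded_data(self):
        improved = 0
        for seed in range(10):
            d = self._confounded_data(seed)
            model = mat.fit_propensity(d, ["conf", "noise"])
            ms = mat.full_match(d, model, exact_keys=())
            rep = mat.balance_report(d, ["conf", "noise"], ms)
            if rep["smd_after"].abs().mean() < rep["smd_before"].abs().mean():
                improved += 1
        assert improved >= 9

    def test_pruning_monotone_never_worsens(self):
        d = self._confounded_data(2)
        # degrade: an extreme-scale pure-noise covariate
        rng = np.random.default_rng(3)
        d["noise"] = rng.normal(scale=100.0, size=len(d))
        _, _, report, log = mat.prune_covariates(
            d, ["conf", "noise"], exact_keys=(), smd_threshold=0.01
        )
        maxes = [e["max_abs_smd"] for e in log]
        assert all(a >= b for a, b in zip(maxes, maxes[1:]))
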