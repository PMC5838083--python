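"""Habitat model: assembly, GVIF, the binomial GAMM, selection, ensemble."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import cpforage.model as mdl


def _synthetic_table(n=600, n_groups=12, beta1=2.0, beta2=0.0, group_sd=0.0,
                     seed=0, balanced=False):
    """Logistic-model table with known coefficients on two covariates."""
    rng = np.random.default_rng(seed)
    per = (n // n_groups) // 2 * 2  # even group size for balanced labels
    n = per * n_groups
    grp = np.repeat([f"A{i:02d}" for i in range(n_groups)], per)
    x1 = rng.uniform(0, 1, n)
    x2 = rng.uniform(0, 1, n)
    b = rng.normal(0, group_sd, n_groups)
    eta = beta1 * (x1 - 0.5) + beta2 * (x2 - 0.5) + np.repeat(b, per)
    if balanced:
        y = np.concatenate([rng.permutation(np.repeat([0, 1], per // 2))
                            for _ in range(n_groups)])
    else:
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"c1": x1, "c2": x2, "animal_id": grp, "presence": y})


class TestAssembleDataset:
    def _matchups(self):
        rows = []
        for animal, trips in [("A", {"A_T01": 9, "A_T02": 12}),
                              ("B", {"B_T01": 7})]:
            for trip, n in trips.items():
                dates = pd.date_range("2006-11-01", periods=n, freq="D")
                for src, sim in [("presence", ""), ("pseudoabsence", "o0"),
                                 ("pseudoabsence", "o1"),
                                 ("pseudoabsence", "i0")]:
                    for d in dates:
                        rows.append({"source": src, "animal_id": animal,
                                     "trip_id": trip, "sim_id": sim,
                                     "date": d, "lon": -121.0, "lat": 34.0,
                                     "sst": 15.0, "bathymetry": -500.0})
        return pd.DataFrame(rows)

    def test_most_locations_trip_kept(self):
        out = mdl.assemble_dataset(self._matchups(), seed=0)
        assert set(out[out["animal_id"] == "A"]["trip_id"]) == {"A_T02"}

    def test_one_to_one_balance(self):
        out = mdl.assemble_dataset(self._matchups(), seed=0)
        counts = out.groupby(["animal_id", "presence"]).size().unstack()
        assert (counts[0] == counts[1]).all()

    def test_tie_broken_by_duration(self):
        m = self._matchups()
        # make A_T01 span 12 calendar days with 12 locations too,
        # A_T02 span 12 locations over 11 days: durations differ
        rows = []
        dates_long = pd.date_range("2006-12-01", periods=12, freq="2D")
        for src, sim in [("presence", ""), ("pseudoabsence", "o0")]:
            for d in dates_long:
                rows.append({"source": src, "animal_id": "A",
                             "trip_id": "A_T03", "sim_id": sim, "date": d,
                             "lon": -121.0, "lat": 34.0, "sst": 15.0,
                             "bathymetry": -500.0})
        m = pd.concat([m, pd.DataFrame(rows)], ignore_index=True)
        out = mdl.assemble_dataset(m, seed=0)
        assert set(out[out["animal_id"] == "A"]["trip_id"]) == {"A_T03"}

    def test_too_few_individuals_raises(self):
        m = self._matchups()
        with pytest.raises(ValueError):
            mdl.assemble_dataset(m[m["animal_id"] == "A"], seed=0)


class TestGVIF:
    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(rng.normal(size=(10000, 4)),
                           columns=["a", "b", "c", "d"])
        out = mdl.gvif_check(tab, ["a", "b", "c", "d"])
        assert out["gvif"].between(1.0, 1.1).all()
        assert not out["flagged"].any()

    def test_duplicated_covariate_is_aliased(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({"a": rng.normal(size=500)})
        tab["b"] = tab["a"]
        tab["c"] = rng.normal(size=500)
        with pytest.raises(ValueError, match="alias"):
            mdl.gvif_check(tab, ["a", "b", "c"])

    def test_strongly_correlated_pair_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=20000)
        b = 0.99 * a + np.sqrt(1 - 0.99 ** 2) * rng.normal(size=20000)
        tab = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=20000)})
        out = mdl.gvif_check(tab, ["a", "b", "c"]).set_index("covariate")
        # closed form: VIF = 1/(1-r^2) ~ 50
        assert out.loc["a", "gvif"] == pytest.approx(1 / (1 - 0.99 ** 2), rel=0.1)
        assert out.loc["a", "flagged"] and out.loc["b", "flagged"]
        assert not out.loc["c", "flagged"]


class TestRocAuc:
    def test_perfect_separation(self):
        assert mdl.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert mdl.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_enumerated_example(self):
        assert mdl.roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mdl.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_all_pairs_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(10, 200)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 2)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert mdl.roc_auc(y, s) == pytest.approx(brute, abs=1e-12)


class TestFit:
    def test_strong_monotone_covariate_recovered(self):
        tab = _synthetic_table(n=600, beta1=6.0, seed=6)
        fit = mdl.fit_binomial_gamm(tab, mdl.ModelSpec(covariates=["c1", "c2"]))
        assert fit.auc >= 0.8
        pr = fit.partial_responses["c1"]
        mid = pr[(pr["x"] > 0.05) & (pr["x"] < 0.95)]
        assert (np.diff(mid["fit"].values) > -1e-6).all()

    def test_null_group_effect_variance_near_zero(self):
        tab = _synthetic_table(n=800, beta1=2.0, group_sd=0.0, seed=7)
        fit = mdl.fit_binomial_gamm(tab, mdl.ModelSpec(covariates=["c1", "c2"]))
        assert fit.random_intercept_var < 1e-3

    def test_real_group_effect_detected(self):
        tab = _synthetic_table(n=1200, beta1=1.0, group_sd=1.5, seed=8)
        fit = mdl.fit_binomial_gamm(tab, mdl.ModelSpec(covariates=["c1", "c2"]))
        assert fit.random_intercept_var > 0.1

    def test_type_one_error_rate_at_strict_alpha(self):
        """Under the null, p < .001 occurs in at most 5% of replicates."""
        alphas = None
        hits = trials = 0
        for rep in range(100):
            tab = _synthetic_table(n=500, beta1=0.0, seed=1000 + rep,
                                   balanced=True)
            fit = mdl.fit_binomial_gamm(
                tab, mdl.ModelSpec(covariates=["c1", "c2"]), alphas=alphas)
            if alphas is None:
                alphas = fit.alphas
            for s in fit.smooths:
                trials += 1
                hits += s.p_value < 0.001
        assert hits / trials <= 0.05

    def test_permuted_labels_auc_centered_at_half(self, balanced_null_table):
        rng = np.random.default_rng(9)
        spec = mdl.ModelSpec(covariates=["c1", "c2"])
        aucs = []
        for _ in range(50):
            perm = balanced_null_table.copy()
            perm["presence"] = perm.groupby("animal_id")["presence"].transform(
                lambda s: rng.permutation(s.values))
            fit = mdl.fit_binomial_gamm(perm, spec, alphas=[30.0, 30.0, 30.0])
            aucs.append(fit.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.02

    def test_aic_improves_with_active_covariate(self):
        tab = _synthetic_table(n=600, beta1=3.0, seed=10)
        null_fit = mdl.fit_binomial_gamm(tab, mdl.ModelSpec(covariates=["c2"]))
        full_fit = mdl.fit_binomial_gamm(tab, mdl.ModelSpec(covariates=["c1", "c2"]))
        assert full_fit.aic <= null_fit.aic + 2.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_fit_agrees_with_mgcv_reference(tmp_path):
    """Cross-check fitted probabilities against an mgcv binomial GAM."""
    tab = _synthetic_table(n=500, beta1=2.5, beta2=-1.5, group_sd=0.8, seed=11)
    fit = mdl.fit_binomial_gamm(tab, mdl.ModelSpec(covariates=["c1", "c2"]))
    csv = tmp_path / "tab.csv"
    tab.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(f"""
library(mgcv)
d <- read.csv("{csv}")
d$animal_id <- factor(d$animal_id)
m <- gam(presence ~ s(c1, k=4) + s(c2, k=4) + s(animal_id, bs="re"),
         family=binomial, data=d, method="REML")
write.csv(data.frame(p=fitted(m)), "{tmp_path / 'fitted.csv'}", row.names=FALSE)
""")
    subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "fitted.csv")["p"].values
    ours = fit.fitted  # conditional fitted values, as mgcv reports
    from scipy.stats import spearmanr
    assert spearmanr(ours, ref).statistic > 0.9
    assert mdl.roc_auc(tab["presence"], ours) == pytest.approx(
        mdl.roc_auc(tab["presence"], ref), abs=0.05)


class TestSelectModel:
    def _table(self):
        return _synthetic_table(n=400, beta1=3.0, beta2=0.0, seed=12)

    def test_concordant_choice(self):
        tab = self._table()
        good = mdl.ModelSpec(covariates=["c1"], name="signal")
        bad = mdl.ModelSpec(covariates=["c2"], name="noise")
        best, ranking = mdl.select_model([good, bad], tab)
        assert best.name == "signal"
        assert ranking["aic"].is_monotonic_increasing

    def test_single_candidate_raises(self):
        with pytest.raises(ValueError):
            mdl.select_model([mdl.ModelSpec(covariates=["c1"])], self._table())


class TestEnsemble:
    def _matchups(self, n_sims_per_phase=1):
        """Matchup-like table where each trip has a controllable CRW pool."""
        rng = np.random.default_rng(13)
        rows = []
        for a in range(6):
            animal = f"A{a}"
            trip = f"{animal}_T01"
            dates = pd.date_range("2006-11-01", periods=10, freq="D")
            for d in dates:
                x = rng.uniform(0, 1)
                rows.append({"source": "presence", "animal_id": animal,
                             "trip_id": trip, "sim_id": "", "date": d,
                             "lon": 0.0, "lat": 0.0, "c1": x + 0.8,
                             "c2": rng.uniform(0, 1)})
            for k in range(n_sims_per_phase):
                for d in dates:
                    rows.append({"source": "pseudoabsence",
                                 "animal_id": animal, "trip_id": trip,
                                 "sim_id": f"o{k}", "date": d, "lon": 0.0,
                                 "lat": 0.0, "c1": rng.uniform(0, 1),
                                 "c2": rng.uniform(0, 1)})
        return pd.DataFrame(rows)

    def test_single_crw_pool_gives_identical_runs(self):
        ens = mdl.run_ensemble(mdl.ModelSpec(covariates=["c1", "c2"]),
                               self._matchups(1), n_runs=5, seed=1)
        for cov in ("c1", "c2"):
            assert ens.n_significant[cov] in (0, ens.n_runs)
            mean, mn, mx = ens.edf[cov]
            assert mn == pytest.approx(mx)

    def test_aggregates_ordered(self):
        ens = mdl.run_ensemble(mdl.ModelSpec(covariates=["c1", "c2"]),
                               self._matchups(3), n_runs=8, seed=2)
        for agg in (ens.aic, ens.auc, ens.deviance_explained,
                    *ens.edf.values(), *ens.chi_sq.values()):
            mean, mn, mx = agg
            assert mn <= mean <= mx

    def test_report_layout(self):
        ens = mdl.run_ensemble(mdl.ModelSpec(covariates=["c1", "c2"]),
                               self._matchups(2), n_runs=4, seed=3)
        text = ens.report()
        assert "n-significant" in text
        assert "AUC" in text and "AIC" in text
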