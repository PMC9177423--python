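"""Hierarchical beta-binomial growth model: HPDI, overdispersion, fits, outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import clonekinetics as ck
from clonekinetics.model import MCMCConfig, assign_effect_labels
from clonekinetics.simulate import LONGITUDINAL_COLUMNS


def brute_force_hpdi(samples, mass):
    """O(n^2) oracle: scan every window of ceil(mass*n) sorted points."""
    s = np.sort(np.asarray(samples, dtype=float))
    w = int(np.ceil(mass * len(s)))
    best = None
    for i in range(len(s) - w + 1):
        width = s[i + w - 1] - s[i]
        if best is None or width < best[0] - 0:
            best = (width, s[i], s[i + w - 1])
    return best[1], best[2]


class TestHPDI:
    def test_degenerate_identical_samples(self):
        iv = ck.hpdi([3.5] * 20, 0.9)
        assert iv.lower == iv.upper == 3.5

    def test_integer_window_earliest_tie_break(self):
        iv = ck.hpdi(np.arange(1, 101), 0.90)
        assert (iv.lower, iv.upper) == (1, 90)
        assert iv.upper - iv.lower == 89

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=rng.integers(10, 60))
            mass = rng.uniform(0.5, 0.95)
            lo, hi = brute_force_hpdi(x, mass)
            iv = ck.hpdi(x, mass)
            assert iv.lower == lo and iv.upper == hi

    def test_standard_normal_quantiles(self, rng):
        iv = ck.hpdi(rng.normal(size=100_000), 0.90)
        assert abs(iv.lower + 1.645) < 0.05
        assert abs(iv.upper - 1.645) < 0.05

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            ck.hpdi(np.arange(20), 1.2)
        with pytest.raises(ValueError):
            ck.hpdi(np.arange(5), 0.9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-1e6, 1e6), min_size=10, max_size=200),
        mass=st.floats(0.1, 0.95),
    )
    def test_interval_contains_requested_mass(self, data, mass):
        iv = ck.hpdi(data, mass)
        arr = np.asarray(data)
        inside = np.mean((arr >= iv.lower) & (arr <= iv.upper))
        assert inside >= mass - 1e-12


class TestOverdispersion:
    def test_parameter_recovery_within_25pct(self):
        """30 triplicate groups at depth 2000 recover beta=100 within 25%."""
        reps = ck.generate_replicates(
            [0.05, 0.02, 0.01], depth=2000, beta_od=100.0, k=3, seed=3,
            groups_per_vaf=10,
        )
        od = ck.estimate_overdispersion(reps, mode="triplicate")
        assert abs(od.mu_od - 100.0) / 100.0 < 0.25
        assert od.n_posterior >= 1000

    def test_near_binomial_data_estimates_large_beta(self):
        """With essentially binomial replicates the fitted beta is large enough
        that the implied beta-binomial variance is within 5% of binomial."""
        reps = ck.generate_replicates(
            [0.05, 0.02, 0.01], depth=2000, beta_od=1e5, k=3, seed=4,
            groups_per_vaf=10,
        )
        od = ck.estimate_overdispersion(reps, mode="triplicate")
        n, q = 2000, 0.05
        alpha = od.mu_od * q / (1 - q)
        bb_var = n * q * (1 - q) * (alpha + od.mu_od + n) / (alpha + od.mu_od + 1)
        assert bb_var / (n * q * (1 - q)) < 1.05

    def test_disjoint_replicate_sets_agree(self):
        ests = []
        for seed in (10, 20):
            reps = ck.generate_replicates(
                [0.05, 0.02, 0.01], depth=2000, beta_od=100.0, k=3, seed=seed,
                groups_per_vaf=10,
            )
            ests.append(ck.estimate_overdispersion(reps, mode="triplicate"))
        assert abs(ests[0].mu_od - ests[1].mu_od) < 2 * (
            ests[0].sigma_od + ests[1].sigma_od
        )

    def test_all_zero_groups_error(self):
        df = pd.DataFrame(
            {"group_id": ["a", "a", "b", "b", "c", "c"],
             "depth": [100] * 6, "alt_count": [0] * 6}
        )
        reps = ck.ReplicateSet(df=df)
        with pytest.raises(ValueError, match="zero"):
            ck.estimate_overdispersion(reps)

    def test_dilution_mode_pools_same_vaf_groups(self):
        reps = ck.generate_replicates([0.05, 0.02], depth=2000, beta_od=100.0,
                                      k=3, seed=5, groups_per_vaf=5)
        od = ck.estimate_overdispersion(reps, mode="dilution")
        assert od.mu_od > 0


class TestEffectLabels:
    def _df(self, rows):
        data = [(r[0], f"c{i}", r[1], r[2], r[3], 60.0, 100, 5)
                for i, r in enumerate(rows)]
        return pd.DataFrame(data, columns=LONGITUDINAL_COLUMNS)

    def test_recurrent_site_needs_two_individuals(self):
        df = self._df([
            ("i1", "JAK2", "V617F", "missense"),
            ("i2", "JAK2", "V617F", "missense"),
            ("i3", "TET2", "X100", "missense"),
        ])
        cg, cs, genes, sites = assign_effect_labels(df)
        assert "JAK2:V617F" in sites
        assert "TET2:X100" not in sites

    def test_single_mutation_gene_is_site_only(self):
        """A gene present only as one recurrent hotspot has no gene effect."""
        df = self._df([
            ("i1", "JAK2", "V617F", "missense"),
            ("i2", "JAK2", "V617F", "missense"),
            ("i1", "DNMT3A", "R882H", "missense"),
            ("i2", "DNMT3A", "Q606X", "truncating"),
        ])
        cg, cs, genes, sites = assign_effect_labels(df)
        assert all(v is None for c, v in cg.items() if "JAK2" in str(cs[c]) or cs[c] == "JAK2:V617F")
        assert "JAK2" not in genes

    def test_truncating_and_missense_split(self):
        df = self._df([
            ("i1", "DNMT3A", "R882H", "missense"),
            ("i2", "DNMT3A", "Q606X", "truncating"),
        ])
        _, _, genes, _ = assign_effect_labels(df)
        assert set(genes) == {"DNMT3A:M", "DNMT3A:T"}

    def test_site_rule_collapses_when_one_carrier_remains(self, od_calibrated, fast_mcmc):
        """Dropping all but one carrier of a recurrent site removes b_site."""
        ds = ck.sample_model_cohort({"GENE_A": 0.1}, 4, [60, 70], depth=500,
                                    beta_od=120.0, seed=3)
        df = ds.df.copy()
        df["site"] = "H100"
        fit_all = ck.fit_trajectories(
            ck.LongitudinalDataset(df=df), od_calibrated,
            fast_mcmc.reduced(iterations=400, leapfrog_steps=15),
        )
        assert "GENE_A:H100" in fit_all.site_labels
        keep = df["individual_id"] == df["individual_id"].iloc[0]
        fit_one = ck.fit_trajectories(
            ck.LongitudinalDataset(df=df[keep].reset_index(drop=True)),
            od_calibrated, fast_mcmc.reduced(iterations=400, leapfrog_steps=15),
        )
        assert fit_one.site_labels == []


class TestFitTrajectories:
    def test_noiseless_logistic_recovery(self, single_clone_fit):
        """Exact-logistic counts (b=0.2, u=-12) are recovered within 0.02 and
        the 90% HPDI covers the truth."""
        _, fit = single_clone_fit
        bt = fit.b_total("c1")
        assert abs(np.mean(bt) - 0.2) < 0.02
        iv = ck.hpdi(bt)
        assert iv.lower <= 0.2 <= iv.upper
        assert abs(np.mean(fit.u_draws("c1")) + 12) < 1.0

    def test_flat_trajectory_hpdi_contains_zero(self, od_calibrated, fast_mcmc):
        rng = np.random.default_rng(8)
        rows = [("i1", "c1", "G", "", "missense", float(a), 2000,
                 int(rng.binomial(2000, 0.08))) for a in (55, 60, 65, 70, 75)]
        ds = ck.LongitudinalDataset(df=pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS))
        fit = ck.fit_trajectories(ds, od_calibrated, fast_mcmc)
        iv = ck.hpdi(fit.b_total("c1"))
        assert iv.lower <= 0.0 <= iv.upper

    def test_gene_ordering_recovered(self, small_cohort_fit):
        """Gene B (0.05/yr) vs gene C (0.15/yr): posterior means rank correctly
        and HPDIs cover the truth."""
        _, fit = small_cohort_fit
        means = {g: float(np.mean(fit.b_gene[:, i]))
                 for i, g in enumerate(fit.gene_labels)}
        assert means["GENE_C"] > means["GENE_B"] > means["GENE_A"] - 0.02
        for g, truth in (("GENE_B", 0.05), ("GENE_C", 0.15)):
            iv = ck.hpdi(fit.b_gene[:, fit.gene_labels.index(g)])
            assert iv.lower - 0.02 <= truth <= iv.upper + 0.02

    def test_time_translation_invariance(self, od_calibrated):
        """Shifting all ages by +5 years shifts u but leaves b_total alone."""
        ds = ck.sample_model_cohort({"G": 0.15}, 3, [60, 65, 70, 75], depth=3000,
                                    beta_od=120.0, seed=5)
        mc = MCMCConfig(iterations=1200, leapfrog_steps=40, chains=2, seed=7)
        fit_a = ck.fit_trajectories(ds, od_calibrated, mc)
        df2 = ds.df.copy()
        df2["age_years"] += 5
        fit_b = ck.fit_trajectories(ck.LongitudinalDataset(df=df2), od_calibrated, mc)
        for cid in fit_a.clone_ids:
            ba, bb = np.mean(fit_a.b_total(cid)), np.mean(fit_b.b_total(cid))
            sd = np.std(fit_a.b_total(cid))
            assert abs(ba - bb) < 4 * sd + 0.01
            ua, ub = np.mean(fit_a.u_draws(cid)), np.mean(fit_b.u_draws(cid))
            assert abs((ua - ub) - 5 * ba) < 1.0

    def test_fitted_vaf_bounded_and_monotone(self, single_clone_fit):
        _, fit = single_clone_fit
        ages = np.linspace(0, 100, 21)
        qs = np.array([np.mean(fit.q_draws("c1", a)) for a in ages])
        assert np.all((qs > 0) & (qs < 1))
        assert np.all(np.diff(qs) > 0)  # b_total > 0 here

    def test_all_zero_clone_flagged_uninformative(self, od_calibrated, fast_mcmc):
        rows = [("i1", "c0", "G", "", "missense", float(a), 500, 0)
                for a in (60, 65, 70)]
        rows += [("i1", "c1", "G", "", "missense", float(a), 500, 40)
                 for a in (60, 65, 70)]
        ds = ck.LongitudinalDataset(df=pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS))
        fit = ck.fit_trajectories(
            ds, od_calibrated, fast_mcmc.reduced(iterations=400, leapfrog_steps=15)
        )
        assert fit.uninformative == ["c0"]

    def test_single_timepoint_clone_rejected(self, od_calibrated, fast_mcmc):
        rows = [("i1", "c1", "G", "", "missense", 60.0, 500, 10)]
        ds = ck.LongitudinalDataset(df=pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS))
        with pytest.raises(ValueError, match="fewer than 2"):
            ck.fit_trajectories(ds, od_calibrated, fast_mcmc)

    def test_summary_schema(self, single_clone_fit, tmp_path):
        _, fit = single_clone_fit
        summ = fit.summary()
        assert list(summ.columns) == ["entity", "type", "mean", "median",
                                      "hpdi_low", "hpdi_high"]
        assert set(summ["type"]) == {"gene", "clone", "offset", "overdispersion"}
        fit.save_draws(tmp_path / "draws.json")
        back = ck.GrowthPosterior.load_draws(tmp_path / "draws.json")
        assert np.allclose(back.b_total("c1"), fit.b_total("c1"))


class TestOutliers:
    def test_central_point_not_outlier(self, single_clone_fit):
        ds, fit = single_clone_fit
        report = ck.flag_outliers(fit, ds)
        assert not report.observations["outlier"].any()
        assert report.fixed_rate_proportion == 1.0
        assert report.ci_low < 1.0 and report.ci_high > 0.9

    def test_extreme_zero_count_is_flagged(self, single_clone_fit):
        """Expected VAF ~0.2 at depth 1000 but observed 0: tail < 1e-10."""
        ds, fit = single_clone_fit
        df = ds.df.copy()
        # age 72.8 gives q ~ 0.93 for (b=0.2,u=-12); use age where q~0.2
        age = (np.log(0.2 / 0.8) + 12) / 0.2
        df = pd.concat([df, pd.DataFrame(
            [("i1", "c1", "GENEX", "", "missense", age, 1000, 0)],
            columns=LONGITUDINAL_COLUMNS)], ignore_index=True)
        report = ck.flag_outliers(fit, ck.LongitudinalDataset(df=df))
        tail = report.observations["tail_probability"].iloc[-1]
        assert tail < 1e-10
        assert report.observations["outlier"].iloc[-1]
        assert not report.clones.set_index("clone_id").loc["c1", "fixed_rate"]

    def test_missing_clone_errors(self, single_clone_fit):
        ds, fit = single_clone_fit
        df = ds.df.copy()
        df.loc[0, "clone_id"] = "unknown"
        with pytest.raises(KeyError):
            ck.flag_outliers(fit, ck.LongitudinalDataset(df=df))

    def test_tail_probability_matches_exact_betabinomial(self, single_clone_fit):
        """Quadrature tails agree with exact beta-binomial summation."""
        from clonekinetics.model import _bb_tails_quadrature

        n, k = 500, 40
        alpha, beta = 12.0, 120.0
        gl_x, gl_w = np.polynomial.legendre.leggauss(48)
        nodes, weights = 0.5 * (gl_x + 1), 0.5 * gl_w
        lo, up = _bb_tails_quadrature(
            np.array([float(k)]), np.array([float(n)]),
            np.array([alpha]), np.array([beta]), nodes, weights,
        )
        exact_lo = stats.betabinom.cdf(k, n, alpha, beta)
        exact_up = 1 - stats.betabinom.cdf(k - 1, n, alpha, beta)
        assert abs(lo[0] - exact_lo) < 2e-3
        assert abs(up[0] - exact_up) < 2e-3


class TestPrediction:
    def test_in_sample_consistency(self, single_clone_fit):
        ds, fit = single_clone_fit
        last = ds.df.iloc[-1]
        pred, iv = ck.predict_vaf(fit, "c1", last["age_years"])
        obs = last["alt_count"] / last["depth"]
        assert abs(pred - obs) < 0.02
        assert iv.lower <= pred <= iv.upper

    def test_flat_clone_prediction_constant(self, od_calibrated, fast_mcmc):
        rng = np.random.default_rng(2)
        rows = [("i1", "c1", "G", "", "missense", float(a), 5000,
                 int(rng.binomial(5000, 0.1))) for a in (60, 65, 70)]
        ds = ck.LongitudinalDataset(df=pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS))
        fit = ck.fit_trajectories(ds, od_calibrated, fast_mcmc)
        p_now, _ = ck.predict_vaf(fit, "c1", 70)
        p_future, _ = ck.predict_vaf(fit, "c1", 85)
        assert abs(p_future - p_now) < 0.05

    def test_unknown_clone_errors(self, single_clone_fit):
        _, fit = single_clone_fit
        with pytest.raises(KeyError):
            ck.predict_vaf(fit, "nope", 80.0)

    def test_heldout_mae_small_on_simulated_cohort(self, small_cohort_fit, od_calibrated):
        """Refit without the final timepoint; held-out MAE < 5 VAF points."""
        ds, _ = small_cohort_fit
        last_age = ds.df["age_years"].max()
        train = ck.LongitudinalDataset(
            df=ds.df[ds.df["age_years"] < last_age].reset_index(drop=True)
        )
        hold = ds.df[ds.df["age_years"] == last_age].reset_index(drop=True)
        fit = ck.fit_trajectories(
            train, od_calibrated,
            MCMCConfig(iterations=1600, leapfrog_steps=40, chains=2, seed=3),
        )
        mae = ck.prediction_mae(fit, hold)
        assert mae < 5.0
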