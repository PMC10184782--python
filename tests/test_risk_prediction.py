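"""Feature assembly and the leakage-safe random-forest protocol."""

import numpy as np
import pandas as pd
import pytest

from genomerisk import risk_prediction as rp, synthetic_cohort as syn
from genomerisk.errors import InsufficientDataError, InvalidParameterError


def cohort_matrix(seed=0, n=120, **kw):
    tree = syn.generate_tree(n, 1.0, seed=seed)
    params = syn.CohortParams(n_species=n, seed=seed, **kw)
    c = syn.simulate_species_traits(tree, params)
    f = c.features
    eco = f.filter(like="eco_")
    return rp.build_feature_matrix(
        f[list(syn.SUMMARY_COLUMNS)], f.threatened.astype(object), ecological=eco)


class TestBuildFeatureMatrix:
    def test_groups_and_dimensions(self):
        fm = cohort_matrix(seed=1, n=60)
        assert len(fm.columns_for(("summary",))) == 13
        assert len(fm.columns_for(("ecological",))) == 39
        assert fm.data.shape == (60, 52)

    def test_missing_group_allowed(self):
        s = pd.DataFrame({"a": [1.0, 2, 3]}, index=["x", "y", "z"])
        fm = rp.build_feature_matrix(s, pd.Series([True, False, True], index=s.index))
        assert set(fm.groups.values()) == {"summary"}
        with pytest.raises(InvalidParameterError):
            fm.columns_for(("ecological",))

    def test_unknown_species_in_join_named(self):
        s = pd.DataFrame({"a": [1.0, 2]}, index=["x", "y"])
        eco = pd.DataFrame({"e": [1.0]}, index=["zz"])
        with pytest.raises(InvalidParameterError, match="zz"):
            rp.build_feature_matrix(s, pd.Series([True, False], index=s.index), ecological=eco)

    def test_duplicate_species_rejected(self):
        s = pd.DataFrame({"a": [1.0, 2]}, index=["x", "x"])
        with pytest.raises(InvalidParameterError, match="duplicate"):
            rp.build_feature_matrix(s, pd.Series([True, False], index=s.index))

    def test_variance_filter_keeps_top_k(self, rng):
        s = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        w = pd.DataFrame(rng.standard_normal((50, 20)) * 1.5 ** np.arange(20),
                         columns=[f"w{i}" for i in range(20)], index=s.index)
        fm = rp.build_feature_matrix(s, pd.Series(True, index=s.index), windows=w)
        filt = rp.variance_filter(fm, top_k=5)
        kept = [c for c in filt.data.columns if filt.groups[c] == "windows"]
        assert kept == [f"w{i}" for i in range(15, 20)]


class TestTrainRf:
    def test_informative_feature_near_perfect(self):
        fm = cohort_matrix(seed=2, n=80)
        leaky = fm.data.copy()
        leaky["ne_harmonic"] = fm.labels.astype(float)  # plant a label copy
        fm2 = rp.FeatureMatrix(leaky, fm.groups, fm.labels)
        tm = rp.train_rf(fm2, ("summary",), seed=0, grid=rp.SMALL_GRID)
        assert tm.report.auroc >= 0.99

    def test_permuted_labels_null(self):
        fm = cohort_matrix(seed=3, n=100)
        rng = np.random.default_rng(0)
        aurocs = []
        for rep in range(20):
            perm = rp.FeatureMatrix(
                fm.data, fm.groups,
                pd.Series(rng.permutation(fm.labels.to_numpy()), index=fm.labels.index))
            tm = rp.train_rf(perm, ("summary",), seed=rep, grid=rp.SMALL_GRID)
            aurocs.append(tm.report.auroc)
        assert 0.40 <= np.mean(aurocs) <= 0.60

    def test_imputation_fit_on_training_rows_only(self):
        """A sentinel extreme value planted in a held-out row must not move
        the imputer's statistics."""
        fm = cohort_matrix(seed=4, n=80)
        y = fm.labels.astype(bool).to_numpy()
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(y))
        tr, te = train_test_split(idx, test_size=0.25, stratify=y, random_state=0)
        tm1 = rp.train_rf(fm, ("summary",), seed=0, grid=rp.SMALL_GRID, split=(tr, te))
        data = fm.data.copy()
        col = "ne_harmonic"
        data.iloc[te[0], data.columns.get_loc(col)] = 1e12  # sentinel in test row
        tm2 = rp.train_rf(rp.FeatureMatrix(data, fm.groups, fm.labels),
                          ("summary",), seed=0, grid=rp.SMALL_GRID, split=(tr, te))
        s1 = tm1.pipeline.named_steps["impute"].statistics_
        s2 = tm2.pipeline.named_steps["impute"].statistics_
        assert np.array_equal(s1, s2)

    def test_too_few_species(self):
        fm = cohort_matrix(seed=5, n=60)
        small = rp.FeatureMatrix(fm.data.iloc[:30], fm.groups, fm.labels.iloc[:30])
        with pytest.raises(InsufficientDataError):
            rp.train_rf(small, ("summary",), grid=rp.SMALL_GRID)

    def test_single_class_rejected(self):
        fm = cohort_matrix(seed=6, n=60)
        ones = rp.FeatureMatrix(fm.data, fm.groups,
                                pd.Series(True, index=fm.labels.index, dtype=object))
        with pytest.raises(InvalidParameterError):
            rp.train_rf(ones, ("summary",), grid=rp.SMALL_GRID)

    def test_determinism(self):
        fm = cohort_matrix(seed=7, n=80)
        a = rp.train_rf(fm, ("summary",), seed=5, grid=rp.SMALL_GRID)
        b = rp.train_rf(fm, ("summary",), seed=5, grid=rp.SMALL_GRID)
        assert a.report.auroc == b.report.auroc
        assert a.report.best_params == b.report.best_params


class TestCompareFeatureSets:
    def test_ecological_signal_dominates_when_planted(self):
        """Cohorts where the ecological factor drives threat rank the
        ecological model above the summary model in most seeds."""
        wins = 0
        reps = 15
        for s in range(reps):
            fm = cohort_matrix(seed=s, n=100,
                               beta_threat_ne=-0.15, beta_threat_eco=0.85)
            rep = rp.compare_feature_sets(
                fm, seed=s, group_sets=(("summary",), ("ecological",)),
                grid=rp.SMALL_GRID)
            r = rep.set_index("group_set").auroc
            wins += r["ecological"] > r["summary"]
        assert wins >= 0.8 * reps

    def test_summary_signal_reverses_ordering(self):
        wins = 0
        reps = 15
        for s in range(reps):
            fm = cohort_matrix(seed=100 + s, n=100,
                               beta_threat_ne=-0.85, beta_threat_eco=0.1)
            rep = rp.compare_feature_sets(
                fm, seed=s, group_sets=(("summary",), ("ecological",)),
                grid=rp.SMALL_GRID)
            r = rep.set_index("group_set").auroc
            wins += r["summary"] > r["ecological"]
        assert wins >= 0.8 * reps

    def test_identical_seed_identical_reports(self):
        fm = cohort_matrix(seed=8, n=80)
        a = rp.compare_feature_sets(fm, seed=1, grid=rp.SMALL_GRID)
        b = rp.compare_feature_sets(fm, seed=1, grid=rp.SMALL_GRID)
        pd.testing.assert_frame_equal(a, b)


class TestPredictUnlabeled:
    def make_dd(self, seed=9, n=90):
        fm = cohort_matrix(seed=seed, n=n)
        labels = fm.labels.copy()
        dd = list(labels.index[:3])
        labels.loc[dd] = np.nan
        return rp.FeatureMatrix(fm.data, fm.groups, labels), dd

    def test_probability_consistency_with_training_twin(self):
        fm, dd = self.make_dd()
        # make a DD species an exact copy of a labeled one
        data = fm.data.copy()
        twin_src = fm.labels.dropna().index[0]
        data.loc[dd[0]] = data.loc[twin_src]
        fm2 = rp.FeatureMatrix(data, fm.groups, fm.labels)
        model = rp.train_rf(fm2, ("summary",), seed=0, grid=rp.SMALL_GRID)
        probs, refusals = rp.predict_unlabeled(model, fm2)
        x = data.loc[[twin_src], list(model.feature_columns)].to_numpy(float)
        p_src = model.pipeline.predict_proba(x)[0][
            list(model.pipeline.classes_).index(True)]
        assert abs(probs[dd[0]] - p_src) <= 0.1

    def test_missing_group_is_refused(self):
        fm, dd = self.make_dd()
        data = fm.data.copy()
        eco_cols = [c for c, g in fm.groups.items() if g == "ecological"]
        data.loc[dd[0], eco_cols] = np.nan
        fm2 = rp.FeatureMatrix(data, fm.groups, fm.labels)
        model = rp.train_rf(fm2, ("ecological",), seed=0, grid=rp.SMALL_GRID)
        probs, refusals = rp.predict_unlabeled(model, fm2)
        assert dd[0] in refusals and dd[0] not in probs.index

    def test_extreme_low_ne_high_load_ranks_high(self):
        """A DD species planted at the risky extreme scores above the
        cohort median threat probability in most seeds."""
        hits = 0
        reps = 10
        for s in range(reps):
            fm, dd = self.make_dd(seed=200 + s, n=90)
            data = fm.data.copy()
            lab = fm.labels.dropna().astype(bool)
            risky = dd[0]
            data.loc[risky, "ne_harmonic"] = data["ne_harmonic"].quantile(0.02)
            for c in ("prop_missense_fixed", "prop_missense_het", "froh"):
                data.loc[risky, c] = data[c].quantile(0.98)
            fm2 = rp.FeatureMatrix(data, fm.groups, fm.labels)
            model = rp.train_rf(fm2, ("summary",), seed=s, grid=rp.SMALL_GRID)
            probs, _ = rp.predict_unlabeled(model, fm2)
            cols = list(model.feature_columns)
            all_p = model.pipeline.predict_proba(
                data.loc[lab.index, cols].to_numpy(float))[:,
                list(model.pipeline.classes_).index(True)]
            hits += probs[risky] > np.median(all_p)
        assert hits >= 0.9 * reps
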