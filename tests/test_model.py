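"""Threshold-optimizing mixed ANOVA, biomarker regressions, selection and
the voting classifier."""

import numpy as np
import pandas as pd
import pytest

from pbmnet import constants
from pbmnet.model import (
    BiomarkerRegression,
    ModelError,
    VotingClassifier,
    fit_biomarker_model,
    fit_biomarker_regressions,
    mixed_anova_interaction,
    optimize_threshold,
    predict_subject,
    predictor_matrix,
    rmanova_group_by_period,
    select_biomarkers,
    voting_score,
)


def pingouin_interaction(x, g):
    """Independent oracle: pingouin's mixed ANOVA on long-format data."""
    import pingouin as pg

    S, P = x.shape
    df = pd.DataFrame(
        {
            "y": x.ravel(),
            "subj": np.repeat(np.arange(S), P),
            "period": np.tile(np.arange(P), S),
            "grp": np.repeat(g, P),
        }
    )
    aov = pg.mixed_anova(df, dv="y", within="period", subject="subj", between="grp")
    row = aov[aov.Source == "Interaction"].iloc[0]
    return float(row["F"]), float(row["p_unc"]), (int(row["DF1"]), int(row["DF2"]))


class TestMixedAnova:
    @pytest.mark.parametrize("n1,n2", [(8, 8), (14, 15), (5, 9)])
    def test_matches_pingouin(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        g = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
        x = rng.standard_normal((n1 + n2, 5))
        x[~g] += np.linspace(0, 1, 5)
        F, p, df = rmanova_group_by_period(x, g)
        F2, p2, df2 = pingouin_interaction(x, g)
        assert F == pytest.approx(F2, rel=1e-10)
        assert p == pytest.approx(p2, rel=1e-10)
        assert df == df2

    def test_identical_values_degenerate_p_one(self):
        x = np.full((10, 5), 2.0)
        g = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        with pytest.warns(RuntimeWarning, match="degenerate"):
            F, p, _ = rmanova_group_by_period(x, g)
        assert p == 1.0

    def test_planted_interaction_detected(self):
        """One group drifting +1/period vs a flat group, noise SD 0.1: the
        interaction should be overwhelmingly significant."""
        rng = np.random.default_rng(5)
        hits = 0
        reps = 30
        for _ in range(reps):
            g = np.r_[np.ones(8, bool), np.zeros(8, bool)]
            x = 0.1 * rng.standard_normal((16, 5))
            x[g] += np.arange(5)
            _, p, _ = rmanova_group_by_period(x, g)
            hits += p < 0.01
        assert hits >= 0.95 * reps

    def test_null_p_uniform_under_permutation(self):
        """Permuting group labels on planted data yields uniform p-values."""
        from scipy import stats as st

        rng = np.random.default_rng(6)
        ps = []
        for _ in range(300):
            g = rng.permutation(np.r_[np.ones(8, bool), np.zeros(8, bool)])
            x = rng.standard_normal((16, 5))
            _, p, _ = rmanova_group_by_period(x, g)
            ps.append(p)
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        x = np.zeros((3, 5))
        with pytest.raises(ModelError):
            mixed_anova_interaction(x, np.array([True, False, False]))

    def test_vectorized_matches_single(self):
        rng = np.random.default_rng(8)
        g = np.r_[np.ones(6, bool), np.zeros(7, bool)]
        batch = rng.standard_normal((4, 13, 5))
        Fb, pb, _ = mixed_anova_interaction(batch, g)
        for k in range(4):
            F, p, _ = mixed_anova_interaction(batch[k], g)
            assert Fb[k] == pytest.approx(F) and pb[k] == pytest.approx(p)


class TestOptimizeThreshold:
    @staticmethod
    def _table(rng, n_sub=12, signal_idx=None):
        x = rng.standard_normal((n_sub, 3, 3, constants.THRESHOLD_GRID.size, 5))
        if signal_idx is not None:
            g = np.r_[np.ones(n_sub // 2, bool), np.zeros(n_sub - n_sub // 2, bool)]
            x[np.ix_(np.flatnonzero(g))] += 0.0
            x[np.flatnonzero(g)[:, None, None, None, None],
              np.arange(3)[None, :, None, None, None] * 0, 0, signal_idx, :] += \
                np.arange(5) * 2.0
        return x

    def test_scan_shape_and_grid(self, rng):
        x = rng.standard_normal((10, 3, 3, 51, 5))
        g = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        scan = optimize_threshold(x, g)
        assert scan.p.shape == (3, 3, 51)
        assert scan.chosen.shape == (3, 3)
        assert np.all(np.isin(scan.chosen, constants.THRESHOLD_GRID))

    def test_planted_signal_threshold_recovered(self, rng):
        """Group separation injected at one grid index is found there."""
        g = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        x = rng.standard_normal((12, 3, 3, 51, 5)) * 0.05
        target = 17
        x[np.flatnonzero(g), 0, 0, target, :] += np.arange(5)
        scan = optimize_threshold(x, g)
        assert scan.chosen_idx[0, 0] == target

    def test_tie_broken_toward_smallest_threshold(self):
        """A scan with identical p everywhere picks index 0 (smallest)."""
        rng = np.random.default_rng(1)
        base = rng.standard_normal((10, 1, 1, 1, 5))
        x = np.tile(base, (1, 3, 3, 51, 1))  # every threshold identical
        g = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        scan = optimize_threshold(x, g)
        assert np.all(scan.chosen_idx == 0)
        assert np.all(scan.chosen == constants.THRESHOLD_GRID[0])

    def test_chosen_attains_min_p(self, rng):
        x = rng.standard_normal((14, 3, 3, 51, 5))
        g = np.r_[np.ones(7, bool), np.zeros(7, bool)]
        scan = optimize_threshold(x, g)
        assert np.allclose(
            np.take_along_axis(scan.p, scan.chosen_idx[..., None], axis=-1)[..., 0],
            scan.p.min(axis=-1),
        )


class TestRegressions:
    def test_perfect_linear_relationship(self, rng):
        x = rng.standard_normal((20, 3, 3, 5))
        y = 2.0 * x[:, 0, 0, 0] + 1.0
        regs = fit_biomarker_regressions(x, y)
        first = [r for r in regs if r.key == "HbO:DC:baseline"][0]
        assert first.r_squared == pytest.approx(1.0)
        assert first.slope == pytest.approx(2.0)
        assert first.p_value < 1e-12

    def test_type_one_error_calibrated(self):
        """Independent predictor at n=29: slope p < 0.05 in ≈5% of nulls."""
        rng = np.random.default_rng(10)
        from scipy import stats as st

        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.standard_normal(29)
            y = rng.standard_normal(29)
            hits += st.linregress(x, y).pvalue < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.015)

    def test_duplicated_data_same_slope_smaller_p(self, rng):
        x = rng.standard_normal((15, 3, 3, 5))
        y = 0.5 * x[:, 0, 0, 0] + rng.standard_normal(15)
        single = fit_biomarker_regressions(x, y)[0]
        doubled = fit_biomarker_regressions(
            np.concatenate([x, x]), np.concatenate([y, y]))[0]
        assert doubled.slope == pytest.approx(single.slope)
        assert doubled.p_value < single.p_value

    def test_constant_predictor_skipped_with_warning(self, rng):
        x = rng.standard_normal((10, 3, 3, 5))
        x[:, 1, 1, 2] = 3.0
        with pytest.warns(RuntimeWarning, match="constant predictor"):
            regs = fit_biomarker_regressions(x, rng.standard_normal(10))
        assert len(regs) == 44
        assert not any(r.key == "HbR:GE:delta3" for r in regs)

    def test_predictor_matrix_baseline_and_deltas(self):
        periods = np.arange(5.0)[None, None, None, :] * np.ones((2, 3, 3, 5))
        pred = predictor_matrix(periods)
        assert np.allclose(pred[0, 0, 0], [0, 1, 2, 3, 4])  # baseline 0, Δk = k−0


def reg(chrom, metric, period, slope=-1.0, intercept=1.0, p=0.01, r2=0.5):
    return BiomarkerRegression(chromophore=chrom, metric=metric, period=period,
                               slope=slope, intercept=intercept,
                               r_squared=r2, p_value=p)


class TestSelection:
    def test_study_pattern_six_significant(self):
        """Reconstructing the published regression table's p-values selects
        exactly the six starred cells."""
        p_table = {
            ("HbO", "CC"): [0.4025, 0.7547, 0.3911, 0.0087, 0.0245],
            ("HbO", "DC"): [0.6948, 0.6861, 0.5138, 0.0806, 0.0302],
            ("HbO", "GE"): [0.8046, 0.7195, 0.8149, 0.1387, 0.0581],
            ("HbR", "CC"): [0.3352, 0.9893, 0.9257, 0.0167, 0.0279],
            ("HbR", "DC"): [0.8976, 0.4248, 0.3936, 0.2791, 0.1907],
            ("HbR", "GE"): [0.6801, 0.2771, 0.2886, 0.8325, 0.6616],
            ("HbT", "CC"): [0.5059, 0.9949, 0.1612, 0.0551, 0.0841],
            ("HbT", "DC"): [0.6868, 0.8108, 0.0825, 0.3576, 0.8516],
            ("HbT", "GE"): [0.6441, 0.7997, 0.0318, 0.3055, 0.6866],
        }
        periods = ("baseline", "delta2", "delta3", "delta4", "delta5")
        regs = [
            reg(c, m, periods[k], p=pv)
            for (c, m), ps in p_table.items()
            for k, pv in enumerate(ps)
        ]
        sel = select_biomarkers(regs, alpha=0.05)
        keys = {r.key for rs in sel.values() for r in rs}
        assert keys == {
            "HbO:CC:delta4", "HbO:CC:delta5", "HbO:DC:delta5",
            "HbR:CC:delta4", "HbR:CC:delta5", "HbT:GE:delta3",
        }
        assert set(sel) == {"delta3", "delta4", "delta5"}

    def test_alpha_one_selects_everything(self):
        regs = [reg("HbO", "DC", "delta2", p=0.99), reg("HbR", "CC", "delta3", p=0.5)]
        sel = select_biomarkers(regs, alpha=1.0)
        assert sum(len(v) for v in sel.values()) == 2

    def test_nothing_significant_empty_selection(self):
        regs = [reg("HbO", "DC", "delta2", p=0.2)]
        assert select_biomarkers(regs, alpha=0.05) == {}


def _clf(selected, cutoff=0.35):
    return VotingClassifier(
        thresholds=np.full((3, 3), 0.5),
        threshold_idx=np.full((3, 3), 10),
        selected=selected,
        cutoff=cutoff,
    )


def _predictors(values: dict[str, float]) -> np.ndarray:
    x = np.full((3, 3, 5), np.nan)
    c_idx = {c: i for i, c in enumerate(constants.CHROMOPHORES)}
    m_idx = {m: i for i, m in enumerate(constants.GRAPH_METRICS)}
    k_idx = {"baseline": 0, "delta2": 1, "delta3": 2, "delta4": 3, "delta5": 4}
    for key, v in values.items():
        c, m, k = key.split(":")
        x[c_idx[c], m_idx[m], k_idx[k]] = v
    return x


class TestVoting:
    def test_three_biomarkers_two_flags_is_nonresponder(self):
        """Majority of 3: two predictions below the cutoff flag the period."""
        sel = {"delta5": [
            reg("HbO", "CC", "delta5", slope=-1, intercept=0.2),  # pred 0.2 at x=0
            reg("HbR", "CC", "delta5", slope=-1, intercept=0.2),
            reg("HbO", "DC", "delta5", slope=-1, intercept=0.9),
        ]}
        x = _predictors({"HbO:CC:delta5": 0.0, "HbR:CC:delta5": 0.0,
                         "HbO:DC:delta5": 0.0})
        pred = predict_subject(x, _clf(sel))
        assert pred.union_non_responder and pred.per_period["delta5"]

    def test_two_biomarkers_require_unanimity(self):
        sel = {"delta4": [
            reg("HbO", "CC", "delta4", slope=-1, intercept=0.2),
            reg("HbR", "CC", "delta4", slope=-1, intercept=0.9),
        ]}
        x = _predictors({"HbO:CC:delta4": 0.0, "HbR:CC:delta4": 0.0})
        pred = predict_subject(x, _clf(sel))
        assert not pred.union_non_responder
        x2 = _predictors({"HbO:CC:delta4": 0.0, "HbR:CC:delta4": 0.6})
        pred2 = predict_subject(x2, _clf(sel))
        assert pred2.union_non_responder

    def test_four_biomarkers_two_flags_suffice(self):
        sel = {"delta5": [
            reg("HbO", "CC", "delta5", slope=-1, intercept=0.2),
            reg("HbR", "CC", "delta5", slope=-1, intercept=0.2),
            reg("HbO", "DC", "delta5", slope=-1, intercept=0.9),
            reg("HbT", "GE", "delta5", slope=-1, intercept=0.9),
        ]}
        x = _predictors({"HbO:CC:delta5": 0.0, "HbR:CC:delta5": 0.0,
                         "HbO:DC:delta5": 0.0, "HbT:GE:delta5": 0.0})
        pred = predict_subject(x, _clf(sel))
        assert pred.union_non_responder

    def test_no_flags_anywhere_is_responder(self):
        sel = {"delta3": [reg("HbT", "GE", "delta3", slope=-1, intercept=0.9)]}
        x = _predictors({"HbT:GE:delta3": 0.0})
        pred = predict_subject(x, _clf(sel))
        assert not pred.union_non_responder and pred.label == "responder"

    def test_missing_predictor_abstains_default_responder(self):
        sel = {"delta3": [reg("HbT", "GE", "delta3")]}
        x = _predictors({})  # all NaN
        with pytest.warns(RuntimeWarning, match="abstained"):
            pred = predict_subject(x, _clf(sel))
        assert pred.label == "responder"

    def test_monotone_flagging_in_cutoff(self):
        """Lowering the cutoff never converts a flagged subject to unflagged."""
        rng = np.random.default_rng(3)
        sel = {"delta4": [reg("HbO", "CC", "delta4"), reg("HbR", "CC", "delta4")],
               "delta5": [reg("HbO", "CC", "delta5"), reg("HbR", "CC", "delta5"),
                          reg("HbO", "DC", "delta5")]}
        for _ in range(50):
            vals = {k: rng.uniform(0, 1.2) for k in
                    ["HbO:CC:delta4", "HbR:CC:delta4", "HbO:CC:delta5",
                     "HbR:CC:delta5", "HbO:DC:delta5"]}
            x = _predictors(vals)
            flags = [predict_subject(x, _clf(sel, cutoff=c)).union_non_responder
                     for c in (0.2, 0.35, 0.5, 0.8)]
            assert flags == sorted(flags)  # False before True

    def test_voting_score_reproduces_decision(self):
        """score < cutoff iff the voting protocol flags, for any cutoff."""
        rng = np.random.default_rng(4)
        sel = {"delta4": [reg("HbO", "CC", "delta4"), reg("HbR", "CC", "delta4")],
               "delta5": [reg("HbO", "CC", "delta5"), reg("HbR", "CC", "delta5"),
                          reg("HbO", "DC", "delta5")]}
        for _ in range(50):
            vals = {k: rng.uniform(0, 1.2) for k in
                    ["HbO:CC:delta4", "HbR:CC:delta4", "HbO:CC:delta5",
                     "HbR:CC:delta5", "HbO:DC:delta5"]}
            x = _predictors(vals)
            s = voting_score(x, _clf(sel))
            for c in (0.1, 0.35, 0.6, 0.9):
                assert (s < c) == predict_subject(x, _clf(sel, cutoff=c)).union_non_responder

    def test_serialization_round_trip(self):
        sel = {"delta4": [reg("HbO", "CC", "delta4"), reg("HbR", "CC", "delta4")]}
        clf = _clf(sel)
        clone = VotingClassifier.from_json(clf.to_json())
        assert clone.to_json() == clf.to_json()
        assert np.array_equal(clone.thresholds, clf.thresholds)


class TestEndToEndFit:
    def test_fit_recovers_planted_negative_coupling(self, rng):
        """Period indices declining in proportion to ΔGCS produce negative
        fitted slopes for the delta-period biomarkers."""
        n = 29
        y = np.r_[rng.uniform(0.5, 1.5, 14), rng.uniform(-0.3, 0.4, 15)]
        groups = y >= 0.5
        table = rng.standard_normal((n, 3, 3, 51, 5)) * 0.05
        decline = -np.arange(5)[None, :] * y[:, None] * 0.5  # ∝ ΔGCS
        table += decline[:, None, None, None, :]
        clf, predictors = fit_biomarker_model(table, y, groups, alpha=0.05)
        delta_regs = [r for per, rs in clf.selected.items() if per != "baseline"
                      for r in rs]
        assert delta_regs, "planted coupling should select delta biomarkers"
        assert all(r.slope < 0 for r in delta_regs)
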