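"""Feature extraction and the discrimination statistics battery."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from scstim import (
    EMG_SCHEME,
    ControlConfig,
    EncodingConfig,
    GraspTrace,
    NoiseConfig,
    ObjectSpec,
    anova_tukey,
    binomial_above_chance,
    contact_force,
    ellipse_overlap,
    extract_features,
    feature_manova,
    ideal_observer,
    lowpass_force,
    run_encoder,
    run_full_analysis,
    sd_ellipse,
    simulate_glove_trial,
    simulate_session,
    threshold_velocity_controller,
    get_preset,
)
from scstim.analysis import EllipseParams, features_table


def emg_style_trace(envelope, obj, threshold=0.5):
    """Hand-built EMG-scheme trial: constant-envelope controller, clean
    spring force, real force filter."""
    cfg = ControlConfig(scheme=EMG_SCHEME)
    ap = threshold_velocity_controller(envelope, threshold, cfg, start_aperture=90.0)
    clean = np.asarray(contact_force(ap, obj), dtype=float)
    t = np.arange(envelope.size) / 50.0
    above = np.nonzero(envelope >= threshold)[0]
    onset = t[above[0]] if above.size else float("nan")
    return GraspTrace(
        time=t, command=envelope, aperture=ap, raw_force=clean,
        filtered_force=lowpass_force(clean), obj=obj, command_onset_time=onset,
        scheme=EMG_SCHEME, command_threshold=threshold,
    )


class TestExtractFeatures:
    def test_constant_velocity_onset_lag_closed_form(self):
        # start 90 deg, contact 60 deg, 15 deg/s -> contact after 2.0 s
        obj = ObjectSpec("cylinder", "L", "hard", 60.0, 0.45)
        grasp = emg_style_trace(np.ones(300), obj)
        contact_idx = np.nonzero(grasp.raw_force > 0)[0][0]
        assert grasp.time[contact_idx] == pytest.approx(2.0, abs=1 / 50 + 1e-9)
        # ungated encoding of the clean force: stimulation onset == contact
        ungated = run_encoder(
            grasp.raw_force, EncodingConfig(contact_threshold=0.0), time=grasp.time
        )
        fv0 = extract_features(grasp, ungated)
        assert fv0.onset_lag == pytest.approx(2.0, abs=1 / 50 + 1e-9)
        # realistic chain: the contact gate and causal filter add a small
        # strictly positive delay
        stim = run_encoder(grasp.filtered_force, EncodingConfig(), time=grasp.time)
        fv = extract_features(grasp, stim)
        assert 2.0 <= fv.onset_lag <= 2.25
        # a hair below contact aperture: threshold depth plus filter delay
        assert 56.0 <= fv.aperture_at_onset <= 60.0

    def test_zero_force_trial_yields_null_features(self):
        obj = ObjectSpec("cylinder", "L", "hard", 60.0, 0.45)
        grasp = emg_style_trace(np.zeros(100), obj)
        stim = run_encoder(grasp.filtered_force, EncodingConfig(), time=grasp.time)
        fv = extract_features(grasp, stim)
        assert fv.onset_lag is None and fv.peak_amp is None
        assert fv.null_reason == "no_stimulation"

    def test_ramp_force_rate_matches_encoder_gain_times_kv(self):
        # slow smooth closure so the rise dwarfs filter end effects
        enc = EncodingConfig(scheme="linear")
        k, v = 0.2, 10.0
        obj = ObjectSpec("sphere", "M", "medium", 45.0, k)
        ctrl = ControlConfig(scheme="glove_proportional", glove_smooth_rate=v)
        quiet = NoiseConfig(sensor_noise_sd=0.0, command_onset_jitter_sd=0.0, glove_ballistic=False)
        grasp = simulate_glove_trial(obj, ctrl, quiet, timeout=12.0, seed=3)
        stim = run_encoder(grasp.filtered_force, enc, time=grasp.time)
        fv = extract_features(grasp, stim)
        assert fv.rate_of_change == pytest.approx(k * v * enc.linear_gain, rel=0.05)

    def test_mismatched_grids_rejected(self):
        obj = ObjectSpec("cylinder", "L", "hard", 60.0, 0.45)
        grasp = emg_style_trace(np.ones(100), obj)
        stim = run_encoder(np.zeros(50), EncodingConfig())
        with pytest.raises(ValueError):
            extract_features(grasp, stim)


def binomial_upper_tail_oracle(k: int, n: int, p0: Fraction) -> Fraction:
    """Exact P(X >= k) by brute-force enumeration with rational arithmetic."""
    total = Fraction(0)
    for j in range(k, n + 1):
        total += math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
    return total


class TestBinomial:
    def test_perfect_score_closed_form(self):
        res = binomial_above_chance(10, 10, 0.5)
        assert res.p_value == pytest.approx(2**-10, rel=1e-12)

    def test_zero_successes_p_is_one(self):
        assert binomial_above_chance(0, 15, 0.3).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [5, 12, 20])
    @pytest.mark.parametrize("p0", [Fraction(1, 3), Fraction(1, 4), Fraction(1, 2)])
    def test_matches_enumeration_oracle(self, n, p0):
        for k in range(n + 1):
            res = binomial_above_chance(k, n, float(p0))
            assert res.p_value == pytest.approx(float(binomial_upper_tail_oracle(k, n, p0)), abs=1e-12)

    def test_p_monotone_decreasing_in_k(self):
        ps = [binomial_above_chance(k, 30, 1 / 3).p_value for k in range(31)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_invalid_chance_rejected(self):
        with pytest.raises(ValueError):
            binomial_above_chance(1, 10, 1.0)


class TestManova:
    FEATS = ["f1", "f2"]

    @staticmethod
    def _frame(groups):
        rows = []
        for lbl, arr in groups.items():
            for x, y in arr:
                rows.append({"g": lbl, "f1": x, "f2": y})
        return pd.DataFrame(rows)

    def test_hand_fixture_matches_explicit_scatter_arithmetic(self):
        g1 = [(1.0, 2.0), (2.0, 3.0), (3.0, 2.0), (2.0, 1.0)]
        g2 = [(5.0, 6.0), (6.0, 7.0), (7.0, 6.0), (6.0, 5.0)]
        df = self._frame({"a": g1, "b": g2})
        res = feature_manova(df, self.FEATS, "g")
        # independent arithmetic: W and B assembled long-hand
        a = np.array(g1)
        b = np.array(g2)
        W = np.zeros((2, 2))
        for grp in (a, b):
            d = grp - grp.mean(axis=0)
            W += d.T @ d
        grand = np.vstack([a, b]).mean(axis=0)
        B = np.zeros((2, 2))
        for grp in (a, b):
            diff = (grp.mean(axis=0) - grand).reshape(2, 1)
            B += len(grp) * diff @ diff.T
        det2 = lambda m: m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        lam = det2(W) / det2(W + B)
        assert res["wilks_lambda"] == pytest.approx(lam, rel=1e-12)

    def test_agrees_with_statsmodels_manova(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 15),
            "f1": rng.normal(size=45) + np.repeat([0, 1, 2], 15),
            "f2": rng.normal(size=45),
        })
        res = feature_manova(df, self.FEATS, "g")
        from statsmodels.multivariate.manova import MANOVA

        sm = MANOVA.from_formula("f1 + f2 ~ g", data=df).mv_test()
        tbl = sm.results["g"]["stat"]
        assert res["wilks_lambda"] == pytest.approx(tbl.loc["Wilks' lambda", "Value"], rel=1e-8)
        assert res["p_value"] == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], abs=1e-8)

    def test_null_case_lambda_near_one(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(500):
            df = pd.DataFrame({
                "g": np.repeat(["a", "b"], 10),
                "f1": rng.normal(size=20),
                "f2": rng.normal(size=20),
            })
            res = feature_manova(df, self.FEATS, "g")
            pvals.append(res["p_value"])
        assert np.median(pvals) > 0.3

    def test_strongly_separated_groups_significant(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "g": np.repeat(["a", "b"], 30),
                "f1": rng.normal(size=60) + np.repeat([0.0, 10.0], 30),
                "f2": rng.normal(size=60),
            })
            assert feature_manova(df, self.FEATS, "g")["p_value"] < 0.001

    def test_collinear_features_named_in_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 10), "f1": x, "f2": 2 * x})
        with pytest.raises(ValueError, match="f1"):
            feature_manova(df, self.FEATS, "g")


class TestAnovaTukey:
    def test_textbook_fixture_matches_hand_computed_sums_of_squares(self):
        groups = {"a": [2.0, 3, 4, 5, 6], "b": [4.0, 5, 6, 7, 8], "c": [7.0, 8, 9, 10, 11]}
        vals = np.concatenate([np.array(v) for v in groups.values()])
        labels = np.repeat(list(groups), 5)
        res = anova_tukey(vals, labels)
        grand = vals.mean()
        ss_between = sum(5 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        F = (ss_between / 2) / (ss_within / 12)
        assert res["F"] == pytest.approx(F, rel=1e-12)

    def test_null_groups_p_not_small(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(500):
            vals = rng.normal(size=30)
            pvals.append(anova_tukey(vals, np.repeat(["a", "b", "c"], 10))["p_value"])
        assert np.median(pvals) > 0.3

    def test_single_shifted_group_flagged_by_tukey(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([
                rng.normal(size=15), rng.normal(size=15), rng.normal(10.0, 1.0, size=15)
            ])
            res = anova_tukey(vals, np.repeat(["a", "b", "c"], 15))
            tuk = res["tukey"].set_index(res["tukey"]["group1"] + "|" + res["tukey"]["group2"])
            assert bool(tuk.loc["a|c", "reject"]) and bool(tuk.loc["b|c", "reject"])
            assert not bool(tuk.loc["a|b", "reject"])

    def test_all_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey(np.ones(12), np.repeat(["a", "b", "c"], 4))


class TestSdEllipse:
    def test_isotropic_cloud_near_circular(self):
        rng = np.random.default_rng(3)
        e = sd_ellipse(rng.normal(size=5000), rng.normal(size=5000))
        assert e.semi_axes[0] / e.semi_axes[1] < 1.1

    def test_collinear_points_degenerate_to_segment(self):
        x = np.linspace(0, 1, 10)
        e = sd_ellipse(x, 2 * x)
        assert e.semi_axes[1] == pytest.approx(0.0, abs=1e-9)
        assert e.orientation == pytest.approx(math.atan2(2, 1), abs=1e-9)

    def test_correlated_normal_orientation_45_degrees(self):
        rng = np.random.default_rng(4)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=5000)
        e = sd_ellipse(xy[:, 0], xy[:, 1])
        assert math.degrees(e.orientation) == pytest.approx(45.0, abs=3.0)
        assert e.pearson_r == pytest.approx(0.8, abs=0.05)

    def test_centroid_is_sample_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        y = np.array([0.0, 3.0, 3.0])
        e = sd_ellipse(x, y)
        assert e.centroid == (pytest.approx(3.0), pytest.approx(2.0))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sd_ellipse(np.ones(5), np.ones(5))


def circle(cx, cy, r=1.0):
    return EllipseParams(centroid=(cx, cy), semi_axes=(r, r), orientation=0.0, pearson_r=0.0)


class TestEllipseOverlap:
    def test_distant_circles_disjoint(self):
        assert not ellipse_overlap(circle(0, 0), circle(3, 0))

    def test_concentric_ellipses_overlap(self):
        inner = EllipseParams((0, 0), (0.5, 0.2), 0.3, 0.0)
        assert ellipse_overlap(circle(0, 0), inner)

    def test_tangent_circles_count_as_overlap(self):
        assert ellipse_overlap(circle(0, 0), circle(2, 0))

    def test_degenerate_segment_handled(self):
        seg = EllipseParams((0, 0), (2.0, 0.0), 0.0, 1.0)
        assert ellipse_overlap(seg, circle(1, 0.5))
        assert not ellipse_overlap(seg, circle(0, 5))


def labeled_features(rng, n_per_class, shift):
    rows = []
    for i, cls in enumerate(["S", "M", "L"]):
        for _ in range(n_per_class):
            rows.append({
                "size_class": cls,
                "compliance_class": "hard",
                "onset_lag": rng.normal(i * shift),
                "peak_amp": rng.normal(),
                "rate_of_change": rng.normal(),
                "aperture_at_onset": rng.normal(),
            })
    return pd.DataFrame(rows)


class TestIdealObserver:
    FEATS = ("onset_lag", "peak_amp", "rate_of_change")

    def test_widely_separated_classes_decoded(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            train = labeled_features(rng, 100, shift=10.0)
            test = labeled_features(rng, 100, shift=10.0)
            res = ideal_observer(train, test, "size_class", self.FEATS)
            assert res.overall_accuracy >= 0.95

    def test_uninformative_features_at_chance(self):
        rng = np.random.default_rng(6)
        train = labeled_features(rng, 150, shift=0.0)
        test = labeled_features(rng, 100, shift=0.0)
        res = ideal_observer(train, test, "size_class", self.FEATS)
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], 300, 1 / 3) / 300
        assert lo <= res.overall_accuracy <= hi

    def test_three_alternative_chance_is_one_third(self):
        rng = np.random.default_rng(7)
        res = ideal_observer(
            labeled_features(rng, 20, 5.0), labeled_features(rng, 10, 5.0),
            "size_class", self.FEATS,
        )
        assert res.overall_binomial.p0 == pytest.approx(1 / 3)
        assert res.confusion.sum(axis=1).tolist() == [10, 10, 10]

    def test_class_missing_from_training_rejected(self):
        rng = np.random.default_rng(8)
        train = labeled_features(rng, 10, 5.0)
        test = labeled_features(rng, 10, 5.0)
        with pytest.raises(ValueError, match="absent"):
            ideal_observer(train[train.size_class != "L"], test, "size_class", self.FEATS)


class TestFullAnalysis:
    def test_report_structure_for_glove_session(self):
        from scstim.config import config_for_preset

        cfg = config_for_preset("S1-virtual-size", 21)
        preset = get_preset("S1-virtual-size")
        pairs = simulate_session(
            preset.schedule(21), cfg.control.to_dataclass(), cfg.noise.to_dataclass(),
            cfg.encoding.to_dataclass(), master_seed=21,
        )
        rep = run_full_analysis(pairs, queried_property="size")
        assert rep["n_trials"] == 72
        assert "size_class" in rep["manova"]
        assert rep["ideal_observer"]["classes"] == ["S", "M", "L"]
        assert set(rep["ellipse_overlap"]) == {"S|M", "S|L", "M|L"}

    LIMITED = ControlConfig(scheme="glove_proportional", aperture_range=(90.0, 20.0))

    def test_all_null_session_raises_explicitly(self):
        obj = ObjectSpec("sphere", "S", "medium", 5.0, 0.15)  # below the closure limit
        quiet = NoiseConfig(sensor_noise_sd=0.0, command_onset_jitter_sd=0.0, glove_ballistic=False)
        pairs = []
        for seed in range(6):
            g = simulate_glove_trial(obj, self.LIMITED, quiet, timeout=4.0, seed=seed)
            pairs.append((g, run_encoder(g.filtered_force, EncodingConfig(), time=g.time)))
        with pytest.raises(ValueError, match="null features"):
            run_full_analysis(pairs)

    def test_null_trials_counted_not_dropped_silently(self):
        reachable = ObjectSpec("sphere", "M", "medium", 45.0, 0.15)
        unreachable = ObjectSpec("sphere", "S", "soft", 5.0, 0.05)
        quiet = NoiseConfig(sensor_noise_sd=0.0, command_onset_jitter_sd=0.0, glove_ballistic=False)
        pairs = []
        for seed, obj in enumerate([reachable] * 4 + [unreachable] * 2):
            g = simulate_glove_trial(obj, self.LIMITED, quiet, timeout=6.0, seed=seed)
            pairs.append((g, run_encoder(g.filtered_force, EncodingConfig(), time=g.time)))
        df = features_table(pairs)
        assert df["null_reason"].notna().sum() == 2
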