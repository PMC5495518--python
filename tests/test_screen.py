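"""Plate normalization, LOESS, z-scoring, validation and screen comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from dsbsirna.screen import (
    ScreenThresholds,
    ValidationRecord,
    call_candidates,
    compare_screens,
    control_thresholds,
    dead_cell_filter,
    loess_fit,
    loess_predict,
    normalize_plates,
    score_wells,
    validate_candidates,
)
from dsbsirna.simulate import PlateSimConfig, simulate_screen


def toy_plate(values, annotation="sample", plate="p1"):
    return pd.DataFrame(
        {
            "plate_id": plate,
            "well": [f"A{i + 1:02d}" for i in range(len(values))],
            "fluc_raw": values,
            "rluc_raw": values,
            "annotation": annotation,
            "target_gene": [f"g{i}" for i in range(len(values))],
        }
    )


class TestNormalizePlates:
    def test_equal_wells_normalize_to_zero(self):
        df = normalize_plates(toy_plate([100.0] * 10))
        assert np.allclose(df["fluc_norm"], 0)
        assert np.allclose(df["rluc_norm"], 0)

    def test_plate_factor_removed(self):
        vals = [50.0, 100.0, 200.0, 400.0]
        a = normalize_plates(toy_plate(vals, plate="p1"))
        b = normalize_plates(toy_plate([v * 7.5 for v in vals], plate="p2"))
        assert np.allclose(a["rluc_norm"], b["rluc_norm"])

    def test_sample_median_is_zero(self):
        rng = np.random.default_rng(5)
        df = normalize_plates(toy_plate(list(rng.lognormal(10, 1, 50))))
        samples = df[df["annotation"] == "sample"]
        assert np.median(samples["fluc_norm"]) == pytest.approx(0, abs=1e-12)

    def test_idempotent_through_exp_roundtrip(self):
        rng = np.random.default_rng(6)
        df1 = normalize_plates(toy_plate(list(rng.lognormal(8, 0.5, 30))))
        again = df1.copy()
        again["fluc_raw"] = np.exp(df1["fluc_norm"])
        again["rluc_raw"] = np.exp(df1["rluc_norm"])
        df2 = normalize_plates(again)
        assert np.allclose(df2["fluc_norm"], df1["fluc_norm"])

    def test_nonpositive_wells_flagged_invalid(self):
        df = toy_plate([100.0, -5.0, 0.0, 50.0])
        out = normalize_plates(df)
        assert list(out["valid"]) == [True, False, False, True]
        assert out.attrs["n_invalid"] == 2

    def test_log_base_irrelevant_after_centering(self):
        vals = [50.0, 100.0, 200.0, 400.0, 800.0]
        e = normalize_plates(toy_plate(vals), log_base=math.e)
        two = normalize_plates(toy_plate(vals), log_base=2)
        # base change rescales both values and median uniformly
        assert np.allclose(e["fluc_norm"] / math.log(2, math.e), two["fluc_norm"])


class TestLoess:
    def test_reproduces_exact_quadratic(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-2, 2, 60)
        y = 1.5 + 0.7 * x - 0.3 * x**2
        fit = loess_fit(x, y, span=0.5, degree=2)
        assert np.allclose(fit.residuals, 0, atol=1e-9)

    def test_span_one_degree_one_center_equals_ols(self):
        x = np.linspace(-1, 1, 21)  # symmetric around 0
        rng = np.random.default_rng(2)
        y = 2 + 3 * x + rng.normal(0, 0.1, 21)
        pred = loess_predict(x, y, np.array([0.0]), span=1.0, degree=1)
        beta = np.polyfit(x, y, 1)
        # tricube weights are symmetric at the center, so the local line
        # and the OLS line agree at x = 0 up to the weighting
        w = (1 - (np.abs(x) / np.abs(x).max()) ** 3) ** 3
        bw = np.polyfit(x, y, 1, w=np.sqrt(w))
        assert pred[0] == pytest.approx(np.polyval(bw, 0.0), abs=1e-10)
        assert pred[0] == pytest.approx(np.polyval(beta, 0.0), abs=0.05)

    @pytest.mark.parametrize("span,degree", [(0.3, 1), (0.9, 2), (1.0, 2)])
    def test_matches_per_point_wls_oracle(self, span, degree):
        """Brute-force tricube weighted least squares at every point."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 80)
        y = np.sin(x) + rng.normal(0, 0.2, 80)
        fit = loess_fit(x, y, span=span, degree=degree)
        q = int(np.ceil(span * len(x)))
        for i in range(len(x)):
            d = np.abs(x - x[i])
            nn = np.sort(np.argsort(d, kind="stable")[:q])
            dmax = d[nn].max()
            w = (1 - (d[nn] / dmax) ** 3) ** 3
            X = np.vander(x[nn] - x[i], degree + 1, increasing=True)
            W = np.diag(w)
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[nn])
            assert fit.fitted_values[i] == pytest.approx(beta[0], rel=1e-8, abs=1e-10)

    def test_agrees_with_statsmodels_lowess(self):
        """Independent cross-check of the degree-1 special case."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 10, 120))
        y = 0.5 * x + rng.normal(0, 0.3, 120)
        ours = loess_fit(x, y, span=0.5, degree=1).fitted_values
        theirs = sm.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
        assert np.allclose(ours, theirs, atol=0.05)

    def test_locality(self):
        """Perturbing data outside a point's neighborhood leaves its
        prediction unchanged."""
        x = np.arange(100, dtype=float)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 100)
        span = 0.3  # q = 30 nearest points
        p0 = loess_predict(x, y, np.array([10.0]), span=span, degree=1)
        y2 = y.copy()
        y2[60:] += 100.0
        p1 = loess_predict(x, y2, np.array([10.0]), span=span, degree=1)
        assert p0[0] == pytest.approx(p1[0])

    def test_degenerate_neighborhood_falls_back(self):
        x = np.ones(10)
        y = np.arange(10, dtype=float)
        pred = loess_predict(x, y, np.array([1.0]), span=1.0, degree=1)
        assert pred[0] == pytest.approx(y.mean())

    def test_span_too_small_rejected(self):
        with pytest.raises(ValueError):
            loess_fit(np.arange(10.0), np.arange(10.0), span=0.1, degree=2)


class TestScoring:
    def _screen(self, seed=0, **kw):
        cfg = PlateSimConfig(seed=seed, **kw)
        plates, truth = simulate_screen(cfg)
        return plates, truth

    def test_on_curve_wells_score_near_zero(self):
        plates, _ = self._screen(n_plates=2, n_spiked=0, noise_sd=0.05)
        scored = score_wells(normalize_plates(plates))
        samp = scored[(scored["annotation"] == "sample") & scored["z"].notna()]
        assert abs(samp["z"].mean()) < 0.05

    def test_zero_noise_no_hits_residuals_vanish(self):
        plates, _ = self._screen(n_plates=1, n_spiked=0, noise_sd=0.0)
        norm = normalize_plates(plates)
        norm = dead_cell_filter(norm)
        fitable = norm[
            norm["valid"] & ~norm["dead"] & (norm["annotation"] == "sample")
        ]
        fit = loess_fit(
            fitable["fluc_norm"].to_numpy(), fitable["rluc_norm"].to_numpy(),
            span=0.9, degree=2,
        )
        assert np.allclose(fit.residuals, 0, atol=1e-6)

    def test_spiked_hits_recovered(self):
        plates, truth = self._screen(seed=11, n_plates=3)
        scored = score_wells(normalize_plates(plates))
        cand = call_candidates(scored)
        called = set(cand.loc[cand["call"] == "positive_candidate", "target_gene"])
        hits = set(truth["spiked_hits"])
        assert len(hits & called) / len(hits) >= 0.95

    def test_negative_control_z_centered(self):
        # 10 plates x 8 negative wells so the mean is estimated well
        plates, _ = self._screen(seed=12, n_plates=10, n_spiked=0)
        scored = score_wells(normalize_plates(plates))
        neg = scored.loc[scored["annotation"].str.startswith("neg_ctrl"), "z"]
        assert abs(neg.mean()) < 0.2

    def test_null_calibration(self):
        """No-effect screen: |z| > 2 rate among samples near the Gaussian
        expectation."""
        plates, _ = self._screen(seed=13, n_plates=2, n_spiked=0)
        scored = score_wells(normalize_plates(plates))
        samp = scored[(scored["annotation"] == "sample") & scored["z"].notna()]
        frac = (samp["z"].abs() > 2).mean()
        expected = 2 * (1 - 0.9772498680518208)
        n = len(samp)
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n) + 1e-9

    def test_dead_wells_excluded(self):
        plates, _ = self._screen(n_plates=1)
        norm = dead_cell_filter(normalize_plates(plates))
        thread = norm["annotation"] == "thread_ctrl"
        # thread wells sit at the exclusion floor; samples are far above
        assert norm.loc[~thread & (norm["annotation"] == "sample"), "dead"].mean() < 0.01

    def test_robust_variant_close_to_standard_under_null(self):
        plates, _ = self._screen(seed=14, n_plates=1, n_spiked=0)
        a = score_wells(normalize_plates(plates), z_variant="standard")
        b = score_wells(normalize_plates(plates), z_variant="robust")
        samp = a["annotation"] == "sample"
        assert np.corrcoef(a.loc[samp, "z"], b.loc[samp, "z"])[0, 1] > 0.99


class TestValidation:
    def test_two_of_three_retained(self):
        rec = ValidationRecord("g1", ("positive", "positive", "negative"), "specific")
        out = validate_candidates([rec])
        assert out.loc[0, "final_call"] == "retained"

    def test_one_of_three_dropped(self):
        rec = ValidationRecord("g2", ("positive", "negative", "negative"), "specific")
        out = validate_candidates([rec])
        assert out.loc[0, "final_call"] == "dropped"
        assert out.loc[0, "failed_rule"] == "triggers_lt_2_of_3"

    def test_counter_screen_derepression_dropped(self):
        rec = ValidationRecord(
            "g3", ("positive", "positive", "positive"), "core_pathway_or_transcription"
        )
        out = validate_candidates([rec])
        assert out.loc[0, "final_call"] == "dropped"
        assert out.loc[0, "failed_rule"] == "counter_screen"

    def test_incomplete_record_flagged(self):
        rec = ValidationRecord("g4", ("positive", "positive", "unknown"), "specific")
        out = validate_candidates([rec])
        assert out.loc[0, "final_call"] == "incomplete"


class TestCompareScreens:
    def _scores(self, z_by_gene, thr=1.0):
        df = pd.DataFrame(
            {"target_gene": list(z_by_gene), "z": list(z_by_gene.values())}
        )
        df.attrs["thresholds"] = ScreenThresholds(thr - 1.0, 1.0)
        return df

    def test_classification(self):
        a = self._scores({"g1": 3.0, "g2": 2.5, "g3": 0.1})
        b = self._scores({"g1": 2.8, "g2": 0.2, "g3": 2.2})
        out = compare_screens(a, b, groups={"g1": "splicing"})
        by_gene = out.set_index("target_gene")
        assert by_gene.loc["g1", "effect_class"] == "shared_effect"
        assert by_gene.loc["g2", "effect_class"] == "a_specific"
        assert by_gene.loc["g3", "effect_class"] == "b_specific"
        assert by_gene.loc["g1", "group"] == "splicing"

    def test_planted_two_assay_recovery(self):
        """Two simulated screens sharing some spiked hits recover the
        planted shared/specific sets."""
        shared = {f"gene_{i:04d}": 4.0 for i in (3, 50, 100)}
        only_a = {f"gene_{i:04d}": 4.0 for i in (200, 250)}
        only_b = {f"gene_{i:04d}": 4.0 for i in (300, 350)}
        pa, _ = simulate_screen(
            PlateSimConfig(seed=21, n_plates=5, spiked_hits={**shared, **only_a})
        )
        pb, _ = simulate_screen(
            PlateSimConfig(seed=22, n_plates=5, spiked_hits={**shared, **only_b})
        )
        ca = call_candidates(score_wells(normalize_plates(pa)))
        cb = call_candidates(score_wells(normalize_plates(pb)))
        out = compare_screens(ca, cb).set_index("target_gene")
        for g in shared:
            assert out.loc[g, "effect_class"] == "shared_effect"
        for g in only_a:
            assert out.loc[g, "effect_class"] == "a_specific"
        for g in only_b:
            assert out.loc[g, "effect_class"] == "b_specific"

    def test_no_overlap_rejected(self):
        a = self._scores({"g1": 1.0})
        b = self._scores({"g2": 1.0})
        with pytest.raises(ValueError):
            compare_screens(a, b)
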