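import numpy as np
import pandas as pd
import pytest

from herbniche.errors import ConfigurationError, EmptyDomainError
from herbniche.geodata import EnvStack, RasterGrid
from herbniche.quality import (
    CompoundPanel,
    StepwiseLinearRegression,
    build_panel,
    correlation_table,
    overlay_quality_zoning,
    predict_content_raster,
    stepwise_fit,
)


def _panel(n=10, seed=0, compounds=("Hyp", "Rt")):
    rng = np.random.default_rng(seed)
    sites = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n)], "lon": rng.uniform(100, 110, n), "lat": rng.uniform(25, 35, n)}
    )
    contents = pd.DataFrame(
        {c: rng.uniform(1, 10, n) for c in compounds}, index=sites["id"]
    )
    return CompoundPanel(sites=sites, contents=contents)


class TestBuildPanel:
    def test_identity_passthrough(self):
        p = _panel()
        out = build_panel(p.sites, contents=p.contents)
        pd.testing.assert_frame_equal(out.contents, p.contents)

    def test_unmatched_site_rejected(self):
        p = _panel()
        with pytest.raises(ValueError, match="unmatched"):
            build_panel(p.sites.iloc[:-1], contents=p.contents)

    def test_compound_column_order_fixed(self):
        p = _panel(compounds=("Isa A", "Ch.a", "Hyp"))
        assert list(p.contents.columns) == ["Hyp", "Ch.a", "Isa A"]

    def test_negative_contents_rejected(self):
        p = _panel()
        bad = p.contents.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            CompoundPanel(sites=p.sites, contents=bad)


class TestStepwiseRegression:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((40, 5)), columns=[f"x{i}" for i in range(1, 6)])
        y = 1.0 + 2.0 * X["x1"]
        m = StepwiseLinearRegression().fit(X, y)
        assert m.selected_ == ["x1"]
        assert dict(zip(m.selected_, m.coef_))["x1"] == pytest.approx(2.0, abs=1e-10)
        assert m.r2_ == pytest.approx(1.0)

    def test_pure_noise_keeps_intercept_only_in_most_runs(self):
        hits = 0
        runs = 30
        for s in range(runs):
            rng = np.random.default_rng(100 + s)
            X = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
            y = rng.standard_normal(200)
            m = StepwiseLinearRegression(criterion="BIC").fit(X, y)
            hits += len(m.selected_) == 0
        assert hits / runs >= 0.9

    def test_forward_and_backward_agree_on_strong_signal(self):
        for s in range(5):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
            y = 1.0 + 3.0 * X["c"] + rng.normal(0, 0.1, 60)
            f = StepwiseLinearRegression(direction="forward").fit(X, y)
            b = StepwiseLinearRegression(direction="backward").fit(X, y)
            assert "c" in f.selected_ and "c" in b.selected_
            bf = dict(zip(f.selected_, f.coef_))["c"]
            bb = dict(zip(b.selected_, b.coef_))["c"]
            assert bf == pytest.approx(bb, rel=0.05)

    def test_duplicate_column_design_still_fits(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        y = 2 * x + rng.normal(0, 0.1, 30)
        with pytest.warns(UserWarning, match="rank-deficient"):
            m = StepwiseLinearRegression(direction="both").fit(X, y)
        assert set(m.selected_) & {"a", "b"}

    def test_stepwise_fit_requires_enough_sites(self):
        p = _panel(n=5)
        env = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 4)),
                           columns=list("wxyz"), index=p.contents.index)
        with pytest.raises(ValueError, match="sites"):
            stepwise_fit(p, env, "Hyp")

    def test_seeded_recovery_rate_with_moderate_noise(self):
        """content = beta * factor + noise at SNR 5, n = 60 sites."""
        hits = 0
        runs = 20
        for s in range(runs):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(
                rng.standard_normal((60, 7)), columns=[f"f{i}" for i in range(7)]
            )
            beta = 3.0
            y = 2.0 + beta * X["f2"] + rng.normal(0, beta / 5, 60)
            m = StepwiseLinearRegression().fit(X, y)
            est = dict(zip(m.selected_, m.coef_)).get("f2")
            hits += est is not None and abs(est - beta) / beta <= 0.15
        assert hits / runs >= 0.9


class TestCorrelationTable:
    def test_perfect_correlation(self):
        p = _panel(n=8, compounds=("Hyp",))
        env = pd.DataFrame({"bio1": p.contents["Hyp"].to_numpy()}, index=p.contents.index)
        out = correlation_table(p, env)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["sig"].iloc[0] == "**"

    def test_textbook_t_statistic_p_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        sites = pd.DataFrame({"id": list("abcde"), "lon": x, "lat": x})
        panel = CompoundPanel(
            sites=sites, contents=pd.DataFrame({"Rt": y}, index=list("abcde"))
        )
        env = pd.DataFrame({"f": x}, index=list("abcde"))
        out = correlation_table(panel, env)
        r = out["r"].iloc[0]
        n = 5
        t = r * np.sqrt((n - 2) / (1 - r**2))
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t), n - 2)
        assert out["p"].iloc[0] == pytest.approx(p_expected, rel=1e-9)

    def test_sign_antisymmetry(self):
        p = _panel(n=10, compounds=("Hyp",))
        env = pd.DataFrame(
            {"f": np.random.default_rng(0).standard_normal(10)}, index=p.contents.index
        )
        r1 = correlation_table(p, env)["r"].iloc[0]
        r2 = correlation_table(p, -env)["r"].iloc[0]
        assert r1 == pytest.approx(-r2)

    def test_constant_factor_flagged(self):
        p = _panel(n=6, compounds=("Hyp",))
        env = pd.DataFrame({"f": np.ones(6)}, index=p.contents.index)
        out = correlation_table(p, env)
        assert np.isnan(out["r"].iloc[0])
        assert out["sig"].iloc[0] == "const"


def _stack_and_suit(seed=0, shape=(6, 6)):
    rng = np.random.default_rng(seed)
    base = dict(xll=100.0, yll=30.0, cellsize=0.5, nodata=-9999.0)
    layers = [
        RasterGrid("bio1", values=rng.standard_normal(shape), **base),
        RasterGrid("bio12", values=rng.standard_normal(shape), **base),
    ]
    stack = EnvStack(layers)
    suit = RasterGrid("p", values=rng.uniform(0, 1, shape), **base)
    return stack, suit


class TestPredictContentRaster:
    def test_intercept_only_model_constant_raster(self):
        stack, _ = _stack_and_suit()
        m = StepwiseLinearRegression()
        m.selected_, m.coef_, m.intercept_ = [], np.array([]), 4.2
        raster, n_floored = predict_content_raster(m, stack)
        assert n_floored == 0
        np.testing.assert_allclose(raster.values[raster.mask], 4.2)

    def test_single_factor_model_reproduces_layer(self):
        stack, _ = _stack_and_suit(seed=1)
        m = StepwiseLinearRegression()
        m.selected_, m.coef_, m.intercept_ = ["bio1"], np.array([1.0]), 0.0
        raster, _ = predict_content_raster(m, stack)
        mask = stack.mask & (stack["bio1"].values >= 0)
        np.testing.assert_allclose(raster.values[mask], stack["bio1"].values[mask])

    def test_negative_predictions_floored_and_counted(self):
        stack, _ = _stack_and_suit()
        m = StepwiseLinearRegression()
        m.selected_, m.coef_, m.intercept_ = [], np.array([]), -1.0
        raster, n_floored = predict_content_raster(m, stack)
        assert n_floored == stack.mask.sum()
        np.testing.assert_allclose(raster.values[raster.mask], 0.0)

    def test_missing_layer_rejected(self):
        stack, _ = _stack_and_suit()
        m = StepwiseLinearRegression()
        m.selected_, m.coef_, m.intercept_ = ["zz"], np.array([1.0]), 0.0
        with pytest.raises(ValueError, match="zz"):
            predict_content_raster(m, stack)


class TestOverlayQualityZoning:
    def test_constant_contents_score_half(self):
        stack, suit = _stack_and_suit()
        const = suit.copy_with(np.full(suit.values.shape, 7.0), name="Hyp")
        z = overlay_quality_zoning({"Hyp": const}, suit, mask_threshold=0.2)
        scored = z.score.values[z.score.mask]
        np.testing.assert_allclose(scored, 0.5)

    def test_single_raster_grades_match_jenks_of_raster(self):
        from herbniche.zoning import jenks_breaks

        stack, suit = _stack_and_suit(seed=2)
        content = suit.copy_with(np.random.default_rng(3).uniform(0, 5, suit.values.shape), name="c")
        z = overlay_quality_zoning({"c": content}, suit, mask_threshold=0.2, k_grades=3)
        region = suit.mask & (suit.values >= 0.2)
        v = content.values[region]
        norm = (v - v.min()) / (v.max() - v.min())
        expected = np.searchsorted(jenks_breaks(norm, 3), z.score.values[region], side="right")
        np.testing.assert_array_equal(z.grades.values[region], expected)

    def test_cells_below_threshold_are_nodata(self):
        stack, suit = _stack_and_suit(seed=4)
        content = suit.copy_with(np.random.default_rng(5).uniform(0, 5, suit.values.shape), name="c")
        z = overlay_quality_zoning({"c": content}, suit, mask_threshold=0.5)
        below = suit.mask & (suit.values < 0.5)
        assert np.all(z.score.values[below] == suit.nodata)
        assert np.all(z.grades.values[below] == suit.nodata)

    def test_score_invariant_under_affine_rescale_of_one_content(self):
        stack, suit = _stack_and_suit(seed=6)
        rng = np.random.default_rng(7)
        c1 = suit.copy_with(rng.uniform(0, 5, suit.values.shape), name="a")
        c2 = suit.copy_with(rng.uniform(0, 5, suit.values.shape), name="b")
        z1 = overlay_quality_zoning({"a": c1, "b": c2}, suit)
        c1b = c1.copy_with(3.0 * c1.values + 10.0)
        z2 = overlay_quality_zoning({"a": c1b, "b": c2}, suit)
        np.testing.assert_allclose(
            z1.score.values[z1.score.mask], z2.score.values[z2.score.mask], atol=1e-12
        )

    def test_empty_masked_region_rejected(self):
        stack, suit = _stack_and_suit(seed=8)
        content = suit.copy_with(np.ones(suit.values.shape), name="c")
        with pytest.raises(EmptyDomainError):
            overlay_quality_zoning({"c": content}, suit, mask_threshold=1.01 - 1e-9)
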