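import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from relaxrepro import (
    DesignConfig,
    UndefinedAgreementError,
    agreement_report,
    bland_altman,
    ccc,
    classify_cov,
    cov_pairs,
)


def ccc_oracle(x, y):
    """Direct-formula evaluation of Lin's estimator with 1/n moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    mx, my = x.sum() / n, y.sum() / n
    sx2 = ((x - mx) ** 2).sum() / n
    sy2 = ((y - my) ** 2).sum() / n
    sxy = ((x - mx) * (y - my)).sum() / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


class TestCCC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        c, ci = ccc(x, x)
        assert c == 1.0
        assert ci == (1.0, 1.0)

    def test_perfect_disagreement(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        c, _ = ccc(x, -x)
        assert c == -1.0

    def test_fixed_example_matches_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.1, 2.1, 2.9, 4.2]
        c, _ = ccc(x, y)
        assert c == pytest.approx(ccc_oracle(x, y), abs=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=arrays(np.float64, 12, elements=st.floats(1.0, 100.0)),
        y=arrays(np.float64, 12, elements=st.floats(1.0, 100.0)),
    )
    def test_matches_oracle_and_is_bounded(self, x, y):
        if np.var(x) == 0 and np.var(y) == 0:
            return
        c, ci = ccc(x, y)
        assert c == pytest.approx(ccc_oracle(x, y), abs=1e-10)
        assert -1.0 <= c <= 1.0
        assert ci[0] <= c <= ci[1]
        # symmetry is exact
        assert ccc(y, x)[0] == c
        # accuracy coefficient <= 1: |CCC| <= |Pearson r|
        if np.var(x) > 0 and np.var(y) > 0:
            r = np.corrcoef(x, y)[0, 1]
            assert abs(c) <= abs(r) + 1e-12

    def test_both_constant_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            ccc(np.full(5, 3.0), np.full(5, 4.0))

    def test_ci_behaves_like_lin(self):
        rng = np.random.default_rng(1)
        truth = rng.uniform(10, 30, 15)
        x = truth + rng.normal(0, 1, 15)
        y = truth + rng.normal(0, 1, 15)
        c, (lo, hi) = ccc(x, y)
        assert lo < c < hi
        assert hi - lo < 0.5


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0
        assert ba.loa95 == (0.0, 0.0)

    def test_pure_bias(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x + 3.0)
        assert ba.mean_diff == pytest.approx(-3.0)
        assert ba.loa95 == pytest.approx((-3.0, -3.0))

    def test_hand_arithmetic(self):
        """d = [1, -1, 2, -2]: mean 0, SD = sqrt(10/3), LOA = +/- 1.96*SD."""
        y = np.array([10.0, 10.0, 10.0, 10.0])
        x = y + np.array([1.0, -1.0, 2.0, -2.0])
        ba = bland_altman(x, y)
        sd = np.sqrt(10.0 / 3.0)
        assert ba.mean_diff == 0.0
        assert ba.loa95[0] == pytest.approx(-1.96 * sd, rel=1e-12)
        assert ba.loa95[1] == pytest.approx(1.96 * sd, rel=1e-12)

    def test_loa_covers_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(2024)
        d = rng.normal(0.3, 1.7, 100_000)
        ba = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= ba.loa95[0]) & (d <= ba.loa95[1]))
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestCoV:
    def test_identical_pairs_zero(self):
        assert cov_pairs(x=[10.0, 20.0], y=[10.0, 20.0]) == 0.0

    def test_single_pair_hand_arithmetic(self):
        """(10, 12): two-point SD = 2/sqrt(2), mean 11 -> CoV ~ 12.856%."""
        cov = cov_pairs(x=[10.0], y=[12.0])
        assert cov == pytest.approx(100.0 * np.sqrt(2.0) / 11.0, rel=1e-12)
        assert cov == pytest.approx(12.856, abs=5e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(10, 30, 20)
        y = x + rng.normal(0, 1, 20)
        assert cov_pairs(x=x, y=y) == pytest.approx(cov_pairs(x=7.3 * x, y=7.3 * y), rel=1e-12)

    def test_rms_aggregation_at_least_mean(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(10, 30, 20)
        y = x + rng.normal(0, 1, 20)
        assert cov_pairs(x=x, y=y, agg="rms") >= cov_pairs(x=x, y=y, agg="mean")

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cov_pairs(x=[1.0], y=[-1.0])


class TestClassifyCov:
    @pytest.mark.parametrize(
        "cov,expected",
        [
            (4.43, "excellent"),
            (5.82, "good"),
            (5.0, "excellent"),
            (10.0, "good"),
            (20.0, "moderate"),
            (20.01, "poor"),
            (0.0, "excellent"),
        ],
    )
    def test_bands(self, cov, expected):
        assert classify_cov(cov) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_cov(-0.1)


def make_table(n_subjects=10, noise=0.0, seed=0, bias_reader2=0.0):
    """Long-format measurement table with a known latent truth."""
    rng = np.random.default_rng(seed)
    rows = []
    for w, base in (("T2star", 15.0), ("T2", 40.0)):
        truth = base + rng.uniform(-5, 5, n_subjects)
        for s in range(n_subjects):
            for acq in (1, 2):
                for reader in ("reader1", "reader2"):
                    val = truth[s] + rng.normal(0, noise) + (bias_reader2 if reader == "reader2" else 0)
                    rows.append(
                        dict(subject_id=f"S{s:02d}", field_strength=7.0, weighting=w,
                             contrast_state="pre", acquisition_index=acq,
                             reader_id=reader, mean_T=val)
                    )
    return pd.DataFrame(rows)


class TestAgreementReport:
    def test_duplicate_measurements_give_perfect_agreement(self):
        report = agreement_report(make_table(noise=0.0))
        assert len(report.results) == 8  # 2 weightings x (2 readers + 2 acquisitions)
        for r in report.results:
            assert r.ccc == pytest.approx(1.0)
            assert r.cov_percent == 0.0
            assert r.cov_class == "excellent"
            assert r.mean_diff == 0.0

    def test_empty_table_gives_empty_report(self):
        report = agreement_report(pd.DataFrame())
        assert report.results == []
        assert len(report.pairs) == 0

    def test_incomplete_cells_warned_and_skipped(self):
        table = make_table(n_subjects=5, noise=0.1)
        # drop one subject's second acquisition for reader1/T2star
        drop = (
            (table.subject_id == "S00") & (table.acquisition_index == 2)
            & (table.reader_id == "reader1") & (table.weighting == "T2star")
        )
        with pytest.warns(UserWarning, match="incomplete"):
            report = agreement_report(table[~drop])
        rep = {r.label: r for r in report.results}
        assert rep["T2star|repeatability|reader1"].n == 4
        assert rep["T2star|repeatability|reader2"].n == 5

    def test_stratified_design_multiplies_rows(self):
        table = make_table(noise=0.05)
        pooled = agreement_report(table, DesignConfig())
        stratified = agreement_report(
            table, DesignConfig(pool_over=("contrast_state",))
        )
        assert len(stratified.results) == len(pooled.results)  # single field here
        assert all(r.field_strength == "7.0" for r in stratified.results)

    def test_pairs_table_supports_bland_altman_replot(self):
        report = agreement_report(make_table(noise=0.2))
        assert set(["label", "unit", "x", "y", "pair_mean", "pair_diff"]) <= set(report.pairs.columns)
        assert np.allclose(report.pairs.pair_diff, report.pairs.x - report.pairs.y)

    def test_noise_degrades_cov_and_ccc_monotonically(self):
        """Across a noise grid, CoV rises and CCC falls (Spearman >= 0.9)."""
        noise_levels = [0.05, 0.2, 0.5, 1.0, 2.0]
        covs, cccs = [], []
        for i, noise in enumerate(noise_levels):
            per_rep_cov, per_rep_ccc = [], []
            for rep in range(10):
                rng = np.random.default_rng(1000 + 7 * i + rep)
                truth = rng.uniform(10, 30, 25)
                x = truth + rng.normal(0, noise, truth.size)
                y = truth + rng.normal(0, noise, truth.size)
                per_rep_cov.append(cov_pairs(x=x, y=y))
                per_rep_ccc.append(ccc(x, y)[0])
            covs.append(np.mean(per_rep_cov))
            cccs.append(np.mean(per_rep_ccc))
        assert stats.spearmanr(noise_levels, covs).statistic >= 0.9
        assert stats.spearmanr(noise_levels, cccs).statistic <= -0.9
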