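import numpy as np
import pandas as pd
import pytest

from subfieldseq.core import Contrast, PipelineError
from subfieldseq.de import (
    bh_adjust,
    detected_genes,
    estimate_dispersion,
    estimate_dispersion_within,
    nb_wald_test,
    one_tailed_p,
    size_factors,
)

from conftest import make_count_matrix, make_sheet


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix([[5, 5, 5], [9, 9, 9]])
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_proportional_columns_closed_form(self):
        # column2 = 2 x column1: geometric mean sqrt(2)*c, so the
        # median-of-ratios factors are (1/sqrt(2), sqrt(2))
        cm = make_count_matrix([[10, 20], [3, 6], [7, 14]])
        np.testing.assert_allclose(
            size_factors(cm), [2**-0.5, 2**0.5], rtol=1e-12
        )

    def test_single_sample_gets_unit_factor(self):
        assert size_factors(make_count_matrix([[4], [1]])) == pytest.approx(1.0)

    def test_error_when_no_gene_covers_all_samples(self):
        cm = make_count_matrix([[0, 5], [5, 0]])
        with pytest.raises(PipelineError, match="nonzero"):
            size_factors(cm)

    def test_column_scaling_scales_relative_factor(self):
        """Tripling one sample's counts triples its size factor relative to
        the others (the geometric-mean reference shifts, so only factor
        ratios are identifiable)."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(100, 4))
        base = size_factors(make_count_matrix(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 3
        new = size_factors(make_count_matrix(scaled))
        assert (new[2] / new[0]) / (base[2] / base[0]) == pytest.approx(
            3.0, rel=1e-12
        )

    def test_agrees_with_pydeseq2(self):
        """Independent cross-check against the reference median-of-ratios
        implementation."""
        anndata = pytest.importorskip("anndata")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(5, 0.05, size=(60, 8))
        metadata = pd.DataFrame(
            {"condition": ["a"] * 4 + ["b"] * 4},
            index=[f"s{j}" for j in range(8)],
        )
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts.T, index=metadata.index),
            metadata=metadata,
            design="~condition",
            quiet=True,
        )
        dds.fit_size_factors()
        np.testing.assert_allclose(
            size_factors(make_count_matrix(counts)),
            dds.obs["size_factors"].to_numpy(),
            rtol=1e-8,
        )


class TestDispersion:
    def test_method_of_moments_worked_value(self):
        # mean 10, sample variance 30 -> alpha = (30 - 10) / 100 = 0.2
        x = np.array([[10.0, 10 - np.sqrt(30), 10 + np.sqrt(30)]])
        alpha = estimate_dispersion(x, np.ones(3))
        assert alpha[0] == pytest.approx((30 - 10) / 100)

    def test_underdispersed_gene_gets_floor(self):
        x = np.array([[9, 10, 11]])  # variance 1 << mean 10
        assert estimate_dispersion(x, np.ones(3))[0] == pytest.approx(1e-8)

    def test_poisson_gene_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(50, size=(1, 1000)).astype(float)
        alpha = estimate_dispersion(x, np.ones(1000))[0]
        # MoM noise floor: |alpha| < a few / (mu * sqrt(n))
        assert alpha < 5 / (50 * np.sqrt(1000))

    def test_within_group_estimator_ignores_group_shift(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.poisson(50, (200, 10)), rng.poisson(200, (200, 10))], axis=1
        ).astype(float)
        group = np.array([0] * 10 + [1] * 10)
        pooled = estimate_dispersion(x, np.ones(20))
        within = estimate_dispersion_within(x, np.ones(20), group)
        # the pooled estimator mistakes the group shift for overdispersion
        assert np.median(pooled) > 0.1
        assert np.median(within) < 0.02


class TestWaldTest:
    def _run(self, counts, n1, n2, **kwargs):
        cm = make_count_matrix(counts)
        sheet = make_sheet(n1, n2)
        contrast = Contrast("age_group", "young", "aged")
        return nb_wald_test(cm, sheet, contrast, **kwargs)

    def test_identical_groups_give_zero_lfc_unit_p(self):
        counts = np.tile([[10, 20, 30, 10, 20, 30]], (3, 1))
        res = self._run(counts, 3, 3)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-10)
        np.testing.assert_allclose(res["p_two"], 1.0, atol=1e-10)

    def test_lfc_matches_closed_form_group_means(self):
        """With equal size factors within a group the NB score equation is
        solved exactly by the plain group mean, whatever the dispersion, so
        the saturated fit has a closed form to compare against."""
        from subfieldseq.de import _fit_group_log_means

        rng = np.random.default_rng(5)
        values = rng.poisson(40, size=(50, 6)).astype(float) + 1.0
        alpha = np.full(50, 0.3)
        beta, _, converged = _fit_group_log_means(values, np.ones(6), alpha)
        assert converged.all()
        np.testing.assert_allclose(
            beta / np.log(2), np.log2(values.mean(axis=1)), atol=1e-6
        )

    def test_agrees_with_statsmodels_glm(self):
        """Coefficient and SE cross-check against an independent NB GLM fit
        (statsmodels, same fixed dispersion and offsets)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        counts = rng.negative_binomial(10, 10 / (10 + 80.0), size=(5, 12))
        cm = make_count_matrix(counts)
        sheet = make_sheet(6, 6)
        alpha = np.full(5, 0.1)
        res = nb_wald_test(
            cm, sheet, Contrast("age_group", "young", "aged"), dispersions=alpha
        )
        sf = size_factors(cm)
        X = sm.add_constant(np.repeat([0.0, 1.0], 6))
        for i in range(5):
            fit = sm.GLM(
                counts[i],
                X,
                family=sm.families.NegativeBinomial(alpha=0.1),
                offset=np.log(sf),
            ).fit()
            assert res.loc[i, "log2fc"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-5
            )
            assert res.loc[i, "se"] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3
            )

    def test_scaling_a_sample_leaves_lfc_unshifted(self):
        """Normalization correctness: quadrupling one sample's depth leaves
        fold changes without systematic shift.  (Exact per-gene invariance
        cannot hold — the NB likelihood weights samples by depth — so the
        check is on the distribution of differences.)"""
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=(200, 8))
        res1 = self._run(counts, 4, 4)
        scaled = counts.copy()
        scaled[:, 0] *= 4
        res2 = self._run(scaled, 4, 4)
        keep = (res1["detected"] & res2["detected"]).to_numpy()
        diff = (res2["log2fc"] - res1["log2fc"])[keep]
        assert abs(diff.mean()) < 0.01
        assert diff.abs().max() < 0.2

    def test_null_type_i_error_close_to_nominal(self):
        rng = np.random.default_rng(8)
        mu = np.exp(rng.normal(4, 1, 2000))[:, None]
        size = 1 / 0.1
        counts = rng.negative_binomial(size, size / (size + mu), size=(2000, 24))
        res = self._run(counts, 12, 12)
        p = res.loc[res["detected"], "p_two"].dropna()
        frac = (p < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=4 * np.sqrt(0.05 * 0.95 / len(p)))

    def test_power_monotone_in_effect_and_n(self):
        """Sign-balanced planted effects (so normalization is unaffected)
        in 40% of genes; power measured on the planted subset."""
        rng = np.random.default_rng(9)
        power = {}
        planted = np.zeros(500, bool)
        planted[:200] = True
        signs = np.where(np.arange(200) % 2 == 0, 1.0, -1.0)
        for delta in (0.0, 0.5, 1.0):
            for n in (5, 20):
                mu = np.full((500, 2 * n), 100.0)
                mu[:200, n:] *= 2 ** (delta * signs[:, None])
                counts = rng.negative_binomial(10, 10 / (10 + mu))
                res = self._run(counts, n, n)
                power[(delta, n)] = (res["p_two"][planted] < 0.05).mean()
        assert power[(0.0, 20)] < power[(0.5, 20)] < power[(1.0, 20)]
        assert power[(0.5, 5)] < power[(0.5, 20)]
        assert power[(1.0, 5)] < power[(1.0, 20)]

    def test_undetected_genes_have_no_p_values(self):
        counts = np.vstack([[0, 0, 1, 0, 0, 0], [9, 9, 9, 9, 9, 9]])
        res = self._run(counts, 3, 3)
        assert not res.loc[0, "detected"]
        assert np.isnan(res.loc[0, "p_two"]) and np.isnan(res.loc[0, "p_adj"])

    def test_p_adj_at_least_p_two(self, small_sim):
        res = nb_wald_test(
            small_sim["counts_a"],
            small_sim["sheet"],
            Contrast("region", "CA1", "CA3"),
        )
        ok = res["p_adj"].notna()
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p_two"] - 1e-12).all()


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.001, 1.0], [0.002, 1.0]),
        ],
    )
    def test_hand_worked_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(PipelineError):
            bh_adjust([0.5, 1.2])

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(10)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestOneTailed:
    @pytest.mark.parametrize(
        "p_two, lfc, sign, expected",
        [
            (0.04, 1.2, 1, 0.02),
            (0.04, -1.2, 1, 0.98),
            (0.04, -0.3, -1, 0.02),
            (0.5, 0.0, 1, 1.0),
        ],
    )
    def test_directional_conversion(self, p_two, lfc, sign, expected):
        assert one_tailed_p(p_two, lfc, sign) == pytest.approx(expected)

    def test_rejects_zero_expected_sign(self):
        with pytest.raises(PipelineError):
            one_tailed_p(0.5, 1.0, 0)


def test_detection_rule_counts_nonzero_samples():
    counts = np.array([[0, 0, 0, 5], [1, 1, 1, 0], [2, 0, 3, 1]])
    np.testing.assert_array_equal(
        detected_genes(counts, min_samples=3), [False, True, True]
    )
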