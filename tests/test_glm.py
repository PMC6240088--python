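"""Specialisation detection: DCT bases, design assembly, partial F, maps, CVA."""

import numpy as np
import pytest
from scipy import stats

from meabayes import generative as g
from meabayes import glm
from meabayes import recordings as rec


@pytest.fixture(scope="module")
def protocol():
    sources = g.sample_sources(4, 256, seed=41)
    stimuli = g.sample_stimuli(sources, seed=41)
    return sources, stimuli


class TestDctBasis:
    @pytest.mark.parametrize("n,k", [(256, 8), (1000, 33), (64, 64)])
    def test_orthonormal(self, n, k):
        B = glm.dct_basis(n, k)
        assert np.allclose(B.T @ B, np.eye(k), atol=1e-10)

    def test_single_component_is_constant(self):
        B = glm.dct_basis(100, 1)
        assert np.allclose(B, B[0, 0])

    def test_non_dc_columns_have_zero_mean(self):
        B = glm.dct_basis(256, 8)
        assert np.all(np.abs(B[:, 1:].mean(axis=0)) < 1e-12)

    @pytest.mark.parametrize("n,k", [(10, 0), (10, 11)])
    def test_invalid_sizes_rejected(self, n, k):
        with pytest.raises(ValueError):
            glm.dct_basis(n, k)


class TestBuildDesign:
    def test_column_layout(self, protocol):
        sources, stimuli = protocol
        stim_e = int(stimuli.site_map[0])
        d = glm.build_design(sources, stimuli, stim_e)
        assert d.p == 8 + 36  # 8 interest; own-site, total, 32 drift, other, const
        assert len(d.interest) == 8
        assert "own_site_stim" in d.labels
        unstim_e = int(np.setdiff1d(np.arange(64), stimuli.site_map)[0])
        d2 = glm.build_design(sources, stimuli, unstim_e)
        assert d2.p == 8 + 35 and "own_site_stim" not in d2.labels

    def test_interest_nearly_orthogonal_to_intercept(self, protocol):
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 0)
        for j in d.interest:
            col = d.X[:, j]
            corr = col.mean() / (col.std() + 1e-30) * np.sqrt(len(col))
            assert abs(corr) < 3.5  # centred indicator: only sampling noise remains

    def test_constant_source_flags_rank_deficiency(self, protocol):
        _, stimuli = protocol
        n = stimuli.n_epochs
        const_sources = g.SourceTrain(
            states=np.column_stack([np.ones(n, int), np.zeros(n, int)]),
            session_index=np.zeros(n),
        )
        d = glm.build_design(const_sources, stimuli, 0)
        assert d.rank_deficient


class TestFitGlm:
    def test_confound_combination_gives_zero_F(self, protocol, rng):
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 3)
        y = d.X[:, d.confounds] @ rng.normal(size=len(d.confounds))
        fit = glm.fit_glm(y, d)
        assert fit.F == pytest.approx(0.0, abs=1e-8)

    def test_confound_invariance(self, protocol, rng):
        """Adding any confound combination to y leaves the partial F unchanged."""
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 5)
        y = rng.normal(size=d.n)
        f0 = glm.fit_glm(y, d).F
        y2 = y + d.X[:, d.confounds] @ rng.normal(size=len(d.confounds))
        assert glm.fit_glm(y2, d).F == pytest.approx(f0, abs=1e-8)

    def test_partial_f_matches_statsmodels(self, protocol, rng):
        """Dual-route check: the extra-sum-of-squares F equals the linear
        restriction test of a reference OLS implementation."""
        import statsmodels.api as sm

        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 7)
        R = np.zeros((len(d.interest), d.p))
        R[np.arange(len(d.interest)), d.interest] = 1.0
        for _ in range(10):
            y = rng.normal(size=d.n)
            fit = glm.fit_glm(y, d)
            ref = sm.OLS(y, d.X).fit().f_test(R)
            assert fit.F == pytest.approx(float(ref.fvalue), rel=1e-10)
            assert fit.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_null_pvalue_calibration(self, protocol):
        """Gaussian null responses: partial-F p < 0.05 in 5% +- 2% of fits."""
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 7)
        null_rng = np.random.default_rng(0)
        hits = sum(glm.fit_glm(null_rng.normal(size=d.n), d).pvalue < 0.05
                   for _ in range(1000))
        assert abs(hits / 1000 - 0.05) < 0.02

    def test_known_coefficients_recovered(self, protocol, rng):
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 9)
        beta = np.zeros(d.p)
        beta[d.interest] = rng.normal(0, 0.5, len(d.interest))
        y = d.X @ beta + 0.1 * rng.normal(size=d.n)
        fit = glm.fit_glm(y, d)
        cov = fit.sigma2 * np.linalg.pinv(d.X.T @ d.X)
        se = np.sqrt(np.diag(cov))[d.interest]
        assert np.all(np.abs(fit.coef[d.interest] - beta[d.interest]) < 3 * se)

    def test_zero_variance_response_rejected(self, protocol):
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 0)
        with pytest.raises(ValueError):
            glm.fit_glm(np.ones(d.n), d)

    def test_learning_curve_is_present_minus_absent(self, protocol, rng):
        sources, stimuli = protocol
        d = glm.build_design(sources, stimuli, 2)
        fit = glm.fit_glm(rng.normal(size=d.n), d)
        assert np.allclose(fit.learning_curve, fit.present_trace - fit.absent_trace)


class TestFMap:
    def test_shape_and_planted_argmax(self, protocol, rng):
        sources, stimuli = protocol
        n = sources.n_epochs
        Y = rng.normal(size=(64, n))
        target = 13
        # emerging selectivity: a constant source effect would be absorbed by
        # the stimulation confounds (it is stimulation-evoked on average)
        ramp = np.linspace(0, 1, n)
        Y[target] += 3.0 * (sources.states[:, 0] - 0.5) * ramp
        fits = glm.fit_all_electrodes(Y, sources, stimuli)
        fmap = glm.f_map(fits)
        assert fmap.shape == (8, 8)
        assert np.nanargmax(fmap) == target

    def test_null_map_calibrated_at_high_quantile(self, protocol, rng):
        """Across null recordings the fraction of F values above the 99.9th
        percentile of the reference F distribution matches 0.1%."""
        sources, stimuli = protocol
        exceed = total = 0
        for run in range(10):
            Y = rng.normal(size=(64, sources.n_epochs))
            fits = glm.fit_all_electrodes(Y, sources, stimuli)
            for f in fits:
                q = stats.f.ppf(0.999, *f.df)
                exceed += f.F > q
                total += 1
        assert exceed / total < 0.005


class TestSelectResponses:
    def test_max_f_picks_planted_electrode(self, protocol, rng):
        sources, stimuli = protocol
        n = sources.n_epochs
        Y = rng.normal(size=(64, n))
        Y[22] += 3.0 * (sources.states[:, 0] - 0.5) * np.linspace(0, 1, n)
        fits = glm.fit_all_electrodes(Y, sources, stimuli)
        sel = glm.select_responses(Y, fits, sources, stimuli, mode="max_f")
        assert sel.electrodes.tolist() == [22]

    def test_infinite_threshold_gives_empty_selection(self, protocol, rng):
        sources, stimuli = protocol
        Y = rng.normal(size=(64, sources.n_epochs))
        fits = glm.fit_all_electrodes(Y, sources, stimuli)
        sel = glm.select_responses(Y, fits, sources, stimuli,
                                   mode="threshold_mean", threshold=np.inf)
        assert sel.empty and sel.series is None

    def test_modes_agree_on_closed_loop_data(self, loop8):
        """Max-F, threshold-mean and CVA learning curves tell the same story."""
        fits = loop8.fits["true", 0]
        curves = []
        for mode in ("max_f", "threshold_mean", "cva"):
            sel = glm.select_responses(
                loop8.recording.counts, fits, loop8.sources, loop8.stimuli,
                mode=mode, threshold=80.0,
            )
            assert not sel.empty
            curves.append(sel.fit.learning_curve)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.corrcoef(curves[i], curves[j])[0, 1] > 0.8


class TestCva:
    def test_weight_concentrates_on_planted_electrode(self, protocol, rng):
        sources, stimuli = protocol
        n = sources.n_epochs
        Y = rng.normal(size=(n, 12))
        Y[:, 4] += 1.5 * (sources.states[:, 0] - 0.5) * np.linspace(0, 1, n)
        res = glm.cva(Y, sources, stimuli)
        assert np.argmax(np.abs(res.weights)) == 4

    def test_rotation_invariance(self, protocol, rng):
        sources, stimuli = protocol
        n = sources.n_epochs
        Y = rng.normal(size=(n, 10))
        Y[:, 2] += 0.6 * (sources.states[:, 0] - 0.5) * np.linspace(0, 1, n)
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        r1 = glm.cva(Y, sources, stimuli)
        r2 = glm.cva(Y @ Q, sources, stimuli)
        assert np.max(np.abs(r1.variate - r2.variate)) < 1e-8

    def test_null_data_not_significant(self, rng):
        """Wilks test of the first canonical variate is calibrated under null."""
        sources = g.sample_sources(1, 256, seed=55)
        stimuli = g.sample_stimuli(sources, seed=55)
        nonsig = sum(
            glm.cva(rng.normal(size=(256, 12)), sources, stimuli,
                    k_drift=16).wilks_pvalue > 0.05
            for _ in range(100)
        )
        assert nonsig >= 90
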