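"""Hierarchical beta-MPT estimation, T1 fit, classification, contrasts."""

import numpy as np
import pytest

from quadbias.fit_bayes import (
    FitClassification,
    HierarchicalConfig,
    PosteriorSummary,
    T1Result,
    classify_by_fit,
    contrast_posterior,
    fit_hierarchical,
    param_vs_zero,
    t1_fit,
)
from quadbias.iat_data import CELLS, ResponseCountTable
from quadbias.quad_core import QuadParameters, simulate_counts

from conftest import simulate_participants

SMALL = HierarchicalConfig(n_chains=2, n_warmup=300, n_samples=1000, seed=5)


@pytest.fixture(scope="module")
def small_fit(outgroup_spec):
    """40 participants x 120 trials, moderate concentration: a quick fit
    shared by the read-out tests."""
    tables, _ = simulate_participants(
        outgroup_spec, (0.25, 0.10, 0.85, 0.50, 0.55), 20.0,
        n_participants=40, trials_per_cell=15, seed=31,
    )
    return tables, fit_hierarchical(tables, outgroup_spec, SMALL)


class TestSampler:
    def test_reproducible_under_seed(self, outgroup_spec):
        tables, _ = simulate_participants(
            outgroup_spec, (0.3, 0.1, 0.85, 0.5, 0.5), 20.0, 8, 15, seed=2
        )
        cfg = HierarchicalConfig(n_chains=2, n_warmup=100, n_samples=1000, seed=9)
        a = fit_hierarchical(tables, outgroup_spec, cfg)
        b = fit_hierarchical(tables, outgroup_spec, cfg)
        for p in a.group_mean_draws:
            assert np.array_equal(a.group_mean_draws[p], b.group_mean_draws[p])
        assert np.array_equal(a.individual_draws, b.individual_draws)

    def test_identical_participants_get_similar_estimates(self, outgroup_spec):
        params = QuadParameters(0.3, 0.1, 0.9, 0.5, 0.5)
        table = simulate_counts(params, outgroup_spec, 2000, seed=0)
        cfg = HierarchicalConfig(n_chains=2, n_warmup=1500, n_samples=2000, seed=5)
        fit = fit_hierarchical([table, table], outgroup_spec, cfg)
        est = fit.individual_estimates
        assert np.allclose(est[0], est[1], atol=0.05)

    def test_rejects_degenerate_inputs(self, outgroup_spec):
        with pytest.raises(ValueError):
            fit_hierarchical([], outgroup_spec, SMALL)
        empty = ResponseCountTable({c: (0, 0) for c in CELLS})
        with pytest.raises(ValueError):
            fit_hierarchical([empty, empty], outgroup_spec, SMALL)

    def test_group_mean_draws_in_unit_interval(self, small_fit):
        _, post = small_fit
        for p, draws in post.group_mean_draws.items():
            assert draws.shape == (2, 1000)
            assert np.all((draws > 0) & (draws < 1))
        assert all(np.isfinite(v) for v in post.rhat.values())


class TestT1:
    def test_self_consistent_data_fits(self, small_fit, outgroup_spec):
        """Data simulated from the fitted model family: group-level ppp in
        the calibrated middle range."""
        tables, post = small_fit
        res = t1_fit(post, tables, level="group")
        assert isinstance(res, T1Result)
        assert 0.05 < res.ppp < 0.99

    def test_constructed_misfit_detected(self, small_fit, outgroup_spec):
        """Grossly misfitting data — all errors packed into one cell —
        must yield a tiny posterior-predictive p."""
        tables, post = small_fit
        bad_counts = {c: (15, 0) for c in CELLS}
        bad_counts[CELLS[0]] = (0, 15)
        bad = [ResponseCountTable(bad_counts)] * len(tables)
        res = t1_fit(post, bad, level="group")
        assert res.ppp < 0.05

    def test_participant_level_shapes(self, small_fit):
        tables, post = small_fit
        res = t1_fit(post, tables, level="participant", n_draws=200)
        assert len(res) == len(tables)
        assert all(0.0 <= r.ppp <= 1.0 for r in res)


class TestClassification:
    @pytest.mark.parametrize(
        "ppp_out, ppp_in, expected",
        [
            (0.60, 0.02, FitClassification.OUTGROUP_BIASED),
            (0.02, 0.60, FitClassification.INGROUP_BIASED),
            (0.03, 0.04, FitClassification.EXCLUDED),  # neither fits
            (0.50, 0.495, FitClassification.EXCLUDED),  # tie window
            (0.30, 0.60, FitClassification.INGROUP_BIASED),
        ],
    )
    def test_tie_and_threshold_rules(self, monkeypatch, small_fit,
                                     ppp_out, ppp_in, expected):
        """Decision logic probed with controlled ppp values."""
        import quadbias.fit_bayes as fb

        tables, post = small_fit

        def fake_t1(posterior, tabs, level, n_draws=500, seed=None):
            ppp = ppp_out if posterior is post_out else ppp_in
            return [T1Result(1.0, np.array([1.0]), ppp) for _ in tabs]

        import copy

        post_out = post
        post_in = copy.copy(post)
        monkeypatch.setattr(fb, "t1_fit", fake_t1)
        labels = fb.classify_by_fit(tables[:3], post_out, post_in)
        assert labels == [expected] * 3

    def test_dominant_outgroup_structure_classified_outgroup(
        self, outgroup_spec, ingroup_spec
    ):
        """Participants generated with a dominant outgroup-pleasant /
        ingroup-unpleasant association pattern should be labeled
        outgroup-biased at least 3x as often as ingroup-biased."""
        tables, _ = simulate_participants(
            outgroup_spec, (0.30, 0.10, 0.85, 0.50, 0.55), 20.0,
            n_participants=200, trials_per_cell=15, seed=77,
        )
        cfg = HierarchicalConfig(n_chains=2, n_warmup=400, n_samples=1000, seed=3)
        fit_out = fit_hierarchical(tables, outgroup_spec, cfg)
        fit_in = fit_hierarchical(tables, ingroup_spec, cfg)
        labels = classify_by_fit(tables, fit_out, fit_in, t1_seed=101)
        n_out = labels.count(FitClassification.OUTGROUP_BIASED)
        n_in = labels.count(FitClassification.INGROUP_BIASED)
        assert n_out >= 3 * max(n_in, 1)


class TestContrasts:
    def test_identical_params_zero_contrast(self, small_fit):
        _, post = small_fit
        res = contrast_posterior(post, "ac_a", "ac_a")
        assert res.mean_difference == 0.0
        assert (res.bci_low, res.bci_high) == (0.0, 0.0)
        assert not res.excludes_zero

    def test_antisymmetry(self, small_fit):
        _, post = small_fit
        ab = contrast_posterior(post, "ac_a", "ac_b")
        ba = contrast_posterior(post, "ac_b", "ac_a")
        assert ab.mean_difference == pytest.approx(-ba.mean_difference, abs=1e-12)
        assert ab.bci_low == pytest.approx(-ba.bci_high, abs=1e-12)

    def test_bci_contains_median(self, small_fit):
        _, post = small_fit
        res = contrast_posterior(post, "ac_a", "ac_b")
        diff = post.pooled_group_means("ac_a") - post.pooled_group_means("ac_b")
        assert res.bci_low <= np.median(diff) <= res.bci_high

    def test_shifted_draws(self, small_fit):
        _, post = small_fit
        shifted = PosteriorSummary(
            participant_ids=post.participant_ids,
            spec=post.spec,
            config=post.config,
            group_mean_draws={
                "ac_a": post.group_mean_draws["ac_b"] + 0.02,
                "ac_b": post.group_mean_draws["ac_b"],
            },
            kappa_draws=post.kappa_draws,
            individual_draws=post.individual_draws,
            rhat=post.rhat,
            ess=post.ess,
            converged=post.converged,
        )
        res = contrast_posterior(shifted, "ac_a", "ac_b")
        assert res.mean_difference == pytest.approx(0.02, abs=1e-12)
        assert res.excludes_zero

    def test_param_vs_zero_vacuous_threshold(self, small_fit):
        _, post = small_fit
        distinguishable, bci = param_vs_zero(post, "ac_a", near_zero_delta=1.0)
        assert not distinguishable
        assert 0.0 <= bci[0] <= bci[1] <= 1.0

    def test_param_vs_zero_clear_signal(self, small_fit):
        _, post = small_fit
        # d_detect generated at 0.85 with 40 participants: unambiguous
        distinguishable, _ = param_vs_zero(post, "d_detect")
        assert distinguishable
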