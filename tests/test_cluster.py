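"""Cluster-model forward evaluation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpnmr import (
    ClusterComponent,
    ClusterModelParams,
    PeptideSequence,
    ResidueTable,
    SimulationConfig,
    compare_variants,
    fit_cluster_model,
    model_r2,
    residue_weights,
    simulate_r2_profile,
)


from oracles import brute_force_r2


class TestWeights:
    def test_size_weighted_rule_on_tc5b(self, tc5b):
        w = residue_weights(tc5b, "size_weighted")
        light = {int(i) for i, wi in zip(tc5b.indices, w) if wi == 1.0}
        assert light == {10, 11, 15}
        assert set(w) == {1.0, 7.0}

    def test_uniform_variant_all_ones(self, tc5b):
        assert np.all(residue_weights(tc5b, "uniform") == 1.0)

    def test_poly_gly_identical_in_both_variants(self):
        seq = PeptideSequence("GGGGGG")
        np.testing.assert_array_equal(
            residue_weights(seq, "size_weighted"),
            residue_weights(seq, "uniform"),
        )


class TestModelR2:
    def test_zero_components_equals_baseline(self, tc5b):
        w = residue_weights(tc5b)
        p = ClusterModelParams(0.05, 2.0, w)
        np.testing.assert_allclose(model_r2(p, tc5b), brute_force_r2(p, tc5b))

    def test_small_lambda_collapses_to_self_term(self, tc5b):
        w = residue_weights(tc5b)
        p = ClusterModelParams(0.05, 0.05, w)
        np.testing.assert_allclose(model_r2(p, tc5b), 0.05 * w, rtol=1e-6)

    def test_single_component_matches_brute_force(self, tc5b):
        p = ClusterModelParams(
            0.05, 2.0, residue_weights(tc5b),
            [ClusterComponent(2.0, 8.0, 3.0)],
        )
        np.testing.assert_allclose(
            model_r2(p, tc5b), brute_force_r2(p, tc5b), rtol=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1.0),
        lam=st.floats(0.2, 15.0),
        r2c=st.floats(0.0, 5.0),
        xc=st.floats(-1.0, 22.0),
        delta=st.floats(0.5, 20.0),
    )
    def test_matches_brute_force_for_random_parameters(self, a, lam, r2c, xc, delta):
        seq = PeptideSequence("NLYIQWLKDGGPSSGRPPPS")
        p = ClusterModelParams(
            a, lam, residue_weights(seq), [ClusterComponent(r2c, xc, delta)]
        )
        np.testing.assert_allclose(
            model_r2(p, seq), brute_force_r2(p, seq), rtol=1e-12, atol=1e-14
        )

    def test_baseline_depends_only_on_weight_vector(self):
        a = PeptideSequence("NLYIQW")  # weights 7,7,7,7,7,7
        b = PeptideSequence("KDSSRT")
        pa = ClusterModelParams(0.1, 3.0, residue_weights(a))
        pb = ClusterModelParams(0.1, 3.0, residue_weights(b))
        np.testing.assert_allclose(model_r2(pa, a), model_r2(pb, b))

    def test_adding_component_never_decreases_prediction(self, tc5b):
        w = residue_weights(tc5b)
        p0 = ClusterModelParams(0.05, 2.0, w)
        p1 = ClusterModelParams(0.05, 2.0, w, [ClusterComponent(1.5, 14.0, 2.0)])
        assert np.all(model_r2(p1, tc5b) >= model_r2(p0, tc5b))

    def test_alternate_width_convention(self, tc5b):
        w = residue_weights(tc5b)
        p = ClusterModelParams(0.0, 2.0, w, [ClusterComponent(1.0, 8.0, 3.0)],
                               width_convention="decay")
        prof = model_r2(p, tc5b)
        # residue 7 sits one position off the center xc = 8
        assert prof[6] == pytest.approx(np.exp(-1.0 / 9.0))


class TestFit:
    def test_noiseless_self_consistency(self, tc5b):
        truth = ClusterModelParams(
            0.05, 2.0, residue_weights(tc5b), [ClusterComponent(2.0, 8.0, 3.0)]
        )
        profile = ResidueTable(tc5b.indices, model_r2(truth, tc5b))
        fit = fit_cluster_model(profile, tc5b, n_clusters=1)
        comp = fit.params.components[0]
        assert comp.xc == pytest.approx(8.0, abs=1e-4)
        assert comp.delta == pytest.approx(3.0, abs=1e-3)
        assert comp.r2c == pytest.approx(2.0, abs=1e-4)
        assert fit.params.lambda0 == pytest.approx(2.0, abs=1e-3)

    def test_predicted_equals_baseline_plus_clusters(self, tc5b, cfg):
        _, profile = simulate_r2_profile(cfg)
        fit = fit_cluster_model(profile, tc5b, n_clusters=1)
        cluster_sum = fit.predicted - fit.baseline
        assert np.all(cluster_sum >= -1e-10)
        recomputed = model_r2(fit.params, tc5b)
        np.testing.assert_allclose(fit.predicted, recomputed, rtol=1e-10)

    def test_renumbering_equivariance(self, tc5b, cfg):
        _, profile = simulate_r2_profile(cfg)
        fit1 = fit_cluster_model(profile, tc5b, n_clusters=1)
        shifted_seq = tc5b.renumbered(11)
        shifted = ResidueTable(profile.indices + 10, profile.values,
                               profile.sigmas)
        fit2 = fit_cluster_model(shifted, shifted_seq, n_clusters=1)
        assert fit2.params.components[0].xc == pytest.approx(
            fit1.params.components[0].xc + 10, abs=1e-3
        )

    def test_too_many_clusters_rejected(self, tc5b, cfg):
        _, profile = simulate_r2_profile(cfg)
        with pytest.raises(ValueError, match="identify"):
            fit_cluster_model(profile, tc5b, n_clusters=7)

    def test_all_masked_rejected(self, tc5b):
        profile = ResidueTable(tc5b.indices, np.ones(20),
                               mask=np.zeros(20, dtype=bool))
        with pytest.raises(ValueError, match="masked"):
            fit_cluster_model(profile, tc5b, n_clusters=1)

    def test_bootstrap_sigmas_present_and_positive(self, tc5b, cfg):
        _, profile = simulate_r2_profile(cfg)
        fit = fit_cluster_model(profile, tc5b, n_clusters=1, n_bootstrap=30,
                                seed=1)
        assert set(fit.param_sigmas) == {"a", "lambda0", "r2c1", "xc1", "delta1"}
        assert fit.param_sigmas["xc1"] > 0

    def test_masked_prolines_still_identify_cluster(self, tc5b, cfg):
        from idpnmr.simulate import proline_positions

        _, profile = simulate_r2_profile(cfg)
        profile = profile.masked_at(proline_positions(tc5b))
        fit = fit_cluster_model(profile, tc5b, n_clusters=1)
        assert fit.params.components[0].xc == pytest.approx(8.0, abs=1.0)


class TestCompareVariants:
    def test_both_variants_localize_uniform_truth(self, tc5b):
        cfg = SimulationConfig(seed=9)
        seq = tc5b
        truth = ClusterModelParams(
            0.2, 2.0, residue_weights(seq, "uniform"),
            [ClusterComponent(2.0, 8.0, 3.0)], variant="uniform",
        )
        rng = np.random.default_rng(cfg.seed)
        data = model_r2(truth, seq) + rng.normal(0, 0.1, len(seq))
        profile = ResidueTable(seq.indices, data, np.full(len(seq), 0.1))
        report = compare_variants(profile, seq, n_clusters=1)
        for variant, fit in report.items():
            assert fit.converged, variant
            assert fit.params.components[0].xc == pytest.approx(8.0, abs=1.0)

    def test_deterministic_given_seed(self, tc5b, cfg):
        _, profile = simulate_r2_profile(cfg)
        r1 = compare_variants(profile, tc5b, n_clusters=1, n_bootstrap=10, seed=5)
        r2 = compare_variants(profile, tc5b, n_clusters=1, n_bootstrap=10, seed=5)
        for v in r1:
            assert r1[v].params.components[0].xc == r2[v].params.components[0].xc
            assert r1[v].param_sigmas == r2[v].param_sigmas

    def test_all_masked_propagates_error(self, tc5b):
        profile = ResidueTable(tc5b.indices, np.ones(20),
                               mask=np.zeros(20, dtype=bool))
        with pytest.raises(ValueError):
            compare_variants(profile, tc5b, n_clusters=1)
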