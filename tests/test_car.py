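"""CAR engine tests: decomposition, odds, counterfactuals, closed forms,
epsilon policy, attribution maps, display thresholding, and interactive
overrides."""

import math

import numpy as np
import pytest

from carfundus import (
    DegenerateHeadError,
    EpsilonPolicy,
    FindingHead,
    attribution_map,
    car,
    car_matrix,
    counterfactual_latent,
    counterfactual_odds,
    coupling,
    decompose,
    disease_score,
    finding_score,
    icar,
    instance_icars,
    interactive_adjust,
    odds,
    pool_features,
    select_epsilon,
    top_findings,
)
from carfundus._util import logit, sigmoid
from conftest import random_bundle


class TestDecompose:
    def test_axis_aligned(self):
        head = FindingHead("f", np.array([1.0, 0.0]), 0.0)
        dec = decompose(np.array([2.0, 3.0]), head)
        assert dec.parallel_coeff == pytest.approx(2.0)
        np.testing.assert_allclose(dec.parallel_coeff * dec.direction, [2.0, 0.0])
        np.testing.assert_allclose(dec.orthogonal, [0.0, 3.0])

    def test_parallel_input_has_zero_orthogonal(self, rng):
        w = rng.normal(size=6)
        head = FindingHead("f", w, 0.1)
        dec = decompose(2.5 * w, head)
        np.testing.assert_allclose(dec.orthogonal, np.zeros(6), atol=1e-12)

    def test_reconstruction_and_orthogonality(self, rng):
        for _ in range(20):
            head = FindingHead("f", rng.normal(size=16), float(rng.normal()))
            z = rng.normal(size=16)
            dec = decompose(z, head)
            assert abs(dec.orthogonal @ dec.direction) < 1e-8
            np.testing.assert_allclose(dec.reconstruct(), z, atol=1e-8)

    def test_matches_brute_force_projection(self, rng):
        w = rng.normal(size=16)
        z = rng.normal(size=16)
        head = FindingHead("f", w, 0.0)
        dec = decompose(z, head)
        proj = np.outer(w, w) / (w @ w) @ z  # explicit projection matrix
        np.testing.assert_allclose(dec.parallel_coeff * dec.direction, proj, atol=1e-10)

    def test_unit_norm_convention_ties_coeff_to_logit(self, rng):
        """For unit-norm heads the parallel coefficient is logit(score) - bias."""
        w = rng.normal(size=8)
        head = FindingHead("f", w / np.linalg.norm(w), -0.4)
        z = rng.normal(size=8)
        dec = decompose(z, head)
        yhat = finding_score(head, z)
        assert dec.parallel_coeff == pytest.approx(logit(yhat) - head.bias, abs=1e-8)

    def test_zero_norm_weight_rejected(self):
        head = FindingHead("f", np.zeros(3), 0.0)
        with pytest.raises(DegenerateHeadError):
            decompose(np.ones(3), head)


class TestOdds:
    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (0.9, 9.0)])
    def test_known_values(self, p, expected):
        assert odds(p) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_boundary_rejected(self, p):
        with pytest.raises(ValueError):
            odds(p)

    def test_equals_exp_linear_score(self, rng, bundle, latents):
        for d, head in enumerate(bundle.diseases):
            from carfundus.heads import disease_linear
            p = disease_score(head, latents)
            assert odds(p) == pytest.approx(
                math.exp(disease_linear(head, latents)), rel=1e-8)


class TestCounterfactual:
    def test_counterfactual_score_equals_eps(self, rng):
        for _ in range(10):
            head = FindingHead("f", rng.normal(size=8), float(rng.normal()))
            z = rng.normal(size=8)
            eps = float(rng.uniform(0.001, 0.009))
            z_cf = counterfactual_latent(decompose(z, head), head, eps)
            assert finding_score(head, z_cf) == pytest.approx(eps, abs=1e-8)

    def test_eps_equal_to_prediction_is_identity(self, rng):
        head = FindingHead("f", rng.normal(size=8), 0.2)
        z = rng.normal(size=8)
        yhat = finding_score(head, z)
        z_cf = counterfactual_latent(decompose(z, head), head, yhat)
        np.testing.assert_allclose(z_cf, z, atol=1e-8)

    def test_orthogonal_component_untouched(self, rng):
        head = FindingHead("f", rng.normal(size=8), 0.0)
        z = rng.normal(size=8)
        dec = decompose(z, head)
        z_cf = counterfactual_latent(dec, head, 0.003)
        dec_cf = decompose(z_cf, head)
        np.testing.assert_allclose(dec_cf.orthogonal, dec.orthogonal, atol=1e-10)

    def test_zero_block_makes_counterfactual_equal_odds(self, rng):
        bundle = random_bundle(rng, n_findings=3, coupling_scale=0.3)
        bundle.diseases[0].blocks[1] = np.zeros(8)
        latents = [rng.normal(size=8) for _ in range(3)]
        o = odds(disease_score(bundle.diseases[0], latents))
        c = counterfactual_odds(latents, bundle.diseases[0], bundle.findings[1],
                                1, eps=0.005)
        assert c == pytest.approx(o, rel=1e-10)


class TestICar:
    def test_no_displacement_is_one(self):
        assert icar(0.005, 0.005, coupling_value=1.7) == pytest.approx(1.0)

    def test_zero_coupling_is_one(self):
        assert icar(0.9, 0.005, coupling_value=0.0) == 1.0

    def test_closed_form_value(self):
        # logit(0.5) - logit(0.005) = 5.29330, times coupling 0.2
        expected = math.exp((0.0 - math.log(0.005 / 0.995)) * 0.2)
        assert icar(0.5, 0.005, 0.2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.883, abs=2e-3)

    def test_equals_two_pass_odds_ratio(self, rng):
        """Closed form == O/C computed by two explicit forward passes."""
        bundle = random_bundle(rng, n_findings=5, n_diseases=3)
        latents = [rng.normal(size=8) for _ in range(5)]
        eps = 0.004
        for f, hf in enumerate(bundle.findings):
            yf = finding_score(hf, latents[f])
            for d, hd in enumerate(bundle.diseases):
                closed = icar(yf, eps, coupling(hf, hd, f))
                o = odds(disease_score(hd, latents))
                c = counterfactual_odds(latents, hd, hf, f, eps)
                assert closed == pytest.approx(o / c, rel=1e-8)

    def test_monotone_in_finding_prediction(self):
        """I-CAR increases with the finding score iff the coupling is positive."""
        preds = np.linspace(0.05, 0.95, 10)
        for kappa, sign in [(0.5, 1), (-0.5, -1)]:
            vals = [icar(p, 0.005, kappa) for p in preds]
            diffs = np.diff(vals) * sign
            assert np.all(diffs > 0)
        assert len({icar(p, 0.005, 0.0) for p in preds}) == 1


class TestCar:
    def test_orthogonal_block_gives_unity(self, rng):
        w = np.array([1.0, 0.0, 0.0])
        head_f = FindingHead("f", w, 0.0)
        from carfundus import DiseaseHead
        head_d = DiseaseHead("d", [np.array([0.0, 2.0, -1.0])], 0.3)
        assert car(head_f, head_d, 0, eps=0.005) == pytest.approx(1.0)

    def test_closed_form_vs_two_counterfactual_passes(self, rng):
        """CAR equals the odds ratio of 'surely present' vs 'surely absent'."""
        bundle = random_bundle(rng, n_findings=3)
        latents = [rng.normal(size=8) for _ in range(3)]
        eps = 0.005
        f, hf = 0, bundle.findings[0]
        for d, hd in enumerate(bundle.diseases):
            dec = decompose(latents[f], hf)
            z_hi = counterfactual_latent(dec, hf, 1.0 - eps)
            z_lo = counterfactual_latent(dec, hf, eps)
            hi = list(latents); hi[f] = z_hi
            lo = list(latents); lo[f] = z_lo
            two_pass = odds(disease_score(hd, hi)) / odds(disease_score(hd, lo))
            assert car(hf, hd, f, eps) == pytest.approx(two_pass, rel=1e-8)

    def test_example_value(self):
        # coupling 0.2 at eps 0.005: exp((logit(0.995) - logit(0.005)) * 0.2)
        head_f = FindingHead("f", np.array([1.0, 0.0]), 0.0)
        from carfundus import DiseaseHead
        head_d = DiseaseHead("d", [np.array([0.2, 0.5])], 0.0)
        expected = math.exp((logit(0.995) - logit(0.005)) * 0.2)
        assert car(head_f, head_d, 0, 0.005) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(8.30, abs=0.01)

    def test_negated_block_gives_reciprocal(self, rng):
        bundle = random_bundle(rng, n_findings=2)
        hf, hd = bundle.findings[0], bundle.diseases[0]
        forward = car(hf, hd, 0, 0.005)
        hd.blocks[0] = -hd.blocks[0]
        assert car(hf, hd, 0, 0.005) == pytest.approx(1.0 / forward, rel=1e-10)

    def test_logit_antisymmetry(self):
        for eps in np.geomspace(1e-6, 0.0099, 30):
            assert logit(1.0 - eps, clip=False) == pytest.approx(
                -logit(eps, clip=False), abs=1e-10)


class TestCarMatrix:
    def test_block_diagonal_couplings(self, rng):
        """Disease d coupled only to finding d: off-diagonal entries are 1."""
        from carfundus import DiseaseHead
        C = 4
        ws = [rng.normal(size=C) for _ in range(3)]
        findings = [FindingHead(f"f{i}", w, 0.0) for i, w in enumerate(ws)]
        diseases = []
        for j in range(3):
            blocks = []
            for i in range(3):
                if i == j:
                    blocks.append(0.5 * ws[i])
                else:
                    # orthogonal to w_i by explicit projection removal
                    v = rng.normal(size=C)
                    blocks.append(v - (v @ ws[i]) / (ws[i] @ ws[i]) * ws[i])
            diseases.append(DiseaseHead(f"d{j}", blocks, 0.0))
        from carfundus import ModelBundle
        cm = car_matrix(ModelBundle(findings, diseases), eps=0.005)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(cm.values[off], 1.0, atol=1e-8)
        assert np.all(cm.values[np.eye(3, dtype=bool)] > 1.0)

    def test_log_values_proportional_to_couplings(self, rng, bundle):
        cm = car_matrix(bundle, eps=0.005)
        kappa = np.array([[coupling(hf, hd, f) for hd in bundle.diseases]
                          for f, hf in enumerate(bundle.findings)])
        const = logit(0.995) - logit(0.005)
        np.testing.assert_allclose(cm.log_values(), const * kappa, atol=1e-10)

    def test_eps_change_rescales_logs(self, rng, bundle):
        cm1 = car_matrix(bundle, eps=0.002)
        cm2 = car_matrix(bundle, eps=0.004)
        ratio = (logit(0.996) - logit(0.004)) / (logit(0.998) - logit(0.002))
        np.testing.assert_allclose(cm2.log_values(), ratio * cm1.log_values(),
                                   atol=1e-10)

    def test_instance_independent(self, rng, bundle):
        """The CAR grid never depends on the image; only couplings and eps."""
        cm = car_matrix(bundle, eps=0.005)
        icars_a = instance_icars([rng.normal(size=8) for _ in range(4)], bundle)
        icars_b = instance_icars([rng.normal(size=8) for _ in range(4)], bundle)
        assert not np.allclose(icars_a, icars_b)  # instance grids do vary
        np.testing.assert_array_equal(cm.values,
                                      car_matrix(bundle, eps=0.005).values)


class TestSelectEpsilon:
    def test_fixed_mode(self):
        assert select_epsilon(None, EpsilonPolicy(mode="fixed", value=0.005)) == 0.005

    def test_percentile_is_nearest_rank(self):
        preds = np.linspace(0.00009, 0.009, 100)  # rank 5 = preds[4]
        got = select_epsilon(preds, EpsilonPolicy(mode="benign_percentile"))
        assert got == pytest.approx(preds[4])

    def test_percentile_clipped_below_one_percent(self):
        preds = np.full(100, 0.02)
        with pytest.warns(UserWarning, match="clipped"):
            got = select_epsilon(preds, EpsilonPolicy(mode="benign_percentile"))
        assert 0.0 < got < 0.01

    def test_empty_benign_set_suggests_fixed_mode(self):
        with pytest.raises(ValueError, match="fixed"):
            select_epsilon([], EpsilonPolicy(mode="benign_percentile"))

    def test_fixed_value_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            EpsilonPolicy(mode="fixed", value=0.02)


class TestAttributionMap:
    def test_orthogonal_block_zero_map(self, rng):
        from carfundus import DiseaseHead
        w = np.array([1.0, 0.0])
        head_f = FindingHead("f", w, 0.0)
        head_d = DiseaseHead("d", [np.array([0.0, 3.0])], 0.0)
        amap = attribution_map(rng.normal(size=(2, 4, 4)), head_f, head_d, 0)
        np.testing.assert_allclose(amap.grid, 0.0, atol=1e-12)

    def test_constant_latent_constant_map(self, rng):
        from carfundus import DiseaseHead
        head_f = FindingHead("f", rng.normal(size=3), 0.1)
        head_d = DiseaseHead("d", [rng.normal(size=3)], 0.0)
        amap = attribution_map(np.full((3, 5, 5), 2.0), head_f, head_d, 0)
        assert np.ptp(amap.grid) < 1e-12

    def test_spatial_mean_identity(self, rng):
        """mean(A) = (v . w_hat) * (logit(yhat) - b): the pooled-feature oracle."""
        from carfundus import DiseaseHead
        for _ in range(10):
            head_f = FindingHead("f", rng.normal(size=6), float(rng.normal()))
            head_d = DiseaseHead("d", [rng.normal(size=6)], 0.0)
            maps = rng.normal(size=(6, 5, 5))
            amap = attribution_map(maps, head_f, head_d, 0)
            pooled = pool_features(maps)
            yhat = finding_score(head_f, pooled)
            expected = float(head_d.blocks[0] @ head_f.unit_weight) * (
                logit(yhat) - head_f.bias)
            assert amap.grid.mean() == pytest.approx(expected, abs=1e-6)

    def test_upsample_preserves_scale(self, rng):
        from carfundus import DiseaseHead
        head_f = FindingHead("f", rng.normal(size=3), 0.0)
        head_d = DiseaseHead("d", [rng.normal(size=3)], 0.0)
        amap = attribution_map(rng.normal(size=(3, 8, 8)), head_f, head_d, 0)
        up = amap.upsample(64)
        assert up.shape == (64, 64)
        assert np.abs(up).max() <= np.abs(amap.grid).max() + 1e-6


class TestTopFindings:
    def test_sorted_filtered_truncated(self):
        got = top_findings([9.0, 3.0, 1.1], ["a", "b", "c"], threshold=math.e, k=3)
        assert got == [("a", 9.0), ("b", 3.0)]

    def test_all_below_threshold_empty(self):
        assert top_findings([1.0, 2.0, math.e], ["a", "b", "c"]) == []

    def test_k_one_keeps_largest(self):
        got = top_findings([5.0, 9.0, 4.0], ["a", "b", "c"], k=1)
        assert got == [("b", 9.0)]


class TestInteractiveAdjust:
    def test_override_to_eps_reproduces_counterfactual_odds(self, rng, bundle, latents):
        eps = 0.005
        adjusted = interactive_adjust(latents, bundle, {"f0": eps})
        for d, hd in enumerate(bundle.diseases):
            c = counterfactual_odds(latents, hd, bundle.findings[0], 0, eps)
            assert adjusted[d] == pytest.approx(c / (1.0 + c), abs=1e-12)

    def test_override_to_own_score_is_noop(self, rng, bundle, latents):
        yf = finding_score(bundle.findings[1], latents[1])
        adjusted = interactive_adjust(latents, bundle, {"f1": yf})
        np.testing.assert_allclose(adjusted, bundle.disease_scores(latents), atol=1e-9)

    def test_override_to_one_minus_eps_multiplies_by_car(self, rng, bundle, latents):
        eps = 0.005
        up = interactive_adjust(latents, bundle, {"f0": 1.0 - eps})
        for d, hd in enumerate(bundle.diseases):
            c = counterfactual_odds(latents, hd, bundle.findings[0], 0, eps)
            r = car(bundle.findings[0], hd, 0, eps)
            expected_odds = c * r
            assert odds(float(up[d])) == pytest.approx(expected_odds, rel=1e-8)

    def test_equals_full_recomputation(self, rng, bundle, latents):
        """The shortcut must match brute-force disease scoring exactly."""
        overrides = {"f0": 0.9, "f2": 0.1}
        adjusted = interactive_adjust(latents, bundle, overrides)
        modified = list(latents)
        for name, p in overrides.items():
            f = bundle.finding_index(name)
            head = bundle.findings[f]
            dec = decompose(latents[f], head)
            modified[f] = counterfactual_latent(dec, head, p)
        brute = [disease_score(hd, modified) for hd in bundle.diseases]
        np.testing.assert_array_equal(adjusted, brute)

    def test_unknown_finding_rejected(self, bundle, latents):
        with pytest.raises(KeyError, match="unknown finding"):
            interactive_adjust(latents, bundle, {"nope": 0.5})

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_override_outside_open_interval_rejected(self, bundle, latents, bad):
        with pytest.raises(ValueError):
            interactive_adjust(latents, bundle, {"f0": bad})


class TestNormalizedBundle:
    def test_unit_norms_and_identical_car(self, rng, bundle):
        normed = bundle.normalized()
        for h in normed.findings:
            assert h.norm == pytest.approx(1.0, abs=1e-12)
        # couplings v.w/||w||^2 are not norm-invariant, but the decomposition
        # identities must hold in both conventions
        for b in (bundle, normed):
            z = rng.normal(size=8)
            head = b.findings[0]
            dec = decompose(z, head)
            np.testing.assert_allclose(dec.reconstruct(), z, atol=1e-8)
            z_cf = counterfactual_latent(dec, head, 0.005)
            assert finding_score(head, z_cf) == pytest.approx(0.005, abs=1e-8)
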