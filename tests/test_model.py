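"""Conjugate-gradient affinity fitting, variants, noise model, evaluation."""

import numpy as np
import pytest
from scipy import sparse, stats

from pbmlin.exceptions import DomainError
from pbmlin.kmers import (KmerFeature, KmerSet, build_design_matrix,
                          enumerate_kmers, reverse_complement)
from pbmlin.model import (AffinityModel, NoiseModel, center_intensities,
                          evaluate, fit_affinities, fit_noise_model,
                          fit_stepwise, predict, solve_normal_equations,
                          tie_reverse_complements)
from pbmlin.kmers import DesignMatrix

from conftest import make_sample


def random_design(rng, n=60, length=20, ks=(4,)):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, length)]) for _ in range(n)]
    feats = [f for k in ks for f in enumerate_kmers(k)]
    return seqs, build_design_matrix(seqs, KmerSet(feats))


class TestCentering:
    def test_simple(self):
        c, m = center_intensities(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(c, [-1.0, 0.0, 1.0])
        assert m == 2.0

    def test_constant_and_random(self, rng):
        c, m = center_intensities(np.full(5, 4.2))
        np.testing.assert_allclose(c, 0.0)
        v = rng.standard_normal(100)
        c, _ = center_intensities(v)
        assert abs(c.sum()) < 1e-10

    def test_missing_rejected(self):
        with pytest.raises(DomainError):
            center_intensities(np.array([1.0, np.nan]))


class TestConjugateGradient:
    def test_identity_system(self, rng):
        p = rng.standard_normal(12)
        H = sparse.identity(12, format="csr")
        x = solve_normal_equations(H, p, iterations=20, tol=0.0)
        np.testing.assert_allclose(x, p, atol=1e-8)

    def test_zero_rhs_gives_zero_solution(self):
        H = sparse.random(30, 10, density=0.5, random_state=0, format="csr")
        x = solve_normal_equations(H, np.zeros(30), iterations=10)
        np.testing.assert_array_equal(x, 0.0)

    def test_overdetermined_matches_dense_oracle(self, rng):
        A = rng.standard_normal((200, 50))
        p = rng.standard_normal(200)
        x = solve_normal_equations(sparse.csr_matrix(A), p,
                                   iterations=200, tol=1e-14)
        expected, *_ = np.linalg.lstsq(A, p, rcond=None)
        assert np.linalg.norm(x - expected) / np.linalg.norm(expected) < 1e-6

    def test_iterations_must_be_positive(self):
        H = sparse.identity(3, format="csr")
        with pytest.raises(ValueError):
            solve_normal_equations(H, np.ones(3), iterations=0)


class TestFitAffinities:
    def test_constant_sigma_wls_equals_ols(self, rng):
        seqs, design = random_design(rng)
        p, mean = center_intensities(rng.standard_normal(len(seqs)) + 8.0)
        ols = fit_affinities(design, p, iterations=50, training_mean=mean)
        nm = NoiseModel(sigma0=0.7, beta=0.0)
        wls = fit_affinities(design, p, iterations=50, noise_model=nm,
                             training_mean=mean)
        np.testing.assert_allclose(wls.alpha, ols.alpha, atol=1e-10)
        assert wls.intercept == pytest.approx(ols.intercept, abs=1e-10)

    def test_missing_intensities_rejected(self, rng):
        seqs, design = random_design(rng, n=5)
        with pytest.raises(DomainError):
            fit_affinities(design, np.array([1.0, 2.0, np.nan, 0.0, 1.0]))

    def test_unidentifiable_constant_feature_gets_zero_affinity(self):
        # a feature present in every probe is confounded with the intercept
        kset = KmerSet([KmerFeature("AAAA"), KmerFeature("CCCC")])
        seqs = ["AAAACCCCGG", "AAAAGGGGGG", "AAAATTTTGG", "AAAACCCCTT"]
        design = build_design_matrix(seqs, kset)
        p, mean = center_intensities(np.array([9.0, 8.0, 8.0, 9.0]))
        m = fit_affinities(design, p, iterations=50, tol=1e-12,
                           training_mean=mean)
        assert m.alpha[0] == 0.0  # AAAA in all probes
        assert m.alpha[1] != 0.0  # CCCC varies


class TestStepwise:
    def test_single_partition_equals_joint(self, rng):
        seqs, design = random_design(rng, ks=(4,))
        p, mean = center_intensities(rng.standard_normal(len(seqs)) + 8.0)
        joint = fit_affinities(design, p, iterations=60, training_mean=mean)
        step = fit_stepwise(design, p, iterations=60, training_mean=mean)
        np.testing.assert_allclose(step.alpha, joint.alpha, atol=1e-8)
        assert step.variant == "stepwise"

    def test_short_kmer_truth_leaves_no_residual_for_longer_blocks(self, rng):
        # noiseless 4-mer-only signal: after the 4-mer block the residual is
        # ~0, so the 5-mer block contributes almost nothing
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 24)]) for _ in range(400)]
        planted = {"GATT": 1.0, "ACCA": -0.5}
        p = np.array([sum(a for f, a in planted.items() if f in s)
                      for s in seqs])
        p, mean = center_intensities(p + 8.0)
        kset = KmerSet(enumerate_kmers(4) + enumerate_kmers(5))
        design = build_design_matrix(seqs, kset)
        m = fit_stepwise(design, p, iterations=400, tol=1e-12,
                         training_mean=mean)
        block5 = np.array([j for j, f in enumerate(kset.features)
                           if f.k == 5])
        H = design.matrix.tocsc()
        contrib5 = np.abs(H[:, block5] @ m.alpha[block5])
        assert contrib5.max() < 1e-6

    def test_joint_training_residual_never_worse(self, rng):
        # least-squares optimality: the joint fit minimizes the residual
        # over the full column space, the stepwise fit over a subset path
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 24)]) for _ in range(500)]
        planted = {"GATT": 0.8, "CCGTA": 1.2, "TTAAG": -0.4}
        signal = np.array([sum(a for f, a in planted.items() if f in s)
                           for s in seqs])
        p, mean = center_intensities(signal + 8.0
                                     + 0.2 * rng.standard_normal(500))
        kset = KmerSet(enumerate_kmers(4) + enumerate_kmers(5))
        design = build_design_matrix(seqs, kset)
        joint = fit_affinities(design, p, iterations=800, tol=1e-12,
                               training_mean=mean)
        step = fit_stepwise(design, p, iterations=800, tol=1e-12,
                            training_mean=mean)
        r_joint = np.linalg.norm(p - design.matrix @ joint.coefficients())
        r_step = np.linalg.norm(p - design.matrix @ step.coefficients())
        assert r_joint <= r_step + 1e-8


class TestTieReverseComplements:
    def test_pair_merges_by_or(self):
        kset = KmerSet([KmerFeature("AAAA"), KmerFeature("TTTT")])
        design = build_design_matrix(["AAAAGGGG", "TTTTGGGG", "GGGGCCCC"],
                                     kset)
        tied_set, tied = tie_reverse_complements(kset, design)
        assert len(tied_set) == 1
        assert tied_set.features[0].pattern == "AAAA"  # lexicographic min
        np.testing.assert_array_equal(tied.matrix.toarray()[:, 0],
                                      [1.0, 1.0, 0.0])

    def test_palindrome_maps_to_itself(self):
        kset = KmerSet([KmerFeature("ACGT")])
        design = build_design_matrix(["ACGTACGT"], kset)
        tied_set, _ = tie_reverse_complements(kset, design)
        assert len(tied_set) == 1

    def test_full_4mer_set_collapses_to_136(self):
        # 256 4-mers = 120 revcomp pairs + 16 palindromes
        pal = sum(1 for f in enumerate_kmers(4)
                  if reverse_complement(f.pattern) == f.pattern)
        assert pal == 16
        kset = KmerSet(enumerate_kmers(4))
        design = build_design_matrix(["ACGTACGTACGT"], kset)
        tied_set, tied = tie_reverse_complements(kset, design)
        assert len(tied_set) == 136
        assert tied.matrix.shape == (1, 137)

    def test_tied_model_prediction_invariant_under_revcomp(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(60)]
        kset = KmerSet(enumerate_kmers(4))
        design = build_design_matrix(seqs, kset)
        tied_set, tied = tie_reverse_complements(kset, design)
        p, mean = center_intensities(rng.standard_normal(60) + 8.0)
        m = fit_affinities(tied, p, iterations=50, training_mean=mean)
        test = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(15)]
        fwd = predict(m, test)
        rev = predict(m, [reverse_complement(s) for s in test])
        np.testing.assert_allclose(fwd, rev, atol=1e-10)


class TestPredict:
    def test_intercept_only_model_predicts_training_mean(self):
        kset = KmerSet([KmerFeature("AAAA")])
        m = AffinityModel(kmer_set=kset, alpha=np.zeros(1), intercept=0.0,
                          training_mean=8.25)
        np.testing.assert_allclose(predict(m, ["CCCCGGGG"]), 8.25)

    def test_prediction_is_additive_in_contained_features(self):
        kset = KmerSet([KmerFeature("AAAA"), KmerFeature("CCCC")])
        m = AffinityModel(kmer_set=kset, alpha=np.array([0.5, -0.2]),
                          intercept=0.1, training_mean=8.0)
        pred = predict(m, ["AAAACCCC"])
        assert pred[0] == pytest.approx(8.0 + 0.1 + 0.5 - 0.2)

    def test_length_mismatch_warns_but_proceeds(self):
        kset = KmerSet([KmerFeature("AAAA")])
        m = AffinityModel(kmer_set=kset, alpha=np.array([1.0]), intercept=0.0,
                          training_mean=8.0, training_probe_length=8)
        with pytest.warns(UserWarning, match="length"):
            out = predict(m, ["AAAACCCCGG"])
        assert out.shape == (1,)

    def test_fitted_values_identical_under_feature_reordering(self, rng):
        # alpha is not unique under collinearity, but fitted values are
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(80)]
        p_raw = rng.standard_normal(80) + 8.0
        p, mean = center_intensities(p_raw)
        feats = enumerate_kmers(4)
        perm = list(rng.permutation(len(feats)))
        m1 = fit_affinities(build_design_matrix(seqs, KmerSet(feats)), p,
                            iterations=500, tol=1e-13, training_mean=mean)
        m2 = fit_affinities(
            build_design_matrix(seqs, KmerSet([feats[i] for i in perm])), p,
            iterations=500, tol=1e-13, training_mean=mean)
        np.testing.assert_allclose(predict(m1, seqs), predict(m2, seqs),
                                   atol=1e-8)


class TestNoiseModel:
    def test_constant_sd_recovered_with_zero_slope(self, rng):
        mu = np.full(4000, 9.0) + rng.uniform(-2, 2, 4000)
        reps = [make_sample(["ACGT"] * 4000, mu + 0.3 * rng.standard_normal(4000),
                            log_base=2.0) for _ in range(4)]
        nm = fit_noise_model(reps)
        assert abs(nm.beta) < 0.02
        assert nm.sigma0 + nm.beta * 9.0 == pytest.approx(0.3, rel=0.1)

    def test_identical_replicates_give_zero_noise(self):
        a = make_sample(["ACGT"] * 10, np.arange(1.0, 11.0), log_base=2.0)
        nm = fit_noise_model([a, a.copy()])
        assert nm.sigma0 == 0.0 and nm.beta == 0.0

    def test_needs_two_replicates_and_matching_probes(self):
        a = make_sample(["ACGT"] * 4, [1.0, 2.0, 3.0, 4.0], log_base=2.0)
        with pytest.raises(ValueError):
            fit_noise_model([a])
        b = a.copy()
        b.probes["probe_id"] = ["x0", "x1", "x2", "x3"]
        with pytest.raises(ValueError, match="identical probe set"):
            fit_noise_model([a, b])

    def test_sigma_is_floored(self):
        nm = NoiseModel(sigma0=0.0, beta=0.0)
        assert nm.sigma(np.array([5.0]))[0] > 0


class TestEvaluate:
    def test_identical_vectors(self, rng):
        v = rng.standard_normal(50)
        assert evaluate(v, v) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_monotone_nonlinear_transform(self, rng):
        v = rng.standard_normal(100)
        pe, sp = evaluate(v, np.exp(v))
        assert sp == pytest.approx(1.0)
        assert pe < 1.0

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([3.0, 1.0, 5.0, 9.0])
        pe, sp = evaluate(x, y)
        ex = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pe == pytest.approx(ex, abs=1e-12)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        es = (np.mean(rx * ry) - rx.mean() * ry.mean()) / (rx.std() * ry.std())
        assert sp == pytest.approx(es, abs=1e-12)

    def test_missing_pairs_excluded_and_minimum_size(self):
        pe, _ = evaluate(np.array([1.0, 2.0, np.nan, 3.0]),
                         np.array([1.0, 2.0, 5.0, 3.0]))
        assert pe == pytest.approx(1.0)
        with pytest.raises(ValueError):
            evaluate(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, np.nan]))
        with pytest.raises(DomainError):
            evaluate(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
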