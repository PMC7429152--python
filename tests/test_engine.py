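"""PRS derivation engine: correlation recovery, penalized solver,
hyperparameter tuning, scoring, and score combination."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from copdprs.engine import (
    CombinedModel,
    PRSProfile,
    TuningGrid,
    combine_scores,
    derive_weights,
    fit_sparse_weights,
    pvalue_to_correlation,
    score_individuals,
    soft_threshold,
    tune_hyperparameters,
)
from copdprs.ld import LDBlock, LDBlocks, compute_ld_blocks
from copdprs.simulate import SimConfig, simulate_gwas_sumstats, simulate_ld_genotypes, simulate_lung_phenotypes
from copdprs.sumstats import PRSWeights


def _random_psd_corr(rng, k):
    A = rng.standard_normal((k, k))
    S = A @ A.T + k * np.eye(k)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _ld_from_R(R):
    k = R.shape[0]
    return LDBlocks(blocks=[LDBlock(variant_ids=[f"v{j}" for j in range(k)], R=R)], n_ref=1000)


def oracle_minimize(R, r, s, lam):
    """Generic numerical minimizer of the penalized objective via the
    positive/negative split (smooth bound-constrained QP)."""
    k = len(r)
    A = (1 - s) * R + s * np.eye(k)

    def f(uv):
        b = uv[:k] - uv[k:]
        return 0.5 * b @ A @ b - r @ b + lam * uv.sum()

    def grad(uv):
        b = uv[:k] - uv[k:]
        g = A @ b - r
        return np.concatenate([g + lam, -g + lam])

    res = optimize.minimize(
        f, np.zeros(2 * k), jac=grad, bounds=[(0, None)] * 2 * k,
        method="L-BFGS-B", options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x[:k] - res.x[k:]


class TestPvalueToCorrelation:
    def test_p_one_gives_zero(self):
        assert pvalue_to_correlation(1.0, 1.0, 100) == 0.0

    def test_sign_symmetry(self):
        rp = pvalue_to_correlation(0.01, +1, 200)
        rn = pvalue_to_correlation(0.01, -1, 200)
        assert rn == -rp and rp > 0

    def test_round_trip_through_correlation_test(self):
        # data with known sample correlation; the t-test p must invert back
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        e = rng.standard_normal(50)
        y = 0.3 * x + e
        r0, p = stats.pearsonr(x, y)
        assert pvalue_to_correlation(p, np.sign(r0), 50) == pytest.approx(r0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pvalue_to_correlation(0.0, 1, 100)
        with pytest.raises(ValueError):
            pvalue_to_correlation(0.5, 1, 2)


class TestSparseSolver:
    def test_s_one_reduces_to_soft_threshold(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-0.5, 0.5, 8)
        ld = _ld_from_R(_random_psd_corr(rng, 8))
        beta = fit_sparse_weights(r, ld, s=1.0, lam=0.1)
        np.testing.assert_array_equal(beta, soft_threshold(r, 0.1))

    def test_full_shrinkage_gives_zero(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(-0.3, 0.3, 6)
        ld = _ld_from_R(_random_psd_corr(rng, 6))
        beta = fit_sparse_weights(r, ld, s=0.5, lam=np.abs(r).max())
        np.testing.assert_array_equal(beta, np.zeros(6))

    def test_lam_zero_matches_linear_solve(self):
        rng = np.random.default_rng(3)
        R = _random_psd_corr(rng, 7)
        r = rng.uniform(-0.4, 0.4, 7)
        s = 0.5
        beta = fit_sparse_weights(r, _ld_from_R(R), s=s, lam=0.0, tol=1e-10, max_iter=20000)
        expected = np.linalg.solve((1 - s) * R + s * np.eye(7), r)
        np.testing.assert_allclose(beta, expected, atol=1e-6)

    @pytest.mark.parametrize("s,lam", [(0.2, 0.01), (0.5, 0.05), (0.9, 0.01)])
    def test_matches_generic_minimizer(self, s, lam):
        rng = np.random.default_rng(4)
        for _ in range(5):
            k = rng.integers(2, 9)
            R = _random_psd_corr(rng, k)
            r = rng.uniform(-0.5, 0.5, k)
            beta = fit_sparse_weights(r, _ld_from_R(R), s=s, lam=lam, tol=1e-8)
            expected = oracle_minimize(R, r, s, lam)
            np.testing.assert_allclose(beta, expected, atol=1e-5)

    def test_subgradient_optimality_at_solution(self):
        rng = np.random.default_rng(5)
        R = _random_psd_corr(rng, 10)
        r = rng.uniform(-0.5, 0.5, 10)
        s, lam, tol = 0.3, 0.03, 1e-8
        beta = fit_sparse_weights(r, _ld_from_R(R), s=s, lam=lam, tol=tol)
        g = ((1 - s) * R + s * np.eye(10)) @ beta - r
        for j in range(10):
            if beta[j] > 0:
                assert g[j] + lam == pytest.approx(0, abs=1e-6)
            elif beta[j] < 0:
                assert g[j] - lam == pytest.approx(0, abs=1e-6)
            else:
                assert abs(g[j]) <= lam + 1e-6

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(6)
        R = _random_psd_corr(rng, 20)
        r = rng.uniform(-0.5, 0.5, 20)
        ld = _ld_from_R(R)
        nnz = [
            int((fit_sparse_weights(r, ld, s=0.5, lam=lam) != 0).sum())
            for lam in np.geomspace(0.005, 0.5, 10)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_misaligned_input_rejected(self):
        ld = _ld_from_R(np.eye(3))
        with pytest.raises(ValueError):
            fit_sparse_weights(np.zeros(4), ld, s=0.5, lam=0.1)


@pytest.fixture(scope="module")
def small_prs_setup():
    cfg = SimConfig(n_individuals=3000, n_variants=200, seed=31)
    G = simulate_ld_genotypes(cfg)
    ph = simulate_lung_phenotypes(G, cfg)
    ss = simulate_gwas_sumstats(G, ph["fev1_pct_pred"].to_numpy())
    tune_cfg = SimConfig(n_individuals=1000, n_variants=200, seed=32, architecture_seed=31)
    G_t = simulate_ld_genotypes(tune_cfg)
    ph_t = simulate_lung_phenotypes(G_t, tune_cfg)
    blocks = compute_ld_blocks(G_t, block_assignment=10)
    return ss, blocks, G_t, ph_t


class TestTuning:
    def test_single_grid_point(self, small_prs_setup):
        ss, blocks, G_t, ph_t = small_prs_setup
        grid = TuningGrid(s_values=(0.9,), lambda_values=(0.01,))
        w, report = tune_hyperparameters(ss, blocks, G_t, ph_t, grid)
        assert len(report) == 1
        assert (w.s, w.lam) == (0.9, 0.01)

    def test_selection_is_grid_argmax(self, small_prs_setup):
        ss, blocks, G_t, ph_t = small_prs_setup
        grid = TuningGrid(s_values=(0.5, 1.0), lambda_values=(0.005, 0.02, 0.08))
        w, report = tune_hyperparameters(ss, blocks, G_t, ph_t, grid)
        best = report.loc[report["metric"].idxmax()]
        selected = report[(report["s"] == w.s) & (report["lam"] == w.lam)]["metric"].iloc[0]
        assert selected >= best["metric"] - 1e-12

    def test_tie_broken_toward_larger_lambda(self):
        # one variant: scores are proportional for any lambda that keeps it
        # non-zero, so the trait-r2 metric ties exactly across lambdas
        cfg = SimConfig(n_individuals=500, n_variants=1, block_size=1, seed=33)
        G = simulate_ld_genotypes(cfg)
        ph = simulate_lung_phenotypes(G, cfg)
        ss = simulate_gwas_sumstats(G, ph["fev1_pct_pred"].to_numpy())
        blocks = compute_ld_blocks(G, block_assignment=1)
        grid = TuningGrid(s_values=(1.0,), lambda_values=(0.001, 0.002))
        w, report = tune_hyperparameters(ss, blocks, G, ph, grid)
        assert w.lam == 0.002

    def test_copd_auc_metric(self, small_prs_setup):
        ss, blocks, G_t, ph_t = small_prs_setup
        grid = TuningGrid(s_values=(0.9,), lambda_values=(0.005, 0.02), metric="copd_auc")
        w, report = tune_hyperparameters(ss, blocks, G_t, ph_t, grid)
        assert report["metric"].max() > 0.5  # score predicts COPD above chance


def _profile(values, trait="FEV1"):
    v = np.asarray(values, dtype=float)
    return PRSProfile(
        trait=trait, cohort="t",
        table=pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(v))], "raw": v, "std": v}),
        n_variants_used=1,
    )


class TestScoring:
    def test_weighted_dosage_arithmetic(self):
        cfg = SimConfig(n_individuals=4, n_variants=1, block_size=1, seed=34)
        G = simulate_ld_genotypes(cfg)
        G.dosages[:, 0] = [2.0, 0.0, 1.0, 2.0]
        v = G.variants[0]
        w = PRSWeights(trait="FEV1", s=0.9, lam=0.01, table=pd.DataFrame(
            {"id": [v.id], "chrom": [v.chrom], "pos": [v.pos],
             "effect_allele": [v.effect_allele], "weight": [0.5]}))
        prof = score_individuals(G, w)
        assert prof.raw.tolist() == [1.0, 0.0, 0.5, 1.0]
        assert prof.n_variants_used == 1

    def test_standardization_exact(self, small_prs_setup):
        ss, blocks, G_t, ph_t = small_prs_setup
        w = derive_weights(ss, blocks, s=0.9, lam=0.01)
        prof = score_individuals(G_t, w)
        assert abs(prof.std.mean()) < 1e-10
        assert prof.std.std() == pytest.approx(1.0, abs=1e-10)

    def test_permutation_equivariance(self, small_prs_setup):
        ss, blocks, G_t, ph_t = small_prs_setup
        w = derive_weights(ss, blocks, s=0.9, lam=0.01)
        prof = score_individuals(G_t, w)
        rng = np.random.default_rng(7)
        perm = rng.permutation(G_t.n)
        from copdprs.simulate import GenotypeMatrix
        G_p = GenotypeMatrix(
            dosages=G_t.dosages[perm], sample_ids=[G_t.sample_ids[i] for i in perm],
            variants=G_t.variants)
        prof_p = score_individuals(G_p, w)
        np.testing.assert_allclose(prof_p.raw, prof.raw[perm], atol=1e-12)

    def test_allele_complement_invariance(self, small_prs_setup):
        """Complementing dosages (d -> 2-d) with relabeled alleles leaves
        every individual's score unchanged."""
        ss, blocks, G_t, ph_t = small_prs_setup
        w = derive_weights(ss, blocks, s=0.9, lam=0.01)
        prof = score_individuals(G_t, w)

        from copdprs.simulate import GenotypeMatrix
        from copdprs.sumstats import VariantRecord
        flipped = []
        D = G_t.dosages.copy()
        for j, v in enumerate(G_t.variants):
            D[:, j] = 2.0 - D[:, j]
            flipped.append(VariantRecord(
                id=v.id, chrom=v.chrom, pos=v.pos,
                effect_allele=v.other_allele, other_allele=v.effect_allele))
        G_f = GenotypeMatrix(dosages=D, sample_ids=G_t.sample_ids, variants=flipped)
        prof_f = score_individuals(G_f, w)
        # raw scores shift by a constant (2*sum w); standardized scores match
        np.testing.assert_allclose(prof_f.std, prof.std, atol=1e-10)

    def test_no_overlap_is_error(self, small_prs_setup):
        ss, blocks, G_t, _ = small_prs_setup
        w = derive_weights(ss, blocks, s=0.9, lam=0.01)
        w2 = PRSWeights(trait="FEV1", s=w.s, lam=w.lam,
                        table=w.table.assign(id=["zzz" + i for i in w.table["id"]]))
        with pytest.raises(ValueError, match="overlap"):
            score_individuals(G_t, w2)


class TestCombine:
    def test_fixed_coefficients(self):
        p1 = _profile([1.0, 0.0, -1.0])
        p2 = _profile([0.0, 0.0, 0.0], trait="FEV1_FVC")
        model, prof = combine_scores(p1, p2, mode="fixed", coefficients=(0.43847, 0.58833))
        assert prof.table["raw"].iloc[0] == pytest.approx(0.43847)
        assert model.b_fev1 == 0.43847 and model.b_ratio == 0.58833

    def test_unweighted_sum(self):
        p1 = _profile([1.0, -1.0])
        p2 = _profile([2.0, 0.0], trait="FEV1_FVC")
        _, prof = combine_scores(p1, p2, mode="unweighted")
        np.testing.assert_allclose(prof.table["raw"], [3.0, -1.0])

    def test_collinear_inputs_warn(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(200)
        y = (v + rng.standard_normal(200) > 0).astype(float)
        with pytest.warns(UserWarning, match="collinear"):
            model, prof = combine_scores(_profile(v), _profile(v, "FEV1_FVC"), labels=y, mode="fitted")
        assert abs(np.corrcoef(prof.raw, v)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_fitted_recovers_positive_links(self):
        rng = np.random.default_rng(9)
        n = 4000
        s1 = rng.standard_normal(n)
        s2 = rng.standard_normal(n)
        lin = -1.5 + 0.8 * s1 + 0.6 * s2
        y = rng.binomial(1, 1 / (1 + np.exp(-lin)))
        model, _ = combine_scores(_profile(s1), _profile(s2, "FEV1_FVC"), labels=y, mode="fitted")
        assert model.b_fev1 > 0 and model.b_ratio > 0

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            combine_scores(_profile([1, 2]), _profile([3, 4], "FEV1_FVC"),
                           labels=[1, 1], mode="fitted")

    def test_misaligned_profiles_rejected(self):
        p1 = _profile([1, 2])
        p2 = PRSProfile(trait="FEV1_FVC", cohort="t", table=pd.DataFrame(
            {"sample_id": ["x", "y"], "raw": [1.0, 2.0], "std": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="aligned"):
            combine_scores(p1, p2, mode="unweighted")


def test_end_to_end_score_tracks_true_liability(e2e):
    """Std combined PRS positively associated with true genetic liability."""
    ctx = e2e["context"]
    name = next(iter(ctx["combined"]))
    prof = ctx["combined"][name]
    ph = ctx["cohorts"][name]["ph"]
    liability = -(ph["true_score_fev1"] + ph["true_score_ratio"])  # risk direction
    assert np.corrcoef(prof.std, liability)[0, 1] > 0.3
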