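import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from tsdmeth.diffmeth import (
    bh_adjust,
    classify_dmcs,
    compare_abs_rho,
    dm_logistic_test,
    dm_test_matrix,
    knn_impute,
    run_contrasts,
    run_temperature_contrasts,
    spearman_screen,
    summarize_dmc_rates,
)
from tsdmeth.simulate import SimulationConfig, simulate_hormones, simulate_methylomes

from conftest import make_matrix, make_samples


# ---------------------------------------------------------------------------
# independent brute-force likelihood oracle (numeric 1-D optimization; never
# uses the pooled-proportion shortcut of the implementation)


def _oracle_loglik(m, n, p):
    out = 0.0
    for mi, ni in zip(m, n):
        if ni == 0:
            continue
        out += (mi * np.log(p) if mi else 0.0) + ((ni - mi) * np.log(1 - p) if ni - mi else 0.0)
    return out


def _oracle_mle(m, n):
    res = optimize.minimize_scalar(
        lambda p: -_oracle_loglik(m, n, p),
        bounds=(1e-9, 1 - 1e-9),
        method="bounded",
        options={"xatol": 1e-13},
    )
    return res.x


def oracle_dm_test(m_a, n_a, m_b, n_b):
    pA, pB = _oracle_mle(m_a, n_a), _oracle_mle(m_b, n_b)
    p0 = _oracle_mle(list(m_a) + list(m_b), list(n_a) + list(n_b))
    lrt = 2 * (
        _oracle_loglik(m_a, n_a, pA)
        + _oracle_loglik(m_b, n_b, pB)
        - _oracle_loglik(list(m_a) + list(m_b), list(n_a) + list(n_b), p0)
    )
    phi = sum(
        (mi - ni * p) ** 2 / (ni * p * (1 - p))
        for m, n, p in ((m_a, n_a, pA), (m_b, n_b, pB))
        for mi, ni in zip(m, n)
        if ni > 0 and 0 < p < 1
    ) / (sum(1 for ni in list(n_a) + list(n_b) if ni > 0) - 2)
    return max(lrt, 0.0), phi


class TestDMLogisticTest:
    def test_identical_groups_are_null(self):
        d, lrt, phi, p = dm_logistic_test([5, 6], [10, 10], [5, 6], [10, 10])
        assert d == 0.0 and lrt == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_hand_example_against_oracle(self):
        # pooled 17/20 = 85% vs 3/20 = 15%
        d, lrt, phi, p = dm_logistic_test(
            [9, 8], [10, 10], [1, 2], [10, 10], correction="chisq"
        )
        assert d == pytest.approx(70.0, abs=1e-9)
        o_lrt, o_phi = oracle_dm_test([9, 8], [10, 10], [1, 2], [10, 10])
        assert lrt == pytest.approx(o_lrt, abs=1e-7)
        assert phi == pytest.approx(o_phi, abs=1e-7)
        assert p == pytest.approx(stats.chi2.sf(o_lrt / max(o_phi, 1.0), 1), abs=1e-9)
        assert lrt == pytest.approx(21.6350474, abs=1e-5)  # frozen oracle value

    def test_agrees_with_oracle_on_binomial_fixture(self):
        """50-locus binomial fixture: |delta p| < 1e-6 wherever phi <= 1."""
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(50):
            n_a = rng.integers(8, 40, size=5)
            n_b = rng.integers(8, 40, size=5)
            base = rng.uniform(0.15, 0.85)
            m_a = rng.binomial(n_a, base)
            m_b = rng.binomial(n_b, base)
            d, lrt, phi, p = dm_logistic_test(m_a, n_a, m_b, n_b, correction="chisq")
            o_lrt, o_phi = oracle_dm_test(m_a, n_a, m_b, n_b)
            assert lrt == pytest.approx(o_lrt, abs=1e-6)
            if phi <= 1.0:
                assert p == pytest.approx(stats.chi2.sf(o_lrt, 1), abs=1e-6)
                checked += 1
        assert checked >= 15

    def test_overdispersion_raises_phi_and_p(self):
        rng = np.random.default_rng(7)
        n = rng.integers(20, 40, size=(100, 12))
        conc = 1 / 0.2 - 1  # beta-binomial rho = 0.2
        pcell = rng.beta(0.5 * conc, 0.5 * conc, size=n.shape)
        m = rng.binomial(n, pcell)
        mask = np.zeros(12, bool)
        mask[:6] = True
        res_c = dm_test_matrix(m, n, mask, ~mask, correction="chisq")
        uncorrected = stats.chi2.sf(res_c["lrt"], 1)
        assert (res_c["phi"] > 1).mean() > 0.9
        assert (res_c["p"] >= uncorrected - 1e-12).all()

    def test_uncovered_side_yields_missing(self):
        res = dm_test_matrix(
            np.array([[3, 4, 0, 0]]),
            np.array([[10, 10, 0, 0]]),
            np.array([True, True, False, False]),
            np.array([False, False, True, True]),
        )
        assert res.isna().all(axis=None)


class TestBHAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_permutation_invariance_and_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_adjust(p)
        perm = rng.permutation(200)
        assert bh_adjust(p[perm]) == pytest.approx(q[perm])
        assert q == pytest.approx(multipletests(p, method="fdr_bh")[1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[[0, 2]]).any()


class TestContrasts:
    def _study_matrix(self):
        samples = make_samples(
            24,
            temps=[30.0] * 8 + [33.5] * 8 + [34.5] * 8,
            sexes=["F"] * 8 + ["M"] * 8 + ["F"] * 4 + ["M"] * 4,
            clutches=["C1"] * 24,
        )
        rng = np.random.default_rng(4)
        cov = rng.integers(20, 40, size=(40, 24))
        meth = rng.binomial(cov, 0.5)
        # locus 0: strong female bias everywhere
        meth[0] = rng.binomial(cov[0], np.where([s.sex == "F" for s in samples], 0.9, 0.2))
        return make_matrix(meth, cov, samples=samples)

    def test_planted_sex_locus_has_minimal_fvm_q(self):
        res = run_contrasts(self._study_matrix())
        assert res["FvM"]["q"].idxmin() == 0

    def test_f345_contrast_uses_only_high_temperature_samples(self):
        m = self._study_matrix()
        res = run_contrasts(m)
        sub_ids = [s.sample_id for s in m.samples if s.temperature == 34.5]
        sub = m.subset_samples(sub_ids)
        mask_a = np.array([s.sex == "F" for s in sub.samples])
        direct = dm_test_matrix(sub.meth, sub.cov, mask_a, ~mask_a)
        assert res["F34.5vM34.5"]["p"].to_numpy() == pytest.approx(
            direct["p"].to_numpy(), nan_ok=True
        )

    def test_empty_contrast_side_raises(self):
        samples = make_samples(4, temps=[30.0] * 4, sexes=["F"] * 4)
        m = make_matrix(np.full((2, 4), 5), np.full((2, 4), 10), samples=samples)
        with pytest.raises(ValueError, match="FvM"):
            run_contrasts(m, contrasts=("FvM",))

    def test_gonad_pairwise_contrasts_cover_all_temperature_pairs(self):
        samples = make_samples(
            8, tissue="gonad", temps=[29.0, 29.0, 32.0, 32.0, 33.5, 33.5, 34.5, 34.5],
            sexes=["unknown"] * 8,
        )
        m = make_matrix(np.full((3, 8), 5), np.full((3, 8), 10), samples=samples)
        res = run_temperature_contrasts(m)
        assert sorted(res) == ["29v32", "29v33.5", "29v34.5", "32v33.5", "32v34.5", "33.5v34.5"]


class TestClassifyDMCs:
    def _frames(self, qs):
        """qs: contrast -> (q_locus0, meth_diff_locus0); other loci null."""
        frames = {}
        for c in ("FvM", "F34.5vM34.5", "30v33.5", "30v34.5", "33.5v34.5"):
            q, d = qs.get(c, (0.9, 0.0))
            frames[c] = pd.DataFrame(
                {
                    "scaffold": ["s1", "s1"],
                    "pos": [100, 200],
                    "meth_diff": [d, 0.0],
                    "p": [q, 0.9],
                    "q": [q, 0.9],
                }
            )
        return frames

    def test_sex_precedence_over_temperature(self):
        cls = classify_dmcs(self._frames({"FvM": (0.01, 12.0), "30v34.5": (0.01, -20.0)}))
        assert cls.loc[0, "class"] == "universal_sex"
        assert cls.loc[0, "direction"] == "female_biased"

    def test_f345_only_locus_is_sex_but_not_universal(self):
        cls = classify_dmcs(self._frames({"F34.5vM34.5": (0.02, -8.0)}))
        assert cls.loc[0, "class"] == "sex"
        assert cls.loc[0, "direction"] == "male_biased"

    def test_temperature_direction_follows_sign_with_temperature(self):
        # lower-minus-higher difference negative => methylation rises with T
        cls = classify_dmcs(self._frames({"30v34.5": (0.02, -15.0)}))
        assert cls.loc[0, "class"] == "temperature"
        assert cls.loc[0, "direction"] == "positive_with_temperature"

    def test_nonsignificant_locus_is_none(self):
        cls = classify_dmcs(self._frames({}))
        assert (cls["class"] == "none").all()

    def test_threshold_is_strict(self):
        cls = classify_dmcs(self._frames({"FvM": (0.1, 5.0)}), fdr=0.1)
        assert cls.loc[0, "class"] == "none"


class TestSummaries:
    @pytest.mark.parametrize(
        "n_dmc,n_cov,expected",
        [(120, 462236, 0.026), (707, 462236, 0.15), (0, 1000, 0.0)],
    )
    def test_dmc_rates_two_significant_figures(self, n_dmc, n_cov, expected):
        assert summarize_dmc_rates(n_dmc, n_cov) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            summarize_dmc_rates(5, 0)
        with pytest.raises(ValueError):
            summarize_dmc_rates(10, 5)


class TestKNNImpute:
    def test_complete_matrix_unchanged(self):
        X = np.arange(12, dtype=float).reshape(3, 4)
        assert (knn_impute(X) == X).all()

    def test_single_neighbour_hand_example(self):
        # locus 0 matches locus 1 closely, locus 2 is far away;
        # the missing cell takes locus 1's value in that sample
        X = np.array(
            [[10.0, 20.0, np.nan], [10.0, 21.0, 30.0], [90.0, 80.0, 70.0]]
        )
        out = knn_impute(X, k=1)
        assert out[0, 2] == pytest.approx(30.0)

    def test_imputed_within_neighbour_range(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 100, size=(60, 10))
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out = knn_impute(Xm, k=5)
        assert np.isfinite(out).all()
        assert (out[mask] >= np.nanmin(Xm) - 1e-9).all()
        assert (out[mask] <= np.nanmax(Xm) + 1e-9).all()

    def test_high_missingness_falls_back_to_row_mean(self):
        X = np.array([[10.0, np.nan, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0],
                      [1.0, 2.0, 3.0, 4.0]])
        out = knn_impute(X, k=1, max_missing_frac=0.5)
        assert out[0, 1:] == pytest.approx([10.0, 10.0, 10.0])

    def test_all_missing_locus_rejected(self):
        with pytest.raises(ValueError, match="at least one observed"):
            knn_impute(np.array([[np.nan, np.nan], [1.0, 2.0]]))


class TestSpearmanScreen:
    def test_monotone_gives_unit_correlation(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        res = spearman_screen(X, [30, 31, 32, 33, 34])
        assert res.loc[0, "rho"] == pytest.approx(1.0)

    def test_hand_rank_example(self):
        res = spearman_screen(np.array([[2.0, 1.0, 4.0, 3.0]]), [1, 2, 3, 4])
        assert res.loc[0, "rho"] == pytest.approx(0.6)

    def test_negating_covariate_negates_rho(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 8)) * 100
        cov = rng.random(8)
        r1 = spearman_screen(X, cov)["rho"]
        r2 = spearman_screen(X, -cov)["rho"]
        assert r1.to_numpy() == pytest.approx(-r2.to_numpy())

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(8)
        X = rng.random((30, 12)) * 100
        cov = rng.random(12)
        res = spearman_screen(X, cov)
        for i in range(30):
            rho, p = stats.spearmanr(X[i], cov)
            assert res.loc[i, "rho"] == pytest.approx(rho)
            assert res.loc[i, "p"] == pytest.approx(p, rel=1e-6)

    def test_constant_locus_flagged(self):
        res = spearman_screen(np.array([[5.0, 5.0, 5.0, 5.0]]), [1, 2, 3, 4])
        assert res.loc[0, "flagged"] and np.isnan(res.loc[0, "rho"])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_screen(np.array([[1.0, 2.0, 3.0]]), [5, 5, 5])


class TestCompareAbsRho:
    def test_identical_samples_give_central_u(self):
        u, p = compare_abs_rho([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert u == pytest.approx(4.5)  # n_a * n_b / 2
        assert p > 0.9

    def test_extreme_separation_matches_enumeration(self):
        # all 6 assignments of {0.9, 0.8, 0.1, 0.2} into two pairs:
        # only the observed split and its mirror are as extreme -> p = 2/6
        u, p = compare_abs_rho([0.9, 0.8], [0.1, 0.2])
        assert u == 4.0
        assert p == pytest.approx(1 / 3)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(20), rng.random(15) * 0.5
        _, p1 = compare_abs_rho(a, b)
        _, p2 = compare_abs_rho(np.sqrt(a), np.sqrt(b))
        assert p1 == pytest.approx(p2)


class TestHormoneScreenIntegration:
    def test_sex_dmcs_track_e2_when_offset_is_strong(self, planted_study):
        """With a strong female E2 offset, planted sex loci correlate more
        strongly with E2 than null loci (rank-based comparison)."""
        cfg = SimulationConfig(
            seed=planted_study["config"].seed, e2_female_offset=1.5
        )
        study = planted_study["study"]
        horm = simulate_hormones(study.metadata, cfg)
        m = planted_study["matrix"]
        pct = knn_impute(m.percent())
        res = spearman_screen(pct, horm["e2"].to_numpy())
        truth = study.truth.set_index(["scaffold", "pos"])
        is_sex = np.array(
            [truth.loc[(l.scaffold, l.pos), "class"] == "sex" for l in m.loci]
        )
        rho = res["rho"].to_numpy()
        _, p = compare_abs_rho(rho[is_sex], rho[~is_sex])
        assert np.nanmean(np.abs(rho[is_sex])) > np.nanmean(np.abs(rho[~is_sex]))
        assert p < 0.01
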