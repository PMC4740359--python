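import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import binom

from provzone import outliers
from provzone.io import MarkerMatrix, ValidationError
from provzone.simulate import SimConfig, simulate_dataset

# ---------------------------------------------------------------------------
# independent numerical-integration oracle (single locus, J populations)

BETA_MEAN, BETA_SD, ALPHA_SD = -1.0, 1.8, 1.0


def _log_marginal_cell(y: int, n: int, eta: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """log of the p-integral: dominant-binomial likelihood against the
    Beta(theta*pi, theta*(1-pi)) frequency prior, theta = exp(-eta).

    Uses the exact expansion of (2 - p)^y, giving a finite signed sum of Beta
    functions -- no quadrature, so the oracle has no shared code path with the
    sampler.  Shapes: eta (E,), pi (P,) -> (E, P).
    """
    theta = np.exp(-eta)[:, None]
    a = theta * pi[None, :]
    b = theta * (1 - pi[None, :])
    log_c_ny = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    terms, signs = [], []
    for k in range(y + 1):
        terms.append(
            gammaln(y + 1) - gammaln(k + 1) - gammaln(y - k + 1)
            + (y - k) * np.log(2.0)
            + betaln(a + y + k, b + 2 * (n - y)) - betaln(a, b) + log_c_ny
        )
        signs.append((-1.0) ** k)
    val, sign = logsumexp(np.stack(terms), b=np.asarray(signs)[:, None, None],
                          axis=0, return_sign=True)
    assert (sign > 0).all()
    return val


def grid_posterior_inclusion(y, n, prior_odds_neutral=10.0,
                             n_pi=60, n_beta=81, n_alpha=81) -> float:
    """Posterior probability of the selection model by dense-grid integration."""
    y, n = np.asarray(y), np.asarray(n)
    pi = (np.arange(n_pi) + 0.5) / n_pi
    w_pi = np.full(n_pi, 1.0 / n_pi)
    beta = np.linspace(BETA_MEAN - 4.5 * BETA_SD, BETA_MEAN + 4.5 * BETA_SD, n_beta)
    w_beta = np.exp(-0.5 * ((beta - BETA_MEAN) / BETA_SD) ** 2)
    w_beta /= w_beta.sum()
    alpha = np.linspace(-4.5 * ALPHA_SD, 4.5 * ALPHA_SD, n_alpha)
    w_alpha = np.exp(-0.5 * (alpha / ALPHA_SD) ** 2)
    w_alpha /= w_alpha.sum()

    L0_pi = np.ones(n_pi)
    per_pop_incl = []
    for j in range(y.size):
        M0 = np.exp(_log_marginal_cell(int(y[j]), int(n[j]), beta, pi))
        L0_pi *= w_beta @ M0
        eta_all = (alpha[:, None] + beta[None, :]).ravel()
        M1 = np.exp(_log_marginal_cell(int(y[j]), int(n[j]), eta_all, pi))
        per_pop_incl.append(np.tensordot(M1.reshape(n_alpha, n_beta, n_pi),
                                         w_beta, axes=([1], [0])))
    L0 = w_pi @ L0_pi
    prod = np.ones((n_alpha, n_pi))
    for Aj in per_pop_incl:
        prod *= Aj
    L1 = w_alpha @ prod @ w_pi
    q = 1.0 / (1.0 + prior_odds_neutral)
    return float(q * L1 / (q * L1 + (1 - q) * L0))


# ---------------------------------------------------------------------------


class TestBandCounts:
    def test_counts_and_monomorphic_rule(self):
        bands = np.array([
            [1, 1, 0, 1], [1, 0, 0, 1], [1, 1, 0, 0], [1, 0, 0, 1],
        ], dtype=np.int8)
        m = MarkerMatrix(list("abcd"), ["A", "A", "B", "B"],
                         ["all1", "poly", "all0", "poly2"], bands)
        present, total, dropped = outliers.band_count_table(m)
        # loci monomorphic across ALL data are dropped; an all-present locus in
        # one population only is kept
        assert dropped == ["all1", "all0"]
        assert list(present.index) == ["poly", "poly2"]
        assert present.loc["poly", "A"] == 1 and present.loc["poly", "B"] == 1
        assert present.loc["poly2", "A"] == 2 and present.loc["poly2", "B"] == 1
        assert (total.to_numpy() == 2).all()

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        bands = (rng.random((12, 8)) < 0.5).astype(np.int8)
        m = MarkerMatrix([f"i{k}" for k in range(12)], ["A"] * 6 + ["B"] * 6,
                         [f"L{j}" for j in range(8)], bands)
        present, total, _ = outliers.band_count_table(m)
        for locus in present.index:
            j = m.locus_ids.index(locus)
            assert present.loc[locus, "A"] == bands[:6, j].sum()
            assert total.loc[locus, "A"] == 6


class TestDominantLikelihood:
    def test_closed_form(self):
        got = outliers.dominant_likelihood(3, 4, 0.5)
        expected = np.log(4) + 3 * np.log(0.75) + np.log(0.25)
        assert got == pytest.approx(expected)

    def test_boundary_behaviour(self):
        assert outliers.dominant_likelihood(4, 4, 1 - 1e-12) == pytest.approx(0.0, abs=1e-9)
        assert outliers.dominant_likelihood(3, 4, 1 - 1e-12) < -20

    def test_matches_genotype_enumeration(self):
        # under HWE the band probability is P(AA) + P(Aa) = p^2 + 2p(1-p)
        p, y, n = 0.3, 5, 9
        band_p = p**2 + 2 * p * (1 - p)
        assert outliers.dominant_likelihood(y, n, p) == pytest.approx(
            binom.logpmf(y, n, band_p))

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            outliers.dominant_likelihood(5, 4, 0.5)
        with pytest.raises(ValidationError):
            outliers.dominant_likelihood(1, 4, 0.0)


class TestMCMC:
    @pytest.mark.parametrize("counts", [((2, 12), (14, 14)), ((6, 7), (14, 14))])
    def test_posterior_inclusion_matches_grid_oracle(self, counts):
        """Chain posterior for one locus agrees with dense-grid integration."""
        y, n = counts
        present = pd.DataFrame([list(y)], index=["L1"], columns=["A", "B"])
        total = pd.DataFrame([list(n)], index=["L1"], columns=["A", "B"])
        oracle = grid_posterior_inclusion(y, n)
        res = outliers.run_outlier_mcmc(
            present, total, profile=outliers.MCMCProfile.fast(), seed=11)
        assert res.per_locus["inclusion_prob"].iloc[0] == pytest.approx(oracle, abs=0.05)

    def test_no_signal_no_decisive_calls(self):
        """Identical counts in every population never yield decisive odds."""
        present = pd.DataFrame(np.tile([5, 5, 5], (6, 1)),
                               index=[f"L{j}" for j in range(6)], columns=list("ABC"))
        total = present * 0 + 12
        for seed in (1, 2, 3):
            res = outliers.run_outlier_mcmc(
                present, total, profile=outliers.MCMCProfile.fast(), seed=seed)
            assert (res.per_locus["log10_po"] <= 2).all()

    def test_truth_loci_top_ranked(self, selected_dataset):
        """Clinal loci occupy the top posterior-odds ranks (generator truth)."""
        m, _, _, truth = selected_dataset
        hits = 0
        for seed in range(5):
            res = outliers.scan_markers(m, profile=outliers.MCMCProfile.fast(), seed=seed)
            top = set(res.per_locus.sort_values("log10_po", ascending=False)
                      .head(int(truth.selected.sum())).index)
            true_set = set(np.array(truth.locus_ids)[truth.selected])
            if len(top & true_set) >= len(true_set) - 1:
                hits += 1
        assert hits >= 4

    def test_seed_stability_of_inclusion(self, selected_dataset):
        m = selected_dataset[0]
        r1 = outliers.scan_markers(m, profile=outliers.MCMCProfile.fast(), seed=7)
        r2 = outliers.scan_markers(m, profile=outliers.MCMCProfile.fast(), seed=8)
        corr = np.corrcoef(r1.per_locus["inclusion_prob"],
                           r2.per_locus["inclusion_prob"])[0, 1]
        assert corr > 0.9

    def test_prior_odds_limits(self):
        rng = np.random.default_rng(5)
        present = pd.DataFrame(rng.integers(1, 11, (8, 3)),
                               index=[f"L{j}" for j in range(8)], columns=list("ABC"))
        total = present * 0 + 12
        profile = outliers.MCMCProfile(pilot_runs=1, pilot_length=100,
                                       burn_in=300, iterations=600, thinning=3)
        hi = outliers.run_outlier_mcmc(present, total, profile=profile,
                                       prior_odds_neutral=1e6, seed=1)
        assert outliers.call_outliers(hi)["loci"] == []
        lo = outliers.run_outlier_mcmc(present, total, profile=profile,
                                       prior_odds_neutral=1e-6, seed=1)
        assert set(outliers.call_outliers(lo, log10_po_threshold=0.5)["loci"]) == set(
            present.index)

    def test_drift_only_data_rarely_called(self):
        """Neutral isolation by distance yields no decisive outliers in >=90%."""
        zero = 0
        for seed in range(20):
            cfg = SimConfig(n_pops=6, n_per_pop=10, n_loci=30, n_selected=0,
                            drift_scale=0.02, selection_slope=0.0, seed=1000 + seed)
            m = simulate_dataset(cfg)[0]
            res = outliers.scan_markers(m, profile=outliers.MCMCProfile.fast(), seed=seed)
            if len(outliers.call_outliers(res)["loci"]) == 0:
                zero += 1
        assert zero >= 18

    def test_reproducible_given_seed(self, selected_dataset):
        m = selected_dataset[0]
        prof = outliers.MCMCProfile(pilot_runs=1, pilot_length=100, burn_in=200,
                                    iterations=400, thinning=4)
        a = outliers.scan_markers(m, profile=prof, seed=3)
        b = outliers.scan_markers(m, profile=prof, seed=3)
        pd.testing.assert_frame_equal(a.per_locus, b.per_locus)


class TestCallsAndQValues:
    def test_q_values_monotone_along_ranking(self, selected_dataset):
        res = outliers.scan_markers(selected_dataset[0],
                                    profile=outliers.MCMCProfile.fast(), seed=2)
        ranked = res.per_locus.sort_values("po", ascending=False)
        assert (np.diff(ranked["q_value"]) >= -1e-12).all()

    def test_fdr_hand_computed(self):
        per_locus = pd.DataFrame({
            "inclusion_prob": [0.999, 0.995, 0.4],
            "log10_po": [3.0, 2.3, -0.2],
            "alpha_mean": [1.0, -0.5, 0.1],
        }, index=["L1", "L2", "L3"])
        res = outliers.OutlierResult(per_locus, pd.DataFrame(), [], {})
        calls = outliers.call_outliers(res)
        assert calls["loci"] == ["L1", "L2"]
        assert calls["fdr"] == pytest.approx((0.001 + 0.005) / 2)
        assert calls["classification"] == {"L1": "diversifying", "L2": "balancing"}

    def test_empty_call_set(self):
        per_locus = pd.DataFrame({"inclusion_prob": [0.2], "log10_po": [-0.6],
                                  "alpha_mean": [0.0]}, index=["L1"])
        calls = outliers.call_outliers(outliers.OutlierResult(per_locus, pd.DataFrame(), [], {}))
        assert calls["loci"] == [] and calls["fdr"] is None
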