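import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wmnet.stats import (
    demographic_tests,
    nodal_family_test,
    partial_spearman,
    permutation_test,
    spearman,
)

import oracles


class TestPermutationTest:
    def test_identical_groups_saturate(self):
        res = permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                               n_perm=500, rng_seed=0)
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_extreme_separation_matches_enumeration(self):
        """a={0,0,0} vs b={10,10,10}: only 2 of the 20 label splits
        reach |diff| = 10, so the exact p is 0.1."""
        res = permutation_test([0.0, 0.0, 0.0], [10.0, 10.0, 10.0],
                               n_perm=20000, rng_seed=1)
        assert res.p_value == pytest.approx(0.1, abs=0.02)

    def test_power_at_two_sd_shift(self):
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(40):
            a = rng.normal(2.0, 1.0, size=31)
            b = rng.normal(0.0, 1.0, size=24)
            res = permutation_test(a, b, n_perm=500, rng_seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 38  # ~100% power at d=2 with n=31 vs 24

    def test_type_one_error_controlled(self):
        """Under the null, P(p <= alpha) tracks alpha."""
        rng = np.random.default_rng(11)
        pvals = []
        for rep in range(400):
            a = rng.normal(size=12)
            b = rng.normal(size=15)
            pvals.append(permutation_test(a, b, n_perm=199,
                                          rng_seed=rep).p_value)
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1):
            assert (pvals <= alpha).mean() <= alpha + 0.035

    def test_relabeling_flips_sign_only(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(0.8, 1, size=12)
        r1 = permutation_test(a, b, n_perm=4000, rng_seed=5)
        r2 = permutation_test(b, a, n_perm=4000, rng_seed=6)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff)
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.03)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0], n_perm=100)


class TestNodalFamily:
    def test_planted_node_flagged_others_not(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(31, 30))
        b = rng.normal(size=(24, 30))
        a[:, 4] += 3.0  # huge effect at node 5
        res = nodal_family_test(a, b, alpha=0.05, n_perm=4999, rng_seed=0)
        flagged = res.query("fdr_significant")["node"].tolist()
        assert flagged == ["5"]

    def test_fdr_decisions_match_stepup_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 40))
        b = rng.normal(size=(18, 40))
        a[:, :3] += 1.5
        res = nodal_family_test(a, b, alpha=0.05, n_perm=1999, rng_seed=1)
        expected = oracles.bh_stepup_oracle(res["p_value"].to_numpy(), 0.05)
        np.testing.assert_array_equal(res["fdr_significant"].to_numpy(),
                                      expected)

    def test_null_family_rarely_fires(self):
        rng = np.random.default_rng(9)
        total = 0
        for rep in range(20):
            a = rng.normal(size=(16, 36))
            b = rng.normal(size=(14, 36))
            res = nodal_family_test(a, b, alpha=0.05, n_perm=499, rng_seed=rep)
            total += int(res["fdr_significant"].sum())
        assert total / 20 <= 0.3  # FDR under the global null


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        res = spearman(x, y)
        assert res.rho == pytest.approx(oracles.spearman_oracle(x, y),
                                        abs=1e-12)

    def test_null_behaviour(self):
        rng = np.random.default_rng(6)
        rhos = [spearman(rng.permutation(55), rng.permutation(55)).rho
                for _ in range(100)]
        assert abs(np.mean(rhos)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialSpearman:
    def test_independent_control_approximates_plain(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = 0.6 * x + rng.normal(size=300)
        z = rng.normal(size=300)
        plain = spearman(x, y).rho
        partial = partial_spearman(x, y, z).rho
        assert partial == pytest.approx(plain, abs=0.05)

    def test_full_mediation_vanishes(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=50)
        x = z + 0.1 * rng.normal(size=50)
        res = partial_spearman(x, z, z)
        assert res.rho == 0.0
        assert res.p_value == 1.0

    def test_recovers_planted_partial_sign(self):
        """x and y share a positive link beyond their common driver z."""
        rng = np.random.default_rng(10)
        z = rng.normal(size=400)
        shared = rng.normal(size=400)
        x = z + shared + 0.5 * rng.normal(size=400)
        y = -z + shared + 0.5 * rng.normal(size=400)
        assert spearman(x, y).rho < 0.3  # masked by opposite z loadings
        assert partial_spearman(x, y, z).rho > 0.3

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        x, y, z = rng.normal(size=(3, 40))
        res = partial_spearman(x, y, z)
        ref = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-8)


def make_pheno(rng, n_control=24, n_amusic=31, shift=False):
    n = n_control + n_amusic
    group = ["control"] * n_control + ["amusic"] * n_amusic
    is_case = np.array([g == "amusic" for g in group])
    mbea = np.where(is_case, rng.normal(64, 5.2, n), rng.normal(88, 6, n))
    tone = np.where(is_case, rng.normal(86, 10, n), rng.normal(97, 2.9, n))
    if not shift:
        mbea = rng.normal(80, 6, n)
        tone = rng.normal(90, 5, n)
    sex = rng.choice(["M", "F"], size=n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": group,
        "mbea": np.clip(mbea, 0, 100),
        "tone": np.clip(tone, 0, 100),
        "age": rng.normal(21.8, 2.5, n),
        "sex": sex,
        "iq": rng.normal(124, 6, n),
        "brain_size": rng.normal(1418, 108, n),
    })


class TestDemographics:
    def test_matched_cohort_mostly_nonsignificant(self):
        rng = np.random.default_rng(3)
        res = demographic_tests(make_pheno(rng))
        matched = res[res["variable"].isin(["age", "iq", "brain_size"])]
        assert (matched["p_value"] > 0.01).all()

    def test_separated_scores_highly_significant(self):
        rng = np.random.default_rng(3)
        res = demographic_tests(make_pheno(rng, shift=True)).set_index("variable")
        assert res.loc["mbea", "p_value"] < 0.001
        assert res.loc["tone", "p_value"] < 0.001
        assert res.loc["mbea", "test"] == "mann_whitney"

    def test_chi_square_matches_contingency_oracle(self):
        """Sex split 10/14 vs 13/18 against the closed-form Pearson
        chi-square on the 2x2 table."""
        rows = []
        for g, m, f in (("control", 10, 14), ("amusic", 13, 18)):
            rows += [(g, "M")] * m + [(g, "F")] * f
        pheno = pd.DataFrame(rows, columns=["group", "sex"])
        for col in ("mbea", "tone", "age", "iq", "brain_size"):
            pheno[col] = np.linspace(10, 90, len(pheno))
        pheno["subject_id"] = [f"s{i}" for i in range(len(pheno))]
        res = demographic_tests(pheno).set_index("variable")
        obs = np.array([[10, 14], [13, 18]], dtype=float)
        expected = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        assert res.loc["sex", "statistic"] == pytest.approx(chi2, abs=1e-10)
        assert res.loc["sex", "p_value"] == pytest.approx(
            sps.chi2.sf(chi2, 1), abs=1e-10)
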