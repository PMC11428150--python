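"""Association engine against independent statistical oracles."""

import numpy as np
import pytest
from scipy.stats import kstest

import slem
from slem.assoc import AssociationTable, _batch_linear
from slem.exceptions import (
    ConfigurationError,
    DegeneratePredictorError,
    InvalidArgumentError,
    SingularDesignError,
)


def statsmodels_oracle(x, y, C):
    """Independent OLS route: statsmodels fit of y ~ 1 + x + C."""
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([x, C]) if C is not None else x)
    fit = sm.OLS(y, X).fit()
    return fit.params[1], fit.pvalues[1]


def normal_equation_oracle(x, y, C):
    """Brute-force normal equations + t distribution, no library fit."""
    from scipy import stats

    n = len(x)
    X = np.column_stack([np.ones(n), x] + ([C] if C is not None else []))
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    p = 2 * stats.t.sf(abs(beta[1] / se), df)
    return beta[1], p


class TestLinearAssoc:
    def test_noiseless_fit(self):
        x = np.arange(10.0)
        rec = slem.linear_assoc(x, 2 * x + 1)
        assert rec.statistic == pytest.approx(2.0, abs=1e-12)
        assert rec.p_value < 1e-30
        assert rec.sign == 1

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("oracle", [statsmodels_oracle, normal_equation_oracle])
    def test_matches_independent_oracle(self, seed, oracle):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        C = rng.normal(size=(50, 3))
        y = 0.4 * x + C @ [0.2, -0.1, 0.3] + rng.normal(size=50)
        rec = slem.linear_assoc(x, y, C)
        slope, p = oracle(x, y, C)
        assert rec.statistic == pytest.approx(slope, abs=1e-8)
        assert rec.p_value == pytest.approx(p, abs=1e-8)

    def test_permutation_null_uniform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        ps = []
        for _ in range(1000):
            ps.append(slem.linear_assoc(x, rng.permutation(y)).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_listwise_deletion(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        x_nan = x.copy()
        x_nan[:5] = np.nan
        rec = slem.linear_assoc(x_nan, y)
        ref = slem.linear_assoc(x[5:], y[5:])
        assert rec.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_predictor_raises(self):
        with pytest.raises(DegeneratePredictorError):
            slem.linear_assoc(np.ones(20), np.random.default_rng(0).normal(size=20))

    def test_singular_design_raises(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        with pytest.raises(SingularDesignError):
            slem.linear_assoc(x, rng.normal(size=30), covariates=np.column_stack([x, x]))


def kendall_pair_oracle(x, y):
    """O(n^2) concordant/discordant pair enumeration, tau-b tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(v.tolist()).values())


class TestKendallAssoc:
    def test_perfect_concordance(self):
        rec = slem.kendall_assoc([1, 2, 3, 4], [1, 2, 3, 4])
        assert rec.statistic == pytest.approx(1.0)
        rec = slem.kendall_assoc([1, 2, 3, 4], [4, 3, 2, 1])
        assert rec.statistic == pytest.approx(-1.0)
        assert rec.sign == -1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=8).astype(float)  # ties included
        y = rng.integers(0, 5, size=8).astype(float)
        rec = slem.kendall_assoc(x, y)
        assert rec.statistic == pytest.approx(kendall_pair_oracle(x, y), abs=1e-12)

    def test_exact_and_approximate_p_agree(self):
        from scipy.stats import kendalltau

        rng = np.random.default_rng(4)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        exact = kendalltau(x, y, method="exact").pvalue
        approx = kendalltau(x, y, method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02
        assert slem.kendall_assoc(x, y).p_value == pytest.approx(exact)

    def test_constant_vector_raises(self):
        with pytest.raises(DegeneratePredictorError):
            slem.kendall_assoc([1, 1, 1, 1], [1, 2, 3, 4])


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert slem.bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_hand_applied_formula(self):
        # p*m/i with step-up monotone enforcement: all become 0.03
        np.testing.assert_allclose(slem.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_empty_input(self):
        assert slem.bh_adjust([]).size == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_rank_and_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=30)
        q = slem.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in p-rank
        perm = rng.permutation(30)
        np.testing.assert_allclose(slem.bh_adjust(p[perm]), q[perm], atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            slem.bh_adjust([0.0, 0.5])


class TestBatchAssoc:
    def test_record_count_is_cartesian(self, small_cohort, small_config):
        dataset, _, _ = small_cohort
        table = slem.batch_assoc(dataset, "snp->isoform")
        assert len(table) == small_config.n_snps * small_config.n_isoforms
        assert table.frame.duplicated(["source", "target"]).sum() == 0

    def test_vectorized_path_matches_single_pair(self, small_cohort):
        dataset, _, _ = small_cohort
        table = slem.batch_assoc(dataset, "snp->marker", covariate_spec=["age", "sex"])
        C = dataset.covariates[["age", "sex"]].to_numpy(float)
        row = table.frame.iloc[17]
        rec = slem.linear_assoc(
            dataset.genotypes[row["source"]], dataset.markers[row["target"]], C
        )
        assert row["statistic"] == pytest.approx(rec.statistic, abs=1e-10)
        assert row["p"] == pytest.approx(rec.p_value, abs=1e-10)

    def test_kendall_used_for_upper_layers(self, small_cohort):
        dataset, _, _ = small_cohort
        table = slem.batch_assoc(dataset, "isoform->marker")
        row = table.frame.iloc[3]
        rec = slem.kendall_assoc(
            dataset.isoforms[row["source"]], dataset.markers[row["target"]]
        )
        assert row["statistic"] == pytest.approx(rec.statistic)

    def test_unknown_layer_pair_and_covariate(self, small_cohort):
        dataset, _, _ = small_cohort
        with pytest.raises(InvalidArgumentError):
            slem.batch_assoc(dataset, "snp->disease")
        with pytest.raises(ConfigurationError):
            slem.batch_assoc(dataset, "snp->marker", covariate_spec=["height"])

    def test_null_fdr_control(self):
        # Zero-effect data: the q < 0.05 discovery fraction stays near zero.
        cfg = slem.SynthConfig(
            n_samples_multilevel=100,
            n_snps=20,
            n_isoforms=10,
            n_markers=3,
            n_phenotypes=2,
            seed=33,
            effect_matrices=(np.zeros((20, 10)), np.zeros((10, 3)), np.zeros((3, 2))),
            liability_weights=np.zeros(2),
        )
        dataset, _ = slem.gen_multilevel(cfg)
        table = slem.batch_assoc(dataset, "snp->isoform", covariate_spec=["age", "sex"])
        frac = (table.frame["q"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(table))
        assert frac <= 0.05 + 3 * se

    def test_planted_pair_has_minimum_p_in_row(self):
        e1 = np.zeros((15, 6))
        e1[4, 2] = 2.0
        cfg = slem.SynthConfig(
            n_samples_multilevel=500,
            n_snps=15,
            n_isoforms=6,
            n_markers=3,
            n_phenotypes=2,
            seed=8,
            effect_matrices=(e1, np.zeros((6, 3)), np.zeros((3, 2))),
            liability_weights=np.zeros(2),
        )
        dataset, _ = slem.gen_multilevel(cfg)
        table = slem.batch_assoc(dataset, "snp->isoform", covariate_spec=["age", "sex"])
        row = table.frame[table.frame["source"] == "snp0004"]
        best = row.loc[row["p"].idxmin(), "target"]
        assert best == "iso0002"

    def test_table_tsv_round_trip(self, small_cohort, tmp_path):
        dataset, _, _ = small_cohort
        table = slem.batch_assoc(dataset, "marker->phenotype")
        path = tmp_path / "assoc.tsv"
        table.to_tsv(path)
        back = AssociationTable.from_tsv(path, "marker->phenotype")
        np.testing.assert_allclose(
            back.frame["statistic"], table.frame["statistic"], rtol=1e-12
        )
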