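"""Normalization oracles, elastic-net screening, NB testing, full runs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyllodiff import (
    SimConfig,
    deseq_size_factors,
    elastic_net_select,
    estimate_common_dispersion,
    filter_contaminants,
    generate_count_table,
    nb_test,
    run_ennb,
    tmm_factors,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# brute-force oracles, written from the textbook definitions with plain loops
# ---------------------------------------------------------------------------

def brute_tmm_factor(counts: pd.DataFrame, sample: str, ref: str,
                     trim_m: float = 0.3, trim_a: float = 0.05) -> float:
    """Trimmed weighted mean of log ratios, one sample vs the reference."""
    nk = counts[sample].sum()
    nr = counts[ref].sum()
    rows = []
    for g in counts.index:
        yk, yr = counts.loc[g, sample], counts.loc[g, ref]
        if yk > 0 and yr > 0:
            m = math.log2((yk / nk) / (yr / nr))
            a = 0.5 * math.log2((yk / nk) * (yr / nr))
            w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
            rows.append((m, a, w))
    n = len(rows)
    lo_m = math.floor(n * trim_m) + 1
    lo_a = math.floor(n * trim_a) + 1
    rank_m = stats.rankdata([r[0] for r in rows])
    rank_a = stats.rankdata([r[1] for r in rows])
    num = den = 0.0
    for (m, a, w), rm, ra in zip(rows, rank_m, rank_a):
        if lo_m <= rm <= n + 1 - lo_m and lo_a <= ra <= n + 1 - lo_a:
            num += w * m
            den += w
    return 2.0 ** (num / den)


def brute_deseq_factors(counts: pd.DataFrame) -> pd.Series:
    logs = []
    for g in counts.index:
        row = counts.loc[g]
        if (row > 0).all():
            logs.append(np.log(row) - np.mean(np.log(row)))
    return np.exp(pd.DataFrame(logs).median(axis=0))


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTmmFactors:
    def test_identical_columns_unity(self):
        counts = pd.DataFrame({"A": [3.0, 8, 12, 5], "B": [3.0, 8, 12, 5]})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.factors, [1.0, 1.0], atol=1e-12)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 10).astype(float) + 1
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.factors, [1.0, 1.0], atol=1e-12)

    def test_single_up_gene_shrinks_factor(self):
        counts = pd.DataFrame(
            {"A": [10.0, 10, 10, 10, 10, 10], "B": [10.0, 10, 10, 10, 10, 80]})
        f = tmm_factors(counts)
        assert f.factors["B"] < f.factors["A"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(50, (10, 4)).astype(float) + 1,
            index=[f"g{i}" for i in range(10)], columns=list("ABCD"))
        counts.iloc[3, 1] *= 6
        ref = counts.sum().idxmax()
        raw = {s: 1.0 if s == ref else brute_tmm_factor(counts, s, ref)
               for s in counts.columns}
        expected = pd.Series(raw)
        expected /= np.exp(np.mean(np.log(expected)))
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.factors[expected.index], expected, atol=1e-10)
        # frozen values independently confirmed against the R reference
        np.testing.assert_allclose(
            f.factors[list("ABCD")],
            [1.09260740, 0.73479270, 1.11184808, 1.12027741], atol=1e-7)

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        with pytest.raises(ValueError, match="B"):
            tmm_factors(counts)

    def test_global_rescale_invariance(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(30, (20, 3)).astype(float) + 1)
        f1 = tmm_factors(counts).factors
        f2 = tmm_factors(counts * 7.3).factors
        np.testing.assert_allclose(f1, f2, rtol=1e-10)


# ---------------------------------------------------------------------------
# DESeq-type size factors
# ---------------------------------------------------------------------------

class TestDeseqSizeFactors:
    def test_identical_columns_equal(self):
        counts = pd.DataFrame({"A": [3.0, 9, 27], "B": [3.0, 9, 27]})
        f = deseq_size_factors(counts)
        np.testing.assert_allclose(f.factors, [1.0, 1.0], atol=1e-12)

    def test_scaled_column_scaled_factor(self):
        counts = pd.DataFrame({"A": [4.0, 10, 25], "B": [12.0, 30, 75]})
        f = deseq_size_factors(counts)
        assert f.factors["B"] / f.factors["A"] == pytest.approx(3.0, abs=1e-12)

    def test_hand_computed_example(self):
        # 4 genes x 3 samples worked by hand: geometric means per gene,
        # then per-sample median of count/geomean ratios
        counts = pd.DataFrame(
            {"A": [10.0, 20, 40, 5], "B": [20.0, 40, 80, 10], "C": [10.0, 20, 40, 20]})
        # genes 1-3: ratios (2^-1/3, 2^2/3, 2^-1/3); gene 4: (0.5, 1, 2);
        # medians per sample: 2^-1/3, 2^2/3, 2^-1/3
        expected = [2 ** (-1 / 3), 2 ** (2 / 3), 2 ** (-1 / 3)]
        f = deseq_size_factors(counts)
        np.testing.assert_allclose(f.factors, expected, atol=1e-12)

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(50, (10, 4)).astype(float) + 1, columns=list("ABCD"))
        counts.iloc[3, 1] *= 6
        np.testing.assert_allclose(
            deseq_size_factors(counts).factors, brute_deseq_factors(counts), atol=1e-10)

    def test_fallback_when_no_all_positive_gene(self):
        counts = pd.DataFrame({"A": [5.0, 0.0], "B": [0.0, 3.0], "C": [6.0, 4.0]})
        # no gene is positive in every sample, but every sample has data
        f = deseq_size_factors(counts, fallback=True)
        assert (f.factors > 0).all()
        with pytest.raises(ValueError):
            deseq_size_factors(counts, fallback=False)


# ---------------------------------------------------------------------------
# elastic-net screening
# ---------------------------------------------------------------------------

class TestElasticNetSelect:
    def _noise_counts(self, seed=0, n_ann=100, n=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.poisson(30, (n_ann, n)).astype(float),
            index=[f"a{i}" for i in range(n_ann)],
            columns=[f"S{j}" for j in range(n)])

    def test_maximal_penalty_empty_selection(self):
        counts = self._noise_counts()
        labels = ["watered"] * 3 + ["drought"] * 3
        res = elastic_net_select(counts, labels, seed=0, c_grid=(1e-6,))
        assert res.selected == ()

    def test_fewer_than_three_per_group_instructs_imputation(self):
        counts = self._noise_counts(n=5)
        labels = ["watered"] * 3 + ["drought"] * 2
        with pytest.raises(ValueError, match="impute"):
            elastic_net_select(counts, labels)

    def test_constant_matrix_empty_with_warning(self):
        counts = pd.DataFrame(np.full((10, 6), 4.0),
                              index=[f"a{i}" for i in range(10)])
        labels = ["watered"] * 3 + ["drought"] * 3
        with pytest.warns(UserWarning, match="constant"):
            res = elastic_net_select(counts, labels)
        assert res.selected == ()

    def test_grouping_effect_duplicated_rows(self):
        # under a mixed penalty (mixing < 1) duplicated predictors enter or
        # leave the model together, unlike the lasso
        rng = np.random.default_rng(4)
        counts = self._noise_counts(seed=4, n_ann=40)
        strong = np.array([10.0, 12, 11, 60, 66, 58])
        counts.loc["dup1"] = strong
        counts.loc["dup2"] = strong
        labels = ["watered"] * 3 + ["drought"] * 3
        res = elastic_net_select(counts, labels, mixing=0.5, seed=1)
        assert ("dup1" in res.selected) == ("dup2" in res.selected)

    def test_deterministic_under_seed(self):
        table, truth = generate_count_table(
            SimConfig(n_annotations=200, n_contaminants=0, seed=3))
        labels = table.samples.loc[table.sample_ids, "treatment"]
        r1 = elastic_net_select(table.counts, labels, seed=5)
        r2 = elastic_net_select(table.counts, labels, seed=5)
        assert r1.selected == r2.selected and r1.lambda_ == r2.lambda_

    def test_signal_enrichment_over_seeds(self):
        # moderate-size check: selection is enriched for planted signal
        tp = fp = pool_sig = pool_null = 0
        for seed in range(4):
            table, truth = generate_count_table(
                SimConfig(n_annotations=400, n_contaminants=0, seed=100 + seed))
            labels = table.samples.loc[table.sample_ids, "treatment"]
            res = elastic_net_select(table.counts, labels, seed=seed)
            sel = set(res.selected)
            sig = truth.differential_ids
            tp += len(sel & sig)
            fp += len(sel - sig)
            pool_sig += len(sig)
            pool_null += 400 - len(sig)
        assert tp / pool_sig > fp / pool_null  # signal selected at a higher rate
        p = stats.hypergeom.sf(tp - 1, pool_sig + pool_null, pool_sig, tp + fp)
        assert p < 0.01


# ---------------------------------------------------------------------------
# NB test
# ---------------------------------------------------------------------------

class TestNbTest:
    LABELS = ["watered"] * 3 + ["drought"] * 3

    def test_identical_groups_null(self):
        y = np.full(6, 20.0)
        res = nb_test(y, self.LABELS, np.zeros(6), dispersion_mode=0.1)
        assert abs(res.coefficient) < 1e-8
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_zero_group_flagged_not_crash(self):
        y = np.array([0.0, 0, 0, 5, 6, 7])
        with pytest.warns(UserWarning):
            res = nb_test(y, self.LABELS, np.zeros(6))
        assert res.p == 1.0 and not res.converged

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            mu = np.array([200.0] * 3 + [800.0] * 3)
            r = 1 / 0.2
            y = rng.negative_binomial(r, r / (r + mu)).astype(float)
            res = nb_test(y, self.LABELS, np.zeros(6), dispersion_mode=0.2)
            if res.converged and abs(res.coefficient - math.log(4)) <= 3 * res.se:
                hits += 1
        assert hits >= 95

    def test_moments_mode_close_to_fixed_for_large_counts(self):
        y = np.array([180.0, 210, 195, 790, 820, 805])
        res = nb_test(y, self.LABELS, np.zeros(6), dispersion_mode="moments")
        assert res.converged
        assert res.coefficient == pytest.approx(math.log(4), rel=0.2)

    def test_offsets_must_be_finite(self):
        with pytest.raises(ValueError):
            nb_test(np.ones(6), self.LABELS, np.full(6, np.inf))


class TestCommonDispersion:
    def test_recovers_generating_dispersion(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(3, 1.5, 2000))[:, None] * np.ones(6)[None, :]
        r = 1 / 0.2
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        treat = np.array([0, 0, 0, 1, 1, 1])
        phi = estimate_common_dispersion(y, treat, np.zeros(6))
        assert phi == pytest.approx(0.2, abs=0.03)


# ---------------------------------------------------------------------------
# full two-stage run
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def clean_small():
    table, truth = generate_count_table(
        SimConfig(n_annotations=300, n_contaminants=20, seed=42))
    cleaned, _ = filter_contaminants(table)
    return cleaned, truth


class TestRunEnnb:
    def test_alpha_zero_no_significant(self, clean_small):
        cleaned, _ = clean_small
        res = run_ennb(cleaned, method=1, alpha=0.0, seed=1)
        assert res.frame["significant"].sum() == 0

    def test_significant_contained_in_selected(self, clean_small):
        cleaned, _ = clean_small
        res = run_ennb(cleaned, method=2, alpha=0.05, seed=1)
        assert (res.frame.loc[res.frame["significant"], "selected"]).all()

    def test_monotone_in_alpha(self, clean_small):
        cleaned, _ = clean_small
        res = run_ennb(cleaned, method=1, alpha=0.05, seed=1)
        s_small = res.significant_at(0.001)
        s_mid = res.significant_at(0.01)
        s_big = res.significant_at(0.05)
        assert s_small <= s_mid <= s_big

    def test_deterministic(self, clean_small):
        cleaned, _ = clean_small
        r1 = run_ennb(cleaned, method=1, alpha=0.01, seed=9)
        r2 = run_ennb(cleaned, method=1, alpha=0.01, seed=9)
        pd.testing.assert_frame_equal(r1.frame, r2.frame)

    def test_mixed_sites_rejected(self):
        table = make_table(np.ones((5, 6)) * 3)
        table.samples.loc["S0", "site"] = "DE"
        with pytest.raises(ValueError, match="site"):
            run_ennb(table)

    def test_unfiltered_controls_rejected(self):
        table = make_table(
            np.ones((5, 4)), treatments=["watered", "watered", "drought", "none"],
            classes=["experimental"] * 3 + ["mock"])
        with pytest.raises(ValueError, match="filter_contaminants"):
            run_ennb(table)

    def test_two_sample_group_imputed(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(40, (80, 5)).astype(float)
        table = make_table(counts, treatments=["watered"] * 3 + ["drought"] * 2)
        res = run_ennb(table, method=1, alpha=0.05, seed=2)
        assert res.n_imputed == 1
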