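"""Alpha, weighted kappa, c-statistic, and banded convergent validity."""

import numpy as np
import pandas as pd
import pytest

import interrai_mh as m
from interrai_mh.errors import UndefinedStatisticError


def alpha_oracle(mat):
    """Spreadsheet-style brute force: explicit variance sums, n-1 divisor."""
    n, k = mat.shape
    totals = mat.sum(axis=1)
    mean_t = totals.sum() / n
    var_t = sum((t - mean_t) ** 2 for t in totals) / (n - 1)
    var_items = 0.0
    for j in range(k):
        mu = mat[:, j].sum() / n
        var_items += sum((x - mu) ** 2 for x in mat[:, j]) / (n - 1)
    return k / (k - 1) * (1 - var_items / var_t)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([0, 1, 2, 3, 1, 2])
        assert m.cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_independent_items_give_near_zero(self):
        rng = np.random.default_rng(60)
        mat = rng.integers(0, 4, size=(5000, 5))
        assert abs(m.cronbach_alpha(mat)) < 0.05

    def test_hand_sized_matrix_matches_brute_force(self):
        mat = np.array(
            [[0, 1, 1, 2, 0, 1], [1, 2, 1, 3, 1, 2], [2, 3, 2, 3, 2, 3], [0, 0, 1, 1, 0, 0]],
            dtype=float,
        ).T  # 6 persons x 4 items
        assert m.cronbach_alpha(mat) == pytest.approx(alpha_oracle(mat), abs=1e-12)

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(61)
        for _ in range(200):
            n, k = int(rng.integers(4, 12)), int(rng.integers(2, 6))
            mat = rng.integers(0, 4, size=(n, k)).astype(float)
            if mat.sum(axis=1).var(ddof=1) == 0:
                continue
            assert m.cronbach_alpha(mat) == pytest.approx(alpha_oracle(mat), abs=1e-10)

    def test_spearman_brown_limit(self):
        """Exchangeable items with correlation r: alpha -> k*r/(1+(k-1)r)."""
        rng = np.random.default_rng(62)
        k, r, n = 5, 0.4, 200_000
        lam = np.sqrt(r)
        theta = rng.standard_normal(n)
        mat = lam * theta[:, None] + np.sqrt(1 - r) * rng.standard_normal((n, k))
        expected = k * r / (1 + (k - 1) * r)
        assert m.cronbach_alpha(mat) == pytest.approx(expected, abs=0.01)

    def test_zero_total_variance_is_undefined(self):
        mat = np.array([[1, 2], [2, 1], [0, 3]])  # constant row sums
        with pytest.raises(UndefinedStatisticError):
            m.cronbach_alpha(mat)

    def test_single_item_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            m.cronbach_alpha(np.array([[1.0], [2.0]]))


def kappa_oracle(table, weights):
    """Cell-by-cell brute force over the k x k table."""
    k = table.shape[0]
    n = table.sum()
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            d = abs(i - j) / (k - 1)
            w = d * d if weights == "quadratic" else d
            expected = table[i, :].sum() * table[:, j].sum() / n
            num += w * table[i, j]
            den += w * expected
    return 1 - num / den


class TestWeightedKappa:
    def test_diagonal_table_gives_one(self):
        assert m.weighted_kappa(np.diag([10, 20, 5])) == pytest.approx(1.0)

    def test_independence_table_gives_zero(self):
        rows = np.array([40.0, 35, 25])
        cols = np.array([30.0, 30, 40])
        table = np.outer(rows, cols) / 100
        assert m.weighted_kappa(table) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weights", ["quadratic", "linear"])
    def test_three_by_three_matches_hand_oracle(self, weights):
        table = np.array([[40, 10, 0], [0, 30, 0], [0, 0, 20]], dtype=float)
        assert m.weighted_kappa(table, weights) == pytest.approx(kappa_oracle(table, weights))

    @pytest.mark.parametrize("weights", ["quadratic", "linear"])
    def test_random_tables_match_oracle(self, weights):
        rng = np.random.default_rng(63)
        for _ in range(300):
            k = int(rng.integers(2, 6))
            table = rng.integers(0, 30, size=(k, k)).astype(float)
            if (kw := (np.abs(np.subtract.outer(range(k), range(k))))).sum() == 0:
                continue
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            d = kw / (k - 1)
            w = d**2 if weights == "quadratic" else d
            if (w * expected).sum() == 0:
                continue
            assert m.weighted_kappa(table, weights) == pytest.approx(
                kappa_oracle(table, weights), abs=1e-10
            )

    def test_quadratic_2x2_equals_unweighted(self):
        """On a 2x2 table every disagreement weight is 1, so kappa_w = Cohen's kappa."""
        table = np.array([[45, 5], [10, 40]], dtype=float)
        n = table.sum()
        po = np.trace(table) / n
        pe = (table.sum(1) * table.sum(0)).sum() / n**2
        cohen = (po - pe) / (1 - pe)
        assert m.weighted_kappa(table, "quadratic") == pytest.approx(cohen)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(64)
        a = rng.integers(0, 4, 500)
        b = np.clip(a + rng.integers(-1, 2, 500), 0, 3)
        table = np.zeros((4, 4))
        for x, y in zip(a, b):
            table[x, y] += 1
        for weights, sk_weights in (("quadratic", "quadratic"), ("linear", "linear")):
            assert m.weighted_kappa(table, weights) == pytest.approx(
                cohen_kappa_score(a, b, weights=sk_weights), abs=1e-10
            )

    def test_degenerate_margins_undefined(self):
        table = np.zeros((3, 3))
        table[1, 1] = 50  # both raters use one category only
        with pytest.raises(UndefinedStatisticError):
            m.weighted_kappa(table)


class TestCStatistic:
    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert m.c_statistic(y, s) == pytest.approx(1.0)

    def test_constant_score_gives_half(self):
        assert m.c_statistic([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0]) == pytest.approx(0.5)

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(65)
        for _ in range(50):
            n = 200
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(y, 1.5), 1)  # plenty of ties
            conc = ties = 0
            cases, controls = s[y == 1], s[y == 0]
            for sc in cases:
                for sn in controls:
                    if sc > sn:
                        conc += 1
                    elif sc == sn:
                        ties += 1
            expected = (conc + 0.5 * ties) / (len(cases) * len(controls))
            assert m.c_statistic(y, s) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(66)
        y = rng.integers(0, 2, 500)
        s = rng.normal(y, 2.0)
        assert m.c_statistic(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(67)
        y = rng.integers(0, 2, 300)
        s = rng.normal(y, 1.0)
        base = m.c_statistic(y, s)
        assert m.c_statistic(y, np.exp(s)) == pytest.approx(base)
        assert m.c_statistic(y, 3 * s - 7) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            m.c_statistic([1, 1, 1], [0.1, 0.2, 0.3])


class TestConvergentValidity:
    BANDS = {"score": [(0, 0), (1, 2), (3, 5), (6, 12)]}

    @staticmethod
    def _simulate(n, log_odds, rng, intercept=-1.5):
        score = rng.integers(0, 13, n)
        band = np.searchsorted([1, 3, 6], score, side="right")
        eta = intercept + np.array([0.0, *log_odds])[band]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        return pd.DataFrame({"score": score, "dx": y.astype(int)})

    def test_recovers_known_band_log_odds(self):
        rng = np.random.default_rng(68)
        true = (0.8, 1.4, 2.0)
        df = self._simulate(10_000, true, rng)
        res = m.convergent_validity(df, "dx", self.BANDS)
        for est, beta in zip(res.estimates, true):
            assert est.ci_low < np.exp(beta) < est.ci_high

    def test_null_association_covers_one(self):
        """OR confidence intervals cover 1 in >= 90% of 100 null replicates."""
        rng = np.random.default_rng(69)
        covered = 0
        for _ in range(100):
            df = self._simulate(400, (0.0, 0.0, 0.0), rng)
            if df["dx"].nunique() < 2:
                covered += 1
                continue
            res = m.convergent_validity(df, "dx", self.BANDS)
            covered += all(e.ci_low <= 1.0 <= e.ci_high for e in res.estimates)
        assert covered >= 90

    def test_monotone_association_gives_c_above_half(self):
        rng = np.random.default_rng(70)
        df = self._simulate(3000, (0.8, 1.4, 2.0), rng)
        res = m.convergent_validity(df, "dx", self.BANDS)
        assert res.c > 0.5

    def test_reference_band_is_implicit_one(self):
        rng = np.random.default_rng(71)
        df = self._simulate(2000, (0.5, 1.0, 1.5), rng)
        res = m.convergent_validity(df, "dx", self.BANDS)
        assert res.reference_band == "score=0"
        assert all(e.band != "score[0]" for e in res.estimates)

    def test_empty_band_dropped_with_warning(self):
        rng = np.random.default_rng(72)
        df = self._simulate(2000, (0.5, 1.0, 1.5), rng)
        df = df[df.score < 6]  # empty the top band
        res = m.convergent_validity(df, "dx", self.BANDS)
        assert "score[6-12]" in res.dropped_bands
        assert len(res.estimates) == 2

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"score": [0, 1, 5], "dx": [0, 0, 0]})
        with pytest.raises(UndefinedStatisticError):
            m.convergent_validity(df, "dx", self.BANDS)
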