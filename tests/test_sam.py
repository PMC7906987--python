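"""SAM statistic, fudge-factor selection, and permutation q-values."""

import numpy as np
import pandas as pd
import pytest

from crosstalk.exceptions import DataValidationError
from crosstalk.meta import choose_s0, sam_qvalues, sam_statistic

from _oracles import sam_d_brute, sam_q_brute

LABELS_3V3 = np.array(["case"] * 3 + ["control"] * 3)


class TestSamStatistic:
    def test_equal_means_give_zero(self):
        d = sam_statistic(np.array([[1.0, 2, 3, 3, 2, 1]]), LABELS_3V3, s0=0.5)
        assert d[0] == pytest.approx(0.0)

    def test_worked_example(self):
        # s_i = sqrt((2/3)/4 * 4) = sqrt(2/3), d = 3/sqrt(2/3)
        d = sam_statistic(np.array([[4.0, 5, 6, 1, 2, 3]]), LABELS_3V3, s0=0.0)
        assert d[0] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-12)

    def test_larger_s0_shrinks_magnitude(self, rng):
        x = rng.normal(size=(20, 8))
        labels = np.array(["case"] * 4 + ["control"] * 4)
        prev = np.abs(sam_statistic(x, labels, 0.0))
        for s0 in (0.5, 2.0, 10.0):
            cur = np.abs(sam_statistic(x, labels, s0))
            assert (cur <= prev + 1e-12).all()
            prev = cur

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=(rng.integers(1, 10), n1 + n2))
            labels = np.array(["case"] * n1 + ["control"] * n2)
            s0 = float(rng.uniform(0, 1))
            got = sam_statistic(x, labels, s0)
            exp = sam_d_brute(x.tolist(), list(range(n1)),
                              list(range(n1, n1 + n2)), s0)
            np.testing.assert_allclose(got, exp, atol=1e-10)

    def test_label_swap_negates_d(self, rng):
        x = rng.normal(size=(15, 10))
        labels = np.array(["case"] * 5 + ["control"] * 5)
        swapped = np.array(["control"] * 5 + ["case"] * 5)
        np.testing.assert_allclose(sam_statistic(x, labels, 0.3),
                                   -sam_statistic(x, swapped, 0.3), atol=1e-12)


class TestChooseS0:
    def test_identical_scatter_returns_smallest_candidate(self):
        s = np.full(200, 0.7)
        num = np.linspace(-1, 1, 200)
        assert choose_s0(s, num) == pytest.approx(0.7)

    def test_tiny_input_falls_back_to_fifth_percentile(self):
        s = np.linspace(0.1, 1.0, 10)
        assert choose_s0(s, np.ones(10)) == pytest.approx(np.percentile(s, 5))

    def test_choice_minimizes_cv_criterion(self, rng):
        """The selected candidate is the argmin of an independently computed
        coefficient of variation of windowed MADs of d."""
        s = rng.gamma(2.0, 0.3, size=500)
        num = rng.normal(0, s + 0.2)  # scatter-dependent numerators
        chosen = choose_s0(s, num)
        candidates = np.percentile(s, np.arange(0, 101, 5))
        edges = np.quantile(s, np.linspace(0, 1, 101))
        bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
        cvs = []
        for cand in candidates:
            d = num / (s + cand)
            mads = [np.median(np.abs(d[bins == b] - np.median(d[bins == b])))
                    for b in np.unique(bins)]
            cvs.append(np.std(mads) / np.mean(mads))
        assert chosen == pytest.approx(candidates[int(np.argmin(cvs))])


class TestSamQValues:
    def test_dominant_gene_gets_q_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(40, 20)) * 0.05
        x[0, :10] += 100.0  # one gene separates the groups completely
        labels = np.array(["case"] * 10 + ["control"] * 10)
        res = sam_qvalues(x, labels, n_permutations=200, rng=rng)
        assert res.q[0] == 0.0
        assert not res.exact

    def test_exact_enumeration_matches_brute_force(self, rng):
        x = rng.normal(size=(12, 6))
        x[:3, :3] += 1.5
        res = sam_qvalues(x, LABELS_3V3, n_permutations=1000, s0=0.2, rng=rng)
        assert res.exact and res.n_permutations == 20
        d_exp, q_exp = sam_q_brute(x, 3, 0.2)
        np.testing.assert_allclose(res.d, d_exp, atol=1e-10)
        np.testing.assert_allclose(res.q, q_exp, atol=1e-10)

    def test_too_few_assignments_is_an_error(self, rng):
        x = rng.normal(size=(5, 4))
        labels = np.array(["case"] * 2 + ["control"] * 2)  # C(4,2) = 6 < 10
        with pytest.raises(DataValidationError, match="distinct label assignments"):
            sam_qvalues(x, labels, n_permutations=100, rng=rng)

    def test_null_data_rarely_reaches_small_q(self):
        """On fully null matrices the q<0.10 call rate stays near or below
        the nominal rate (Monte Carlo, seeded)."""
        fractions = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            x = rng.standard_normal((200, 10))
            labels = np.array(["case"] * 5 + ["control"] * 5)
            res = sam_qvalues(x, labels, n_permutations=252, rng=rng)
            fractions.append(float((res.q < 0.10).mean()))
        assert np.mean(fractions) <= 0.15

    def test_q_monotone_in_abs_d(self, rng):
        x = rng.normal(size=(50, 12))
        labels = np.array(["case"] * 6 + ["control"] * 6)
        res = sam_qvalues(x, labels, n_permutations=300, rng=rng)
        order = np.argsort(-np.abs(res.d), kind="stable")
        assert (np.diff(res.q[order]) >= -1e-12).all()

    def test_deterministic_under_rng_seed(self):
        x = np.random.default_rng(3).normal(size=(30, 14))
        labels = np.array(["case"] * 7 + ["control"] * 7)
        r1 = sam_qvalues(x, labels, n_permutations=200,
                         rng=np.random.default_rng(11))
        r2 = sam_qvalues(x, labels, n_permutations=200,
                         rng=np.random.default_rng(11))
        np.testing.assert_array_equal(r1.q, r2.q)
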