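"""Tests of the diagnostic statistics layer."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from parafundus import (
    ContingencyTable2x2,
    chi2_association,
    decimal_va_to_logmar,
    fisher_exact_association,
    likelihood_ratios,
    roc_analysis,
    sample_size_two_means,
    unpaired_t_test,
)


class TestChi2:
    def test_printed_association_table(self):
        # flame/non-flame vs nonischemic/ischemic
        _, p = chi2_association(ContingencyTable2x2(39, 0, 6, 13))
        assert p < 0.001

    def test_independence_gives_zero_statistic(self):
        stat, p = chi2_association(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_pearson(self):
        # n (ad - bc)^2 / (r1 r2 c1 c2), hand-evaluated
        stat, _ = chi2_association(ContingencyTable2x2(39, 0, 6, 13))
        expected = 58 * (39 * 13 - 0 * 6) ** 2 / (39 * 19 * 45 * 13)
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_row_and_column_swap(self):
        a = chi2_association(ContingencyTable2x2(7, 3, 2, 11))
        b = chi2_association(ContingencyTable2x2(11, 2, 3, 7))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi2_association(ContingencyTable2x2(5, 0, 7, 0))

    def test_fisher_exact_available(self):
        _, p = fisher_exact_association(ContingencyTable2x2(39, 0, 6, 13))
        assert p < 0.001


class TestTTest:
    def test_identical_groups(self):
        t, p, _, _ = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_large_shift_is_significant(self):
        _, p, _, _ = unpaired_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.001

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_textbook_pooled_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 20))
        y = rng.normal(0.4, 1.5, rng.integers(3, 20))
        t, p, _, _ = unpaired_t_test(x, y)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_ref = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
        p_ref = 2 * sps.t.sf(abs(t_ref), nx + ny - 2)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])


def _bruteforce_auc(pos, neg):
    """Between-class pair count with ties worth 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis(
            np.array([0.8, 0.9, 0.1, 0.2]),
            np.array([0, 0, 1, 1]),
            positive_means_low_score=True,
        )
        assert res.auroc == 1.0
        assert res.sensitivity_pct == 100.0
        assert res.specificity_pct == 100.0
        assert 0.2 <= res.cutoff < 0.8
        assert res.lr_pos is None
        assert res.lr_neg == 0.0

    def test_exchangeable_scores_give_half(self):
        res = roc_analysis(
            np.array([0.1, 0.3, 0.1, 0.3]),
            np.array([0, 0, 1, 1]),
            positive_means_low_score=True,
        )
        assert res.auroc == pytest.approx(0.5, abs=1e-12)

    def test_handcrafted_tie_set_matches_mann_whitney(self):
        scores = np.array([0.1, 0.2, 0.2, 0.35, 0.4, 0.4, 0.6, 0.9])
        labels = np.array([1, 1, 0, 1, 0, 1, 0, 0])
        res = roc_analysis(scores, labels, positive_means_low_score=True)
        pos = (-scores[labels == 1]).tolist()
        neg = (-scores[labels == 0]).tolist()
        assert res.auroc == pytest.approx(_bruteforce_auc(pos, neg), abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_auc_matches_bruteforce_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 30)
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels, positive_means_low_score=False)
        ref = _bruteforce_auc(
            scores[labels == 1].tolist(), scores[labels == 0].tolist()
        )
        assert res.auroc == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_complement_symmetry_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.linspace(0, 1, 20))
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_analysis(scores, labels, positive_means_low_score=False).auroc
        b = roc_analysis(-scores, labels, positive_means_low_score=False).auroc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_youden_cutoff_is_maximal(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0.3, 0.15, 40), 2)
        labels = (rng.random(40) < 0.4).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels, positive_means_low_score=True)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        j_best = -np.inf
        for c in np.unique(scores):
            sens = (pos <= c).mean()
            spec = (neg > c).mean()
            j_best = max(j_best, sens + spec - 1)
        j_rep = res.sensitivity_pct / 100 + res.specificity_pct / 100 - 1
        assert j_rep == pytest.approx(j_best, abs=1e-12)

    def test_fixed_specificity_sensitivities(self):
        # 10 negatives, 10 positives with partial overlap
        neg = np.linspace(0.30, 0.75, 10)
        pos = np.linspace(0.05, 0.50, 10)
        scores = np.concatenate([neg, pos])
        labels = np.array([0] * 10 + [1] * 10)
        res = roc_analysis(scores, labels, positive_means_low_score=True)
        # brute force: best sensitivity with specificity >= the floor
        for floor, got in (
            (90.0, res.sens_at_spec90_pct),
            (95.0, res.sens_at_spec95_pct),
        ):
            best = 0.0
            for c in np.unique(scores):
                spec = (neg > c).mean() * 100
                if spec >= floor:
                    best = max(best, (pos <= c).mean() * 100)
            assert got == pytest.approx(best, abs=1e-9)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_analysis(np.array([0.1, 0.2]), np.array([1, 1]))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_delong_ci_matches_pROC(self, tmp_path):
        """DeLong AUC variance cross-checked against R's pROC package."""
        rng = np.random.default_rng(42)
        scores = np.round(np.concatenate([rng.normal(0.6, 0.2, 25),
                                          rng.normal(0.4, 0.2, 20)]), 3)
        labels = np.array([1] * 25 + [0] * 20)
        res = roc_analysis(scores, labels, positive_means_low_score=False)
        csv = tmp_path / "d.csv"
        csv.write_text(
            "score,label\n"
            + "\n".join(f"{s},{l}" for s, l in zip(scores, labels))
        )
        rcode = (
            f'd <- read.csv("{csv}"); suppressMessages(library(pROC));'
            'r <- roc(d$label, d$score, direction="<", quiet=TRUE);'
            'ci <- ci.auc(r, method="delong");'
            'cat(sprintf("%.10f %.10f %.10f", ci[1], ci[2], ci[3]))'
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        lo, auc, hi = map(float, out.stdout.split())
        assert res.auroc == pytest.approx(auc, abs=1e-9)
        assert res.ci95[0] == pytest.approx(lo, abs=1e-6)
        assert res.ci95[1] == pytest.approx(hi, abs=1e-6)


class TestLikelihoodRatios:
    def test_perfect_specificity_row(self):
        lr_pos, lr_neg = likelihood_ratios(94.59, 100.00)
        assert lr_pos is None
        assert round(lr_neg, 2) == 0.05

    def test_foveal_thickness_row(self):
        lr_pos, lr_neg = likelihood_ratios(81.58, 64.29)
        assert round(lr_pos, 2) == 2.28
        assert round(lr_neg, 2) == 0.29

    def test_perfect_test(self):
        lr_pos, lr_neg = likelihood_ratios(100.0, 100.0)
        assert lr_pos is None
        assert lr_neg == 0.0

    def test_zero_specificity_flags_negative_lr(self):
        lr_pos, lr_neg = likelihood_ratios(50.0, 0.0)
        assert lr_neg is None
        assert lr_pos == pytest.approx(0.5)


class TestSampleSize:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(m1=0.33, s1=0.13, m2=0.20, s2=0.11, allocation_ratio=0.75),
            dict(m1=1.0, s1=1.0, m2=0.0, s2=1.0, allocation_ratio=1.0),
            dict(m1=5.0, s1=2.0, m2=4.0, s2=3.0, allocation_ratio=2.0),
        ],
    )
    def test_matches_hand_formula(self, kwargs):
        alpha, beta = 0.05, 0.20
        zsum = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(1 - beta)
        k = kwargs["allocation_ratio"]
        sigma2 = (kwargs["s1"] ** 2 + kwargs["s2"] ** 2) / 2
        n2_raw = (1 + 1 / k) * zsum**2 * sigma2 / (kwargs["m1"] - kwargs["m2"]) ** 2
        n1, n2, total = sample_size_two_means(alpha=alpha, beta=beta, **kwargs)
        assert n2 == math.ceil(n2_raw)
        assert n1 == math.ceil(k * n2_raw)
        assert total == n1 + n2

    def test_standardized_difference_one_equal_allocation(self):
        # n per group = ceil(2 (1.9600 + 0.8416)^2) = 16
        n1, n2, total = sample_size_two_means(1.0, 1.0, 0.0, 1.0)
        assert n1 == n2 == 16
        assert total == 32

    def test_doubling_delta_quarters_n(self):
        zsum = sps.norm.ppf(0.975) + sps.norm.ppf(0.80)
        n_small = 2 * zsum**2 * 1.0 / 0.5**2
        n_large = 2 * zsum**2 * 1.0 / 1.0**2
        assert n_small == pytest.approx(4 * n_large, rel=1e-12)
        # and the implementation's ceilings bracket the same ratio
        _, n2_small, _ = sample_size_two_means(0.5, 1.0, 0.0, 1.0)
        _, n2_large, _ = sample_size_two_means(1.0, 1.0, 0.0, 1.0)
        assert n2_small == math.ceil(n_small)
        assert n2_large == math.ceil(n_large)

    def test_equal_means_infeasible(self):
        with pytest.raises(ValueError):
            sample_size_two_means(0.5, 0.1, 0.5, 0.1)


class TestLogmar:
    @pytest.mark.parametrize(
        "va,expected", [(1.0, 0.0), (0.1, 1.0), (0.5, 0.3010299957)]
    )
    def test_conversion(self, va, expected):
        assert decimal_va_to_logmar(va) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            decimal_va_to_logmar(0.0)


class TestParameterRecovery:
    def test_auroc_recovered_on_perfusion_group_parameters(self):
        """Scores drawn from the two perfusion groups' parallelism
        distributions (0.362+/-0.115 vs 0.222+/-0.126, n=45/13) are
        discriminable in the right direction, and the mean empirical AUROC
        matches the binormal prediction Phi(0.140 / 0.1706) ~= 0.794."""
        expected_auc = sps.norm.cdf(
            (0.362 - 0.222) / math.hypot(0.115, 0.126)
        )
        rng = np.random.default_rng(20160623)
        aucs = []
        for _ in range(200):
            nonisch = rng.normal(0.362, 0.115, 45)
            isch = rng.normal(0.222, 0.126, 13)
            scores = np.concatenate([nonisch, isch])
            labels = np.array([0] * 45 + [1] * 13)
            aucs.append(
                roc_analysis(scores, labels, positive_means_low_score=True).auroc
            )
        aucs = np.asarray(aucs)
        assert np.mean(aucs > 0.5) >= 0.99  # direction recovered
        assert np.mean(aucs) == pytest.approx(expected_auc, abs=0.03)
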