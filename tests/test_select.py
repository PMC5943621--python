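"""Logical/numerical group-specific feature selection."""

import itertools

import numpy as np
import pytest
from scipy import stats

from kmersig.io import SampleEntry, SampleSheet
from kmersig.kmers import KmerVector, canonical, decode_codes
from kmersig.matrix import build_matrix
from kmersig.select import (
    CASE_PRESENT,
    CONTROL_PRESENT,
    ass_logical,
    chi2_logical,
    logistic_ass,
    select_features,
    select_logical,
    select_numerical,
    wilcoxon_pvalues,
    write_features_tsv,
    read_features_tsv,
)


def labels_of(n_case, n_ctrl):
    return np.array([1] * n_case + [0] * n_ctrl)


def matrix_from_rows(rows, labels, k=6):
    """Build a FeatureMatrix whose frequency rows are (proportional to) the
    given nonnegative integer rows."""
    rows = np.asarray(rows)
    n = rows.shape[1]
    pool = []
    codes = np.arange(4**k, dtype=np.uint64)
    for km in decode_codes(codes[: 4 * rows.shape[0] + 8], k):
        if canonical(km) == km:
            pool.append(km)
        if len(pool) == rows.shape[0]:
            break
    entries = [
        SampleEntry(f"s{j}", "case" if l else "control") for j, l in enumerate(labels)
    ]
    vecs = []
    for j in range(n):
        counts = {pool[i]: int(rows[i, j]) for i in range(rows.shape[0]) if rows[i, j] > 0}
        if not counts:
            counts = {pool[0]: 1}
        vecs.append(KmerVector.from_counts(f"s{j}", k, counts))
    return build_matrix(vecs, SampleSheet(entries)), pool


class TestAssLogical:
    def test_perfect_separator(self):
        row = [1] * 10 + [0] * 10
        ass, orient = ass_logical(row, labels_of(10, 10))
        assert ass == 1.0 and orient == CASE_PRESENT

    def test_uninformative_everywhere_present(self):
        ass, _ = ass_logical([1] * 20, labels_of(10, 10))
        assert ass == 0.5

    def test_partial_example(self):
        # 8/10 cases present, 1/10 controls present -> (0.8 + 0.9)/2
        row = [1] * 8 + [0] * 2 + [1] + [0] * 9
        ass, orient = ass_logical(row, labels_of(10, 10))
        assert ass == pytest.approx(0.85) and orient == CASE_PRESENT

    def test_control_present_orientation(self):
        row = [0] * 10 + [1] * 10
        ass, orient = ass_logical(row, labels_of(10, 10))
        assert ass == 1.0 and orient == CONTROL_PRESENT

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            ass_logical([1, 0], [1, 1])

    def test_matches_exhaustive_enumeration_n12(self):
        """ASS equals the brute-force confusion matrix for every presence
        pattern on 12 samples, and always lies in [0.5, 1]."""
        labels = labels_of(6, 6)
        for bits in itertools.product([0, 1], repeat=12):
            row = np.array(bits)
            ass, orient = ass_logical(row, labels)
            # independent oracle: evaluate both orientations explicitly
            best = 0.0
            best_orient = None
            for orient_cp in (True, False):
                pred = row == 1 if orient_cp else row == 0
                sens = (pred & (labels == 1)).sum() / 6
                spec = (~pred & (labels == 0)).sum() / 6
                v = (sens + spec) / 2
                if v > best:
                    best, best_orient = v, orient_cp
            assert ass == pytest.approx(best)
            assert 0.5 <= ass <= 1.0


class TestChi2Logical:
    def test_degenerate_all_present(self):
        assert chi2_logical([1] * 20, labels_of(10, 10)) == 1.0

    def test_perfect_table_closed_form(self):
        # chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 20 -> p ~ 7.7e-6
        p = chi2_logical([1] * 10 + [0] * 10, labels_of(10, 10))
        assert p == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-10)
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_matches_scipy_contingency(self, rng):
        labels = labels_of(8, 12)
        for _ in range(25):
            row = rng.integers(0, 2, 20)
            if row.min() == row.max():
                continue
            table = np.array(
                [
                    [(row[labels == 1] == 1).sum(), (row[labels == 0] == 1).sum()],
                    [(row[labels == 1] == 0).sum(), (row[labels == 0] == 0).sum()],
                ]
            )
            expected = stats.chi2_contingency(table, correction=False).pvalue
            assert chi2_logical(row, labels) == pytest.approx(expected, rel=1e-9)

    def test_null_pvalues_are_uniform(self, rng):
        """Monte-Carlo calibration: label-independent rows give p-values
        whose distribution matches the chi-squared reference."""
        labels = labels_of(25, 25)
        ps = []
        for _ in range(1000):
            row = rng.integers(0, 2, 50)
            ps.append(chi2_logical(row, labels))
        # discrete statistic: compare via empirical CDF at a few quantiles
        ps = np.array(ps)
        for q in (0.1, 0.25, 0.5):
            assert abs((ps <= q).mean() - q) < 0.06


class TestSelectLogical:
    def test_perfect_separator_selected(self):
        labels = labels_of(5, 5)
        rows = np.array([[2] * 5 + [0] * 5, [1] * 10])
        F, pool = matrix_from_rows(rows, labels)
        feats = select_logical(F, theta1=0.8)
        assert [f.kmer for f in feats] == [pool[0]]
        assert feats[0].ass_train == 1.0

    def test_threshold_monotone(self, rng):
        labels = labels_of(8, 8)
        rows = rng.integers(0, 3, (30, 16))
        F, _ = matrix_from_rows(rows, labels)
        strict = {f.kmer for f in select_logical(F, theta1=1.0)}
        loose = {f.kmer for f in select_logical(F, theta1=0.8)}
        assert strict <= loose

    def test_invariant_to_sample_order_and_relabeling(self, rng):
        labels = np.array([1, 0] * 8)
        rows = rng.integers(0, 3, (40, 16))
        F, _ = matrix_from_rows(rows, labels)
        feats = select_logical(F, theta1=0.7)
        # permute samples
        perm = rng.permutation(16)
        Fp, _ = matrix_from_rows(rows[:, perm], labels[perm])
        feats_p = select_logical(Fp, theta1=0.7)
        assert [(f.kmer, f.ass_train) for f in feats] == [
            (f.kmer, f.ass_train) for f in feats_p
        ]
        # flip case/control: ASS unchanged, orientation flips
        Ff, _ = matrix_from_rows(rows, 1 - labels)
        feats_f = select_logical(Ff, theta1=0.7)
        assert [(f.kmer, f.ass_train) for f in feats] == [
            (f.kmer, f.ass_train) for f in feats_f
        ]
        flip = {CASE_PRESENT: CONTROL_PRESENT, CONTROL_PRESENT: CASE_PRESENT}
        for a, b in zip(feats, feats_f):
            if a.ass_train > 0.5:
                assert b.orientation == flip[a.orientation]

    def test_chi2_metric_cuts_same_count(self, rng):
        labels = labels_of(10, 10)
        rows = rng.integers(0, 2, (60, 20)) * rng.integers(1, 4, (60, 20))
        F, _ = matrix_from_rows(rows, labels)
        by_ass = select_logical(F, theta1=0.7, metric="ass")
        by_chi2 = select_logical(F, theta1=0.7, metric="chi2")
        assert len(by_ass) == len(by_chi2)
        assert all(f.selected_by == "chi2" and f.p_value is not None for f in by_chi2)


class TestWilcoxon:
    def test_identical_distributions_removed(self):
        labels = labels_of(6, 6)
        X = np.tile(np.arange(12, dtype=float), (1, 1))
        X = np.array([[5.0] * 12])
        p = wilcoxon_pvalues(X, labels)
        assert p[0] == 1.0

    def test_complete_separation_small_sample_exact(self):
        labels = labels_of(10, 10)
        x = np.concatenate([np.arange(10) + 100.0, np.arange(10)])
        p = wilcoxon_pvalues(x[None, :], labels)
        # exact two-sided tail of complete separation at n=10+10
        expected = stats.mannwhitneyu(
            x[:10], x[10:], alternative="two-sided", method="exact"
        ).pvalue
        assert p[0] == pytest.approx(expected)
        assert p[0] < 0.001

    def test_matches_scipy_exact_small_samples(self, rng):
        for n1, n2 in [(5, 7), (10, 10), (3, 9)]:
            labels = labels_of(n1, n2)
            X = rng.normal(0, 1, (30, n1 + n2))
            p = wilcoxon_pvalues(X, labels)
            for i in range(30):
                expected = stats.mannwhitneyu(
                    X[i, :n1], X[i, n1:], alternative="two-sided", method="exact"
                ).pvalue
                assert p[i] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_asymptotic_with_ties(self, rng):
        labels = labels_of(15, 15)
        X = rng.integers(0, 6, (40, 30)).astype(float)  # heavy ties
        p = wilcoxon_pvalues(X, labels)
        for i in range(40):
            expected = stats.mannwhitneyu(
                X[i, labels == 1], X[i, labels == 0],
                alternative="two-sided", method="asymptotic",
            ).pvalue
            assert p[i] == pytest.approx(expected, rel=1e-9)

    def test_null_type_one_rate_near_theta2(self, rng):
        labels = labels_of(15, 15)
        X = rng.lognormal(0, 1, (10_000, 30))
        p = wilcoxon_pvalues(X, labels)
        rate = (p <= 0.01).mean()
        assert 0.005 <= rate <= 0.015


class TestLogisticAss:
    def test_perfect_separation_reaches_one(self):
        labels = labels_of(5, 5)
        x = np.array([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.15, 0.05, 0.3])
        ass, (b0, b1) = logistic_ass(x, labels)
        assert ass == 1.0
        assert b1 > 0

    def test_constant_row_gives_half(self):
        labels = labels_of(5, 5)
        ass, _ = logistic_ass(np.full(10, 0.3), labels)
        assert ass == 0.5

    def test_partial_overlap_example(self):
        # one misclassification per class -> ASS 0.75
        x = np.array([0.8, 0.9, 0.7, 0.2, 0.1, 0.3, 0.2, 0.6])
        labels = labels_of(4, 4)
        ass, _ = logistic_ass(x, labels)
        assert ass == pytest.approx(0.75)

    def test_matches_sklearn_mle(self, rng):
        from sklearn.linear_model import LogisticRegression

        labels = labels_of(8, 8)
        for _ in range(10):
            x = rng.normal(0, 1, 16) + labels * rng.uniform(0, 1)
            ass, (b0, b1) = logistic_ass(x, labels)
            sk = LogisticRegression(C=1e8, tol=1e-10, max_iter=10_000).fit(
                x[:, None], labels
            )
            # compare decision agreement (coefficients match when MLE exists)
            if abs(sk.coef_[0][0]) < 50:
                assert b1 == pytest.approx(sk.coef_[0][0], rel=1e-3, abs=1e-6)
                assert b0 == pytest.approx(sk.intercept_[0], rel=1e-3, abs=1e-6)


class TestSelectNumerical:
    def test_differential_row_selected_and_exclusivity(self, rng):
        labels = labels_of(12, 12)
        base = rng.integers(50, 60, (1, 24))
        diff = np.where(labels == 1, 300, 100)[None, :] + rng.integers(0, 20, (1, 24))
        logical_row = np.where(labels == 1, 40, 0)[None, :]
        rows = np.vstack([base, diff, logical_row])
        F, pool = matrix_from_rows(rows, labels)
        feats = select_features(F, theta1=0.8, theta2=0.05, theta3=0.8)
        tracks = {f.kmer: f.track for f in feats}
        assert tracks[pool[2]] == "logical"
        assert tracks[pool[1]] == "numerical"
        # a k-mer appears in at most one track
        assert len(tracks) == len(feats)

    def test_null_selection_rate_bounded(self, rng):
        labels = labels_of(10, 10)
        rows = rng.integers(1, 100, (400, 20))
        F, _ = matrix_from_rows(rows, labels)
        feats = select_numerical(F, theta2=0.01, theta3=0.8)
        assert len(feats) <= 0.02 * 400 + 3

    def test_tsv_roundtrip(self, tmp_path, rng):
        labels = labels_of(6, 6)
        diff = np.where(labels == 1, 300, 100)[None, :] + rng.integers(0, 30, (1, 12))
        base = np.full((1, 12), 100)
        F, _ = matrix_from_rows(np.vstack([diff, base]), labels)
        feats = select_features(F, theta2=0.05)
        assert feats
        write_features_tsv(feats, tmp_path / "f.tsv")
        back = read_features_tsv(tmp_path / "f.tsv")
        assert [(f.kmer, f.track, f.orientation) for f in back] == [
            (f.kmer, f.track, f.orientation) for f in feats
        ]
        for a, b in zip(back, feats):
            assert a.ass_train == pytest.approx(b.ass_train, rel=1e-5)
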