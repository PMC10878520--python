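"""Selectivity, classification, correlation and contact-prediction metrics."""

import numpy as np
import pandas as pd
import pytest

import annealdca as ad
from annealdca import AnnealModel, PottsEnergy, SelectivityTable

from .conftest import make_random_energy


def dataset_from_frequencies(freqs_per_round, labels, total=1000):
    """Rounds over variants 0..V-1 (encoded as single-site-ish rows)."""
    V = len(freqs_per_round[0])
    L = 3
    seqs = np.array([[v % 3, (v // 3) % 3, (v // 9) % 3] for v in range(V)],
                    dtype=np.uint8)
    rounds = []
    for label, freqs in zip(labels, freqs_per_round):
        counts = np.round(np.array(freqs) * total).astype(int)
        keep = counts > 0
        rounds.append(ad.SequenceRound(label, seqs[keep], counts[keep]))
    return ad.ScreeningDataset(rounds, ad.Alphabet.generic(3))


class TestLogSelectivity:
    def test_exact_geometric_growth(self):
        # frequencies 0.1 -> 0.2 -> 0.4 double each round: slope log 2, SE 0
        ds = dataset_from_frequencies(
            [(0.1, 0.9), (0.2, 0.8), (0.4, 0.6)], labels=(0, 1, 2)
        )
        table = ad.log_selectivity(ds)
        # variant 0 is row [0,0,0] (lexicographically first)
        assert table.theta[0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert table.uncertainty[0] == pytest.approx(0.0, abs=1e-9)

    def test_constant_frequency_gives_zero(self):
        ds = dataset_from_frequencies(
            [(0.5, 0.5), (0.5, 0.5), (0.5, 0.5)], labels=(0, 2, 5)
        )
        table = ad.log_selectivity(ds)
        np.testing.assert_allclose(table.theta, 0.0, atol=1e-12)

    def test_matches_closed_form_ols(self, rng):
        x = np.array([0.0, 1.0, 3.0])
        f = np.array([0.02, 0.07, 0.2])
        ds = dataset_from_frequencies(
            [(f[0], 1 - f[0]), (f[1], 1 - f[1]), (f[2], 1 - f[2])],
            labels=(0, 1, 3), total=10 ** 6,
        )
        table = ad.log_selectivity(ds)
        y = np.log(np.round(f * 10 ** 6) / 10 ** 6)
        n = 3
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - y.mean() - slope * (x - x.mean())
        se = np.sqrt((resid ** 2).sum() / (n - 2) / sxx)
        assert table.theta[0] == pytest.approx(slope, abs=1e-10)
        assert table.uncertainty[0] == pytest.approx(se, abs=1e-10)

    def test_uses_round_labels_not_indices(self):
        # same frequencies, wider label spacing -> proportionally smaller slope
        freqs = [(0.1, 0.9), (0.2, 0.8), (0.4, 0.6)]
        t_dense = ad.log_selectivity(dataset_from_frequencies(freqs, (0, 1, 2)))
        t_sparse = ad.log_selectivity(dataset_from_frequencies(freqs, (0, 2, 4)))
        assert t_sparse.theta[0] == pytest.approx(t_dense.theta[0] / 2, abs=1e-12)

    def test_invariant_to_count_rescaling(self):
        freqs = [(0.2, 0.8), (0.3, 0.7)]
        a = ad.log_selectivity(dataset_from_frequencies(freqs, (0, 1), total=100))
        b = ad.log_selectivity(dataset_from_frequencies(freqs, (0, 1), total=10 ** 5))
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-12)

    def test_ratio_method_on_two_rounds(self):
        ds = dataset_from_frequencies([(0.1, 0.9), (0.4, 0.6)], labels=(0, 2))
        table = ad.log_selectivity(ds, method="ratio")
        assert table.theta[0] == pytest.approx(np.log(4.0) / 2, abs=1e-12)
        assert (table.uncertainty == 0).all()

    def test_disjoint_rounds_give_empty_table(self, abc3):
        r0 = ad.SequenceRound(0, abc3.encode(["AA", "AC"]), np.array([5, 5]))
        r1 = ad.SequenceRound(1, abc3.encode(["CC", "CD"]), np.array([5, 5]))
        ds = ad.ScreeningDataset([r0, r1], abc3)
        assert len(ad.log_selectivity(ds)) == 0


class TestEnergySelectivityCorrelation:
    def _table_and_model(self, rng, n=200):
        E = make_random_energy(rng, 4, 3)
        seqs = np.unique(rng.integers(0, 3, size=(3 * n, 4)), axis=0)[:n]
        return E, seqs.astype(np.uint8)

    def test_perfect_affine_relation(self, rng):
        E, seqs = self._table_and_model(rng)
        theta = 2.0 * (-E.energy(seqs)) + 0.3
        table = SelectivityTable(seqs, theta, rng.uniform(0, 1, len(seqs)),
                                 np.full(len(seqs), 3))
        model = AnnealModel(E, PottsEnergy.zeros(4, 3), {0: 0.0, 1: 1.0})
        curve = ad.energy_selectivity_correlation(model, table)
        np.testing.assert_allclose(curve["pearson"], 1.0, atol=1e-12)

    def test_independent_noise_decorrelates(self, rng):
        E, seqs = self._table_and_model(rng, n=1000)
        table = SelectivityTable(seqs, rng.normal(size=len(seqs)),
                                 rng.uniform(0, 1, len(seqs)),
                                 np.full(len(seqs), 3))
        model = AnnealModel(E, PottsEnergy.zeros(4, 3), {0: 0.0, 1: 1.0})
        curve = ad.energy_selectivity_correlation(model, table, (1.0,))
        assert abs(curve["pearson"].iloc[0]) < 0.1

    def test_small_fractions_skipped(self, rng):
        E, seqs = self._table_and_model(rng, n=10)
        table = SelectivityTable(seqs, rng.normal(size=10),
                                 rng.uniform(0, 1, 10), np.full(10, 2))
        model = AnnealModel(E, PottsEnergy.zeros(4, 3), {0: 0.0, 1: 1.0})
        curve = ad.energy_selectivity_correlation(model, table, (0.1, 1.0))
        assert curve["retained_fraction"].tolist() == [1.0]


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = ad.roc_auc(np.array([-5.0, -4.0]), np.array([1.0, 2.0]))
        assert auc == 1.0

    def test_identical_multisets_give_half(self):
        scores = np.array([0.3, 1.0, 2.0])
        _, auc = ad.roc_auc(scores, scores.copy())
        assert auc == 0.5

    def test_worked_example_matches_pair_counting(self):
        pos, neg = np.array([-3.0, -1.0]), np.array([-2.0, 0.0])
        _, auc = ad.roc_auc(pos, neg, lower_is_positive=True)
        concordant = sum(
            1.0 if p < n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert auc == pytest.approx(concordant / 4) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(-1.0, 1.0, size=50)
        neg = rng.normal(0.5, 1.0, size=70)
        _, auc1 = ad.roc_auc(pos, neg)
        _, auc2 = ad.roc_auc(np.exp(pos), np.exp(neg))
        _, auc3 = ad.roc_auc(3 * pos + 7, 3 * neg + 7)
        assert auc1 == pytest.approx(auc2) == pytest.approx(auc3)

    def test_empty_group_rejected(self):
        with pytest.raises(ad.DataError):
            ad.roc_auc(np.array([]), np.array([1.0]))


class TestRankCorrelation:
    def test_monotone_transform_spearman(self, rng):
        e = rng.normal(size=20)
        assert ad.rank_correlation(e, np.exp(e), "spearman") == pytest.approx(1.0)
        assert ad.rank_correlation(e, -np.exp(e), "spearman") == pytest.approx(-1.0)

    def test_tied_measurements_average_ranks(self):
        e = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        m = np.array([5.0, 5.0, 7.0, 8.0, 9.0])
        # hand computation with average ranks: r = 9.5 / sqrt(10 * 9.5)
        assert ad.rank_correlation(e, m, "spearman") == pytest.approx(
            9.5 / np.sqrt(95.0), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ad.NumericError):
            ad.rank_correlation(np.ones(5), np.arange(5.0))


class TestPpvCurve:
    def _scores(self, pairs):
        n = len(pairs)
        return pd.DataFrame(
            {"i": [p[0] for p in pairs], "j": [p[1] for p in pairs],
             "score": np.linspace(1.0, 0.1, n)}
        )

    def test_all_predictions_true(self):
        pairs = [(0, 10), (1, 12), (2, 14)]
        ev = ad.ppv_curve(self._scores(pairs), set(pairs))
        np.testing.assert_allclose(ev.ppv, 1.0)

    def test_disjoint_predictions(self):
        ev = ad.ppv_curve(self._scores([(0, 10), (1, 12)]), {(3, 20)})
        np.testing.assert_allclose(ev.ppv, 0.0)

    def test_worked_counting_example(self):
        pairs = [(0, 10), (1, 11), (2, 12), (3, 13), (4, 14), (5, 15)]
        truth = {pairs[0], pairs[1], pairs[3]}
        ev = ad.ppv_curve(self._scores(pairs), truth)
        np.testing.assert_allclose(ev.ppv, [1, 1, 2 / 3, 3 / 4, 3 / 5, 1 / 2])

    def test_short_range_pairs_excluded(self):
        pairs = [(0, 2), (0, 10), (1, 3)]
        ev = ad.ppv_curve(self._scores(pairs), {(0, 2), (0, 10)}, min_separation=5)
        assert len(ev.ppv) == 1 and ev.ppv[0] == 1.0

    def test_hits_times_rank_is_integer_nondecreasing(self, rng):
        pairs = [(i, i + 7) for i in range(20)]
        truth = {p for p in pairs if rng.random() < 0.4}
        truth.add(pairs[0])
        ev = ad.ppv_curve(self._scores(pairs), truth)
        hits = ev.ppv * np.arange(1, len(ev.ppv) + 1)
        np.testing.assert_allclose(hits, np.round(hits), atol=1e-9)
        assert (np.diff(hits) >= -1e-9).all()

    def test_empty_truth_rejected(self):
        with pytest.raises(ad.DataError):
            ad.ppv_curve(self._scores([(0, 10)]), set())
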