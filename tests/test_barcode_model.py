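import numpy as np
import pandas as pd
import pytest

from hrfseq import barcode_model as bm

from conftest import make_fragment_table


def uniform_probs(L):
    return bm.BarcodeDistribution.uniform(L).probabilities()


class TestEstimatePositionFrequencies:
    def test_degenerate_pool(self):
        table = make_fragment_table(
            [("r", t, t + 100, "AAAAAAA", 1) for t in range(1, 5)]
        )
        dist = bm.estimate_position_frequencies(table, 7)
        assert np.allclose(dist.freq[:, 0], 1.0)
        assert np.allclose(dist.freq[:, 1:], 0.0)

    def test_uniform_draws_recover_quarter(self, rng):
        n = 100_000
        codes = rng.integers(0, 4, size=(n, 7))
        barcodes = ["".join(bm.BASES[c] for c in row) for row in codes]
        table = make_fragment_table(
            [("r", i + 1, i + 200, b, 1) for i, b in enumerate(barcodes)]
        )
        dist = bm.estimate_position_frequencies(table, 7)
        # oracle: direct tally (no fragment excluded since all counts equal)
        tally = np.zeros((7, 4))
        for j in range(7):
            for base_idx in range(4):
                tally[j, base_idx] = (codes[:, j] == base_idx).mean()
        assert np.allclose(dist.freq, tally)
        assert np.all(np.abs(dist.freq - 0.25) < 0.01)

    def test_top_quartile_fragment_excluded(self):
        # brute-force quartile on [1, 1000], linear interpolation: Q3 = 750.25
        assert np.percentile([1, 1000], 75) == pytest.approx(750.25)
        table = make_fragment_table(
            [("r", 1, 120, "AAAAAAA", 1), ("r", 2, 120, "CCCCCCC", 1000)]
        )
        dist = bm.estimate_position_frequencies(table, 7)
        assert dist.freq[0, 0] == 1.0  # only the AAAAAAA fragment survives

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            bm.estimate_position_frequencies(make_fragment_table([]), 7)

    def test_non_acgt_barcode_rejected_not_silent(self, caplog):
        table = make_fragment_table(
            [("r", 1, 120, "AAANAAA", 1), ("r", 2, 120, "CCCCCCC", 1)]
        )
        with caplog.at_level("INFO", logger="hrfseq.barcode_model"):
            dist = bm.estimate_position_frequencies(table, 7)
        assert dist.freq[0, 1] == 1.0  # only the clean barcode counted
        assert any("rejected 1" in rec.message for rec in caplog.records)

    def test_all_barcodes_invalid_raises(self):
        table = make_fragment_table([("r", 1, 120, "NNNNNNN", 1)])
        with pytest.raises(ValueError, match="no valid"):
            bm.estimate_position_frequencies(table, 7)


class TestBarcodeProbabilities:
    def test_uniform_L7(self):
        probs = uniform_probs(7)
        assert probs.size == 16384
        assert np.allclose(probs, 1 / 16384)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_length_one_identity(self):
        freq = np.array([[0.5, 0.3, 0.1, 0.1]])
        assert np.allclose(bm.barcode_probabilities(freq), [0.5, 0.3, 0.1, 0.1])

    def test_product_rule_L2(self):
        freq = np.array([[0.5, 0.5, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0]])
        probs = bm.barcode_probabilities(freq)
        assert probs[bm.barcode_index("AA")] == pytest.approx(0.5)
        assert probs[bm.barcode_index("CA")] == pytest.approx(0.5)
        assert probs.sum() == pytest.approx(1.0)
        assert np.count_nonzero(probs) == 2

    def test_refuses_huge_L(self):
        with pytest.raises(ValueError, match="reduce the barcode length"):
            bm.barcode_probabilities(np.full((13, 4), 0.25))

    def test_all_positive_when_freqs_positive(self, rng):
        freq = rng.dirichlet([5.0] * 4, size=3)
        assert np.all(bm.barcode_probabilities(freq) > 0)


class TestExpectedUniqueBarcodes:
    def test_forced_endpoints(self):
        probs = uniform_probs(7)
        assert bm.expected_unique_barcodes(0, probs) == pytest.approx(0.0)
        assert bm.expected_unique_barcodes(1, probs) == pytest.approx(1.0)

    def test_saturation_limit(self):
        probs = uniform_probs(7)
        assert bm.expected_unique_barcodes(10**7, probs) == pytest.approx(
            16384, rel=1e-6
        )

    def test_equal_frequency_reduction(self):
        m = 64
        probs = uniform_probs(3)
        for n in (10, 100, 1000):
            closed = m * (1 - (1 - 1 / m) ** n)
            assert bm.expected_unique_barcodes(n, probs) == pytest.approx(closed)

    def test_negative_n_raises(self):
        with pytest.raises(ValueError):
            bm.expected_unique_barcodes(-1, uniform_probs(2))

    def test_monte_carlo_oracle_equal_L3(self, rng):
        # ligation simulation: multinomial occupancy, 1e5 replicates
        probs = uniform_probs(3)
        n = 100
        counts = rng.multinomial(n, probs, size=100_000)
        k_samples = (counts > 0).sum(axis=1)
        se = k_samples.std(ddof=1) / np.sqrt(len(k_samples))
        assert abs(bm.expected_unique_barcodes(n, probs) - k_samples.mean()) < 3 * se

    @pytest.mark.parametrize("L", [2, 3])
    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_monte_carlo_oracle_unequal(self, L, n):
        rng = np.random.default_rng(500 + 10 * L + n)
        freq = rng.dirichlet([8.0] * 4, size=L)
        probs = bm.barcode_probabilities(freq)
        counts = rng.multinomial(n, probs, size=100_000)
        k_samples = (counts > 0).sum(axis=1)
        se = k_samples.std(ddof=1) / np.sqrt(len(k_samples))
        expected = bm.expected_unique_barcodes(n, probs)
        assert abs(expected - k_samples.mean()) < max(3 * se, 1e-6)

    def test_strictly_increasing_and_concave(self, rng):
        freq = rng.dirichlet([6.0] * 4, size=3)
        probs = bm.barcode_probabilities(freq)
        grid = np.arange(0, 2000)
        k = bm.expected_unique_barcodes(grid, probs)
        diffs = np.diff(k)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 1e-12)  # decreasing finite differences


@pytest.fixture(scope="module")
def table16384():
    return bm.build_euc_table(uniform_probs(7))


class TestEucTable:
    def test_k1_maps_to_1(self, rng):
        freq = rng.dirichlet([4.0] * 4, size=2)
        table = bm.build_euc_table(bm.barcode_probabilities(freq), n_max=5000)
        assert table.lookup(1) == 1

    def test_identity_far_from_saturation(self, table16384):
        assert table16384.lookup(5) == 5

    def test_strong_correction_near_saturation(self, table16384):
        # saturation sets in around sqrt(m) = 128; 8000 is far beyond
        assert table16384.lookup(8000) > 8000 * 1.3

    def test_k_of_n_increasing_bounded(self, table16384):
        assert np.all(np.diff(table16384.k_of_n) > 0)
        assert table16384.k_of_n[-1] <= table16384.m

    def test_n_of_k_non_decreasing_and_geq_k(self, table16384):
        n_of_k = table16384.n_of_k
        assert np.all(np.diff(n_of_k) >= 0)
        assert np.all(n_of_k >= np.arange(len(n_of_k)))

    def test_saturated_k_raises_with_limit(self, table16384):
        with pytest.raises(bm.SaturatedBarcodeError, match=str(table16384.k_max)):
            table16384.lookup(table16384.k_max + 1)

    def test_round_trip_small_n(self, table16384):
        m = table16384.m
        for n in range(1, int(0.5 * np.sqrt(m))):
            k = int(round(table16384.k_of_n[n - 1]))
            assert table16384.lookup(k) in (n - 1, n, n + 1)

    def test_inversion_ties_prefer_smaller_n(self):
        # k(n) spacing < 1 near saturation forces ties; just assert monotone map
        probs = uniform_probs(2)
        table = bm.build_euc_table(probs, n_max=500)
        assert np.all(np.diff(table.n_of_k) >= 0)


class TestEstimateUniqueCount:
    def test_zero_and_one(self):
        table = bm.build_euc_table(uniform_probs(7), n_max=100)
        assert bm.estimate_unique_count(0, table) == 0
        assert bm.estimate_unique_count(1, table) == 1

    def test_recovers_true_n_500(self):
        # simulate ligation of 500 molecules, average recovery within 5%
        probs = uniform_probs(7)
        table = bm.build_euc_table(probs)
        rng = np.random.default_rng(77)
        eucs = []
        for _ in range(100):
            k = int((rng.multinomial(500, probs) > 0).sum())
            eucs.append(table.lookup(k))
        assert abs(np.mean(eucs) - 500) / 500 < 0.05

    def test_euc_removes_pcr_duplication_bias(self):
        # identical true n, duplication factors 1..50: EUC flattens read counts
        rng = np.random.default_rng(99)
        probs = uniform_probs(7)
        table = bm.build_euc_table(probs)
        true_n = 100  # unsaturated (< sqrt(16384))
        read_counts, eucs = [], []
        for _ in range(200):
            k = int((rng.multinomial(true_n, probs) > 0).sum())
            dup = rng.integers(1, 51)
            read_counts.append(true_n * dup)
            eucs.append(table.lookup(k))
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(read_counts) > 0.5
        assert cv(eucs) < 0.1

    def test_attach_euc_column(self):
        table = bm.build_euc_table(uniform_probs(7), n_max=1000)
        agg = pd.DataFrame(
            {
                "rna_id": ["r", "r"],
                "termination_pos": [1, 5],
                "priming_pos": [120, 130],
                "read_count": [10, 3],
                "k": [4, 0],
            }
        )
        out = bm.attach_euc(agg, table)
        assert list(out["euc"]) == [4, 0]


class TestBarcodeDistributionInvariants:
    def test_rows_must_sum_to_one(self):
        bad = np.full((3, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            bm.BarcodeDistribution(bad)

    def test_probs_sum_to_one(self, rng):
        freq = rng.dirichlet([3.0] * 4, size=5)
        dist = bm.BarcodeDistribution(freq)
        assert dist.probabilities().sum() == pytest.approx(1.0, abs=1e-9)

    def test_frame_layout(self):
        frame = bm.BarcodeDistribution.uniform(7).to_frame()
        assert frame.shape == (7, 4)
        assert list(frame.columns) == ["A", "C", "G", "T"]
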