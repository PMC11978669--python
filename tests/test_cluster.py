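import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from hfodetect import cluster as cl
from hfodetect.ste import CandidateEvent


def make_event(signal, fs=2560.0, channel=0):
    x = np.asarray(signal, dtype=float)
    return CandidateEvent(channel=channel, center_sample=0, raw_window=x,
                          filtered_window=x, fs_hz=fs)


def tone(freq, fs=2560.0, n=384, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


def two_clouds(n=40, d=5, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, d))
    b = rng.normal(sep, 1, (n, d))
    return np.vstack([a, b]), np.r_[np.zeros(n, int), np.ones(n, int)]


class TestVectorize:
    def test_column_major_definition(self):
        np.testing.assert_array_equal(cl.vectorize(np.array([[1, 2], [3, 4]])),
                                      [1, 3, 2, 4])

    def test_zero_image_length(self):
        assert cl.vectorize(np.zeros((64, 64))).shape == (4096,)

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        v = cl.vectorize(img)
        np.testing.assert_array_equal(v.reshape(64, 64, order="F"), img)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            cl.vectorize(np.zeros(64))


class TestKMeans:
    def test_separated_clouds_recovered_exactly(self):
        X, y = two_clouds()
        res = cl.kmeans_cluster(X, K=2, seed=0)
        agree = max(np.mean(res.labels == y), np.mean(res.labels == 1 - y))
        assert agree == 1.0

    def test_single_cluster_is_data_mean(self):
        X, _ = two_clouds()
        res = cl.kmeans_cluster(X, K=1, seed=0)
        assert np.all(res.labels == 0)
        np.testing.assert_allclose(res.centers[0], X.mean(0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cl.kmeans_cluster(np.zeros((3, 2)), K=4)


class TestFCM:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hst.integers(0, 10_000))
    def test_memberships_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(5, 40), rng.integers(2, 6)))
        res = cl.fcm_cluster(X, K=3, seed=0, max_iter=40)
        np.testing.assert_allclose(res.memberships.sum(1), 1.0, atol=1e-9)
        assert np.all(res.memberships >= 0)

    def test_agrees_with_kmeans_on_separated_data(self):
        X, y = two_clouds()
        km = cl.kmeans_cluster(X, K=2, seed=0).labels
        fc = cl.fcm_cluster(X, K=2, seed=0).labels
        agree = max(np.mean(km == fc), np.mean(km == 1 - fc))
        assert agree == 1.0

    def test_equidistant_sample_has_half_memberships(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0], [0.1, 0.0], [9.9, 0.0],
                      [5.0, 0.0]])
        res = cl.fcm_cluster(X, K=2, m=2.0, seed=0)
        np.testing.assert_allclose(res.memberships[-1], [0.5, 0.5], atol=1e-3)

    def test_fuzziness_near_one_approaches_hard_partition(self):
        X, y = two_clouds()
        res = cl.fcm_cluster(X, K=2, m=1.05, seed=0)
        hard = res.memberships.max(1)
        assert hard.min() > 0.999

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        res = cl.fcm_cluster(X, K=2, seed=0)
        np.testing.assert_allclose(res.memberships.max(1), 1.0)


class TestGMMAndMeanShift:
    def test_gmm_responsibilities_on_separated_gaussians(self):
        X, y = two_clouds(sep=30.0)
        res = cl.gmm_cluster(X, K=2, seed=0)
        assert np.all(res.memberships.max(1) >= 0.99)
        np.testing.assert_allclose(res.memberships.sum(1), 1.0, atol=1e-9)

    def test_meanshift_huge_bandwidth_single_cluster(self):
        X, _ = two_clouds(sep=5.0)
        res = cl.meanshift_cluster(X, bandwidth=1e4, seed=0)
        assert res.K == 1

    def test_meanshift_mode_merging_caps_cluster_count(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(c, 0.1, (15, 2)) for c in range(6)])
        res = cl.meanshift_cluster(X, bandwidth=0.3, seed=0, reduce_to=4)
        assert res.K <= 4


class TestSpectralCentroid:
    def test_dc_signal_centroid_at_origin(self):
        # the Hamming window leaks a little energy into the first bins, so the
        # centroid of a DC signal sits just above 0, well inside one bin
        bin_hz = 2560.0 / 384
        assert cl.spectral_centroid(np.ones(384), 2560) < bin_hz

    def test_all_zero_signal_convention(self):
        assert cl.spectral_centroid(np.zeros(384), 2560) == 0.0

    @pytest.mark.parametrize("freq", [100.0, 150.0, 250.0, 400.0])
    def test_pure_tone_within_one_bin(self, freq):
        bin_hz = 2560.0 / 384
        assert cl.spectral_centroid(tone(freq), 2560) == pytest.approx(freq, abs=bin_hz)

    def test_equal_power_tones_average(self):
        x = tone(100.0) + tone(400.0)
        bin_hz = 2560.0 / 384
        assert cl.spectral_centroid(x, 2560) == pytest.approx(250.0, abs=bin_hz)

    @pytest.mark.parametrize("amp", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, amp):
        base = cl.spectral_centroid(tone(150.0), 2560)
        assert cl.spectral_centroid(tone(150.0, amp=amp), 2560) == pytest.approx(base)


class TestAssignClasses:
    def build(self, sc_per_cluster, sizes):
        labels, events = [], []
        for c, (freq, size) in enumerate(zip(sc_per_cluster, sizes)):
            for _ in range(size):
                labels.append(c)
                events.append(make_event(tone(freq)))
        labels = np.asarray(labels)
        res = cl.ClusterResult(labels=labels, memberships=np.eye(len(sc_per_cluster))[labels],
                               K=len(sc_per_cluster))
        return res, events

    def test_descending_sc_rank_rule(self):
        res, events = self.build([400.0, 150.0, 60.0, 30.0], [5, 5, 5, 5])
        res = cl.assign_classes(res, events)
        assert res.class_map == {0: "fast_ripple", 1: "ripple", 2: "spike",
                                 3: "artifact"}
        assert res.is_hfo().sum() == 10

    def test_tie_broken_by_cluster_size(self):
        res, events = self.build([100.0, 100.0, 100.0, 100.0], [8, 6, 4, 2])
        with pytest.warns(UserWarning, match="same mean SC"):
            res = cl.assign_classes(res, events)
        assert res.class_map == {0: "fast_ripple", 1: "ripple", 2: "spike",
                                 3: "artifact"}

    def test_empty_cluster_mapped_to_artifact(self):
        res, events = self.build([400.0, 150.0, 60.0], [5, 5, 5])
        res.K = 4  # declared four clusters, one received no samples
        res.memberships = np.pad(res.memberships, ((0, 0), (0, 1)))
        with pytest.warns(UserWarning, match="empty"):
            res = cl.assign_classes(res, events)
        assert res.class_map[3] == "artifact"
        assert res.class_map[0] == "fast_ripple"

    def test_label_permutation_invariance_of_binary_flags(self):
        res, events = self.build([400.0, 150.0, 60.0, 30.0], [4, 4, 4, 4])
        res = cl.assign_classes(res, events)
        perm = np.array([2, 3, 0, 1])
        res2 = cl.ClusterResult(labels=perm[res.labels],
                                memberships=res.memberships[:, np.argsort(perm)],
                                K=4)
        res2 = cl.assign_classes(res2, events)
        np.testing.assert_array_equal(res.is_hfo(), res2.is_hfo())
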