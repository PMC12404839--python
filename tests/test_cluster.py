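"""Segment clustering, prototypes and differential zerotree encoding."""

import itertools

import numpy as np
import pytest

from ezweeg import ezw
from ezweeg.cluster import (
    ClusterModel,
    angle_similarity,
    cluster_segments,
    correlation_coefficient,
    differential_decode,
    differential_encode,
)
from ezweeg.signal_io import Segment


def _segments_from_rows(rows):
    return [Segment(r, segment_index=i + 1) for i, r in enumerate(rows)]


class TestSimilarityMeasures:
    def test_correlation_identity_and_negation(self, rng):
        v = rng.standard_normal(64)
        assert correlation_coefficient(v, v) == pytest.approx(1.0)
        assert correlation_coefficient(v, -v) == pytest.approx(-1.0)

    def test_correlation_hand_value(self):
        assert correlation_coefficient([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_correlation_constant_rejected(self):
        with pytest.raises(ValueError):
            correlation_coefficient([1, 1, 1], [1, 2, 3])

    def test_angle_examples(self):
        assert angle_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0, abs=1e-6)
        assert angle_similarity([1, 0], [0, 1]) == pytest.approx(np.pi / 2)
        assert angle_similarity([1, 1], [1, 0]) == pytest.approx(np.pi / 4)

    def test_angle_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_similarity([0, 0], [1, 0])


class TestKMeans:
    def test_single_cluster_prototype_near_grand_mean(self, rng):
        rows = rng.standard_normal((7, 16))
        model = cluster_segments(_segments_from_rows(rows), 1, seed=0)
        assert model.assignments.tolist() == [1] * 7
        grand = rows.mean(axis=0)
        expected = int(np.argmin(np.linalg.norm(rows - grand, axis=1)))
        assert model.prototypes[1] == expected

    def test_two_well_separated_groups_recovered(self, rng):
        rows = np.vstack([rng.standard_normal((3, 8)), rng.standard_normal((3, 8)) + 100.0])
        segs = _segments_from_rows(rows)
        model = cluster_segments(segs, 2, seed=1)
        # brute-force optimum over all 2-partitions of 6 segments
        best, best_obj = None, np.inf
        for labels in itertools.product([0, 1], repeat=6):
            if len(set(labels)) < 2:
                continue
            obj = sum(
                np.sum((rows[np.array(labels) == g] - rows[np.array(labels) == g].mean(0)) ** 2)
                for g in (0, 1)
            )
            if obj < best_obj:
                best, best_obj = labels, obj
        got = model.assignments
        same = [best[i] == best[0] for i in range(6)]
        got_same = [got[i] == got[0] for i in range(6)]
        assert same == got_same

    def test_identical_segments_well_defined(self, rng):
        rows = np.tile(rng.standard_normal(8), (5, 1))
        model = cluster_segments(_segments_from_rows(rows), 2, seed=0)
        np.testing.assert_allclose(model.centroids[0], model.centroids[1])
        assert all(p in range(5) for p in model.prototypes.values())

    def test_objective_nonincreasing(self, rng):
        rows = rng.standard_normal((30, 12))
        model = cluster_segments(_segments_from_rows(rows), 4, seed=3)
        h = model.objective_history
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))

    def test_matches_sklearn_objective(self, rng):
        from sklearn.cluster import KMeans

        rows = rng.standard_normal((40, 6))
        model = cluster_segments(_segments_from_rows(rows), 3, seed=0)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(rows)
        assert model.objective_history[-1] <= sk.inertia_ * 1.05

    def test_angle_metric(self, rng):
        base = np.abs(rng.standard_normal(8)) + 0.5
        rows = np.vstack([base * s for s in (1.0, 2.0, 5.0)] + [-base * s for s in (1.0, 3.0)])
        model = cluster_segments(_segments_from_rows(rows), 2, metric="angle", seed=0)
        a = model.assignments
        assert a[0] == a[1] == a[2] and a[3] == a[4] and a[0] != a[3]

    def test_more_clusters_than_segments_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_segments(_segments_from_rows(rng.standard_normal((2, 4))), 3)


class TestDifferentialCoding:
    def _model(self, rows, p=2, **kw):
        return cluster_segments(_segments_from_rows(rows), p, seed=0, **kw)

    def test_prototype_equal_segment_is_header_only(self, rng):
        rows = np.round(rng.standard_normal((4, 64)) * 10)
        model = self._model(rows, 2)
        proto = model.prototype_values[1]
        stream = differential_encode(Segment(proto), model, quant_step=1.0)
        assert stream.cluster_preamble == 1
        assert stream.t0 == 0 and stream.passes == []
        back = differential_decode(stream, model)
        np.testing.assert_allclose(back.values, proto, atol=1e-9)

    def test_clustered_round_trip_lossless(self, rng):
        rows = np.round(rng.standard_normal((6, 64)) * 20)
        model = self._model(rows, 2)
        for r in rows:
            stream = differential_encode(Segment(r), model, quant_step=1.0 / 64)
            back = differential_decode(stream, model)
            np.testing.assert_allclose(back.values, r, atol=1.0 / 64)

    def test_unclustered_equals_plain_encoding(self, rng):
        rows = np.round(rng.standard_normal((4, 64)) * 10)
        model = self._model(rows, 2, raw_threshold=1e-9)
        far = np.round(rng.standard_normal(64) * 10) + 500.0
        stream = differential_encode(Segment(far), model, quant_step=1.0)
        assert stream.cluster_preamble == ezw.RAW_PREAMBLE
        from ezweeg.wavelet import dwt_multilevel, quantize_coeffs

        plain = ezw.encode(quantize_coeffs(dwt_multilevel(far, 3, "db4"), 1.0))
        assert stream.total_bits == plain.total_bits + ezw.PREAMBLE_BITS
        back = differential_decode(stream, model)
        np.testing.assert_allclose(back.values, far, atol=1.0)

    def test_unknown_cluster_id_rejected(self, rng):
        rows = np.round(rng.standard_normal((4, 64)) * 10)
        model = self._model(rows, 2)
        stream = differential_encode(Segment(rows[0]), model, quant_step=1.0)
        stream.cluster_preamble = 99
        with pytest.raises(KeyError):
            differential_decode(stream, model)

    def test_tight_clusters_save_bits(self, rng):
        """Residual coding beats independent coding on prototype + small noise."""
        wins = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            protos = g.standard_normal((2, 128)) * 10
            rows = np.vstack(
                [protos[i % 2] + 0.05 * g.standard_normal(128) for i in range(8)]
            )
            segs = _segments_from_rows(rows)
            model = cluster_segments(segs, 2, seed=0)
            q = 1.0 / 16
            diff_bits = sum(
                differential_encode(s, model, quant_step=q).total_bits for s in segs
            )
            from ezweeg.wavelet import dwt_multilevel, quantize_coeffs

            indep_bits = sum(
                ezw.encode(quantize_coeffs(dwt_multilevel(s.values, 3, "db4"), q)).total_bits
                for s in segs
            )
            wins += diff_bits <= indep_bits
        assert wins >= 9


class TestModelSidecar:
    def test_save_load_round_trip(self, tmp_path, rng):
        rows = rng.standard_normal((5, 32))
        model = cluster_segments(_segments_from_rows(rows), 2, seed=0, raw_threshold=4.5)
        p = tmp_path / "model.tsv"
        model.save(p)
        back = ClusterModel.load(p)
        assert back.metric == "euclidean"
        assert back.raw_threshold == pytest.approx(4.5)
        for cid in model.prototype_values:
            np.testing.assert_array_equal(back.prototype_values[cid], model.prototype_values[cid])
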