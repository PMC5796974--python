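"""Matrix machinery: counting, RPKM, quantile normalization, correlation, clustering."""

import numpy as np
import pandas as pd
import pytest

from hormonesig.errors import ConfigError, DataError
from hormonesig.intervals import GenomicInterval, IntervalSet
from hormonesig.matrix import (
    FeatureMatrix,
    build_union_features,
    correlation,
    count_reads,
    feature_ids,
    hcluster,
    quantile_normalize,
    rpkm,
)

from conftest import random_interval_set


def make_matrix(values, samples=None, lengths=None, kind="counts"):
    values = np.asarray(values, dtype=float)
    features = [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=features, columns=samples)
    lengths = pd.Series(lengths if lengths is not None else 1000.0, index=features)
    return FeatureMatrix(data, lengths, kind=kind)


class TestUnionFeatures:
    def test_single_and_disjoint_additivity(self):
        a = IntervalSet([GenomicInterval("c", i * 100, i * 100 + 50) for i in range(10)])
        b = IntervalSet([GenomicInterval("c2", i * 100, i * 100 + 50) for i in range(10)])
        assert len(build_union_features([a])) == 10
        assert len(build_union_features([a, b])) == 20

    def test_overlapping_sets_match_merge_oracle(self, rng):
        from hormonesig.intervals import merge

        a = random_interval_set(rng, 200)
        b = random_interval_set(rng, 200)
        union = build_union_features([a, b])
        assert len(union) == len(merge(IntervalSet(list(a) + list(b))))


class TestCountReads:
    def test_half_open_boundary(self):
        feats = IntervalSet([GenomicInterval("c", 0, 100)])
        tracks = {"s1": [("c", 0), ("c", 99), ("c", 100)]}
        fm = count_reads(feats, tracks)
        assert fm.data.iloc[0, 0] == 2

    def test_empty_track_gives_zero_column(self):
        feats = IntervalSet([GenomicInterval("c", 0, 100)])
        fm = count_reads(feats, {"s1": [], "s2": [("c", 5)]})
        assert fm.data["s1"].sum() == 0 and fm.data["s2"].sum() == 1

    def test_matches_linear_scan_oracle(self, rng):
        feats = random_interval_set(rng, 50)
        from hormonesig.intervals import merge

        merged = merge(feats)
        reads = [("chr1", int(p)) for p in rng.integers(0, 11_000, size=2000)]
        reads += [("chr2", int(p)) for p in rng.integers(0, 11_000, size=2000)]
        fm = count_reads(feats, {"s1": reads})
        oracle = np.zeros(len(merged))
        for chrom, pos in reads:
            for i, iv in enumerate(merged):
                if iv.chrom == chrom and iv.start <= pos < iv.end:
                    oracle[i] += 1
        assert np.array_equal(fm.data["s1"].to_numpy(), oracle)

    def test_read_beyond_chromosome_end_raises(self):
        feats = IntervalSet([GenomicInterval("c", 0, 100)])
        with pytest.raises(DataError, match="beyond"):
            count_reads(feats, {"s1": [("c", 500)]}, chrom_lengths={"c": 200})


class TestRpkm:
    def test_forced_by_formula(self):
        fm = make_matrix([[10.0]], lengths=[1000.0])
        out = rpkm(fm, {"s0": 1e6})
        assert out.data.iloc[0, 0] == pytest.approx(10.0)
        assert out.kind == "rpkm"

    def test_library_rescaling_symmetry(self, rng):
        fm = make_matrix(rng.integers(0, 100, size=(50, 3)))
        sizes = {"s0": 1e6, "s1": 2e6, "s2": 5e5}
        doubled = {k: 2 * v for k, v in sizes.items()}
        assert np.allclose(rpkm(fm, doubled).data, rpkm(fm, sizes).data / 2)

    def test_matches_per_cell_oracle(self, rng):
        values = rng.integers(0, 500, size=(30, 4)).astype(float)
        lengths = rng.integers(100, 5000, size=30).astype(float)
        fm = make_matrix(values, lengths=lengths)
        sizes = {f"s{j}": float(rng.integers(1e5, 1e7)) for j in range(4)}
        out = rpkm(fm, sizes)
        for i in range(30):
            for j in range(4):
                expected = values[i, j] * 1e9 / (lengths[i] * sizes[f"s{j}"])
                assert out.data.iloc[i, j] == pytest.approx(expected)

    def test_zero_library_size_rejected(self):
        fm = make_matrix([[1.0]])
        with pytest.raises(DataError):
            rpkm(fm, {"s0": 0.0})


class TestQuantileNormalize:
    def test_hand_evaluated_example(self):
        fm = make_matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalize(fm)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.data.to_numpy(), expected)

    def test_identical_columns_are_fixed_point(self):
        fm = make_matrix([[3, 3], [1, 1], [7, 7]])
        out = quantile_normalize(fm)
        assert np.allclose(out.data.to_numpy(), fm.data.to_numpy())

    def test_columns_share_sorted_values_and_idempotent(self, rng):
        fm = make_matrix(rng.random((40, 5)) * 100)
        out = quantile_normalize(fm)
        reference = np.sort(out.data.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(out.data.iloc[:, j].to_numpy()), reference)
        again = quantile_normalize(FeatureMatrix(out.data, out.lengths, "counts"))
        assert np.allclose(again.data.to_numpy(), out.data.to_numpy())

    def test_ties_get_mean_of_spanned_reference(self):
        # column 0 has a 3-way tie spanning reference ranks 0..2
        fm = make_matrix([[5, 1], [5, 2], [5, 3], [9, 4]])
        out = quantile_normalize(fm)
        ref = np.sort(np.array([[5, 5, 5, 9], [1, 2, 3, 4]]).T, axis=0).mean(axis=1)
        assert np.allclose(out.data.iloc[:3, 0], ref[:3].mean())
        assert out.data.iloc[3, 0] == pytest.approx(ref[3])


class TestCorrelation:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10.0)
        fm = make_matrix(np.column_stack([x, x[::-1]]))
        corr = correlation(fm)
        assert corr.data.iloc[0, 0] == pytest.approx(1.0)
        assert corr.data.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self, rng):
        X = rng.random((30, 4))
        corr = correlation(make_matrix(X)).data.to_numpy()
        for i in range(4):
            for j in range(4):
                xi, xj = X[:, i], X[:, j]
                num = np.mean((xi - xi.mean()) * (xj - xj.mean()))
                expected = num / (xi.std() * xj.std())
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal_psd(self, rng):
        corr = correlation(make_matrix(rng.random((100, 6)))).data.to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.linalg.eigvalsh(corr).min() > -1e-8

    def test_zero_variance_sample_flagged(self):
        fm = make_matrix([[1, 5], [2, 5], [3, 5]])
        corr = correlation(fm)
        assert corr.degenerate_samples == ["s1"]
        assert np.isnan(corr.data.iloc[0, 1])


class TestHCluster:
    def test_planted_two_group_recovery(self):
        rng = np.random.default_rng(0)
        base = rng.random(200) * 50 + 10
        groups = {}
        for label, shift in (("a", 0.0), ("b", 25.0)):
            for r in range(4):
                col = base + (shift if label == "b" else 0) * (np.arange(200) % 2)
                groups[f"{label}{r}"] = np.maximum(col + rng.normal(0, 1, 200), 0.0)
        fm = make_matrix(np.column_stack(list(groups.values())), samples=list(groups))
        result = hcluster(correlation(fm), k=2)
        labels_a = {result.labels[s] for s in groups if s.startswith("a")}
        labels_b = {result.labels[s] for s in groups if s.startswith("b")}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_two_samples_two_clusters(self, rng):
        fm = make_matrix(rng.random((20, 2)))
        result = hcluster(correlation(fm), k=2)
        assert sorted(result.labels.values()) == [1, 2]

    def test_duplicate_samples_merge_at_height_zero(self, rng):
        x = rng.random(30)
        fm = make_matrix(np.column_stack([x, x, rng.random(30)]))
        result = hcluster(correlation(fm), k=2)
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert result.labels["s0"] == result.labels["s1"]

    def test_k_out_of_range(self, rng):
        corr = correlation(make_matrix(rng.random((10, 3))))
        with pytest.raises(ConfigError):
            hcluster(corr, k=1)
        with pytest.raises(ConfigError):
            hcluster(corr, k=4)

    def test_label_order_invariance(self, rng):
        X = rng.random((50, 5))
        samples = ["s3", "s1", "s4", "s0", "s2"]
        fm1 = make_matrix(X, samples=samples)
        fm2 = make_matrix(X[:, ::-1], samples=samples[::-1])
        r1 = hcluster(correlation(fm1), k=2)
        r2 = hcluster(correlation(fm2), k=2)
        assert r1.labels == r2.labels


def test_matrix_tsv_round_trip(tmp_path, rng):
    fm = make_matrix(rng.integers(0, 50, size=(20, 3)).astype(float))
    p = tmp_path / "m.tsv"
    fm.to_tsv(p)
    back = FeatureMatrix.from_tsv(p)
    assert np.allclose(back.data.to_numpy(), fm.data.to_numpy())
    assert list(back.data.columns) == fm.samples
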