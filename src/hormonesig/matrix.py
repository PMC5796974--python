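"""Count-matrix machinery: union features, read counting, RPKM, quantile
normalization, sample-sample correlation and hierarchical clustering.

Mirrors the standard ChIP-seq / RNA-seq downstream workflow: build the union
of peaks as the feature set, count reads per feature per sample, normalize to
reads per kilobase per million (RPKM), quantile-normalize across samples,
then cluster samples on Pearson correlation with average linkage on 1 - r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError, DataError
from .intervals import GenomicInterval, IntervalSet, merge

VALUE_KINDS = ("counts", "rpkm", "quantile")


@dataclass
class FeatureMatrix:
    """Features x samples numeric matrix with feature lengths.

    ``data`` holds features as rows and samples as columns; ``lengths`` the
    feature lengths in bp (used by RPKM); ``kind`` tracks the normalization
    state and may only move counts -> rpkm -> quantile.
    """

    data: pd.DataFrame
    lengths: pd.Series
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ConfigError(f"unknown value kind {self.kind!r}")
        self.lengths = self.lengths.reindex(self.data.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:3].tolist()
            raise DataError(f"missing feature lengths, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise DataError("feature lengths must be positive")
        if (self.data.to_numpy() < 0).any():
            raise DataError("matrix values must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, kind: str = "counts") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        if "length" not in df.columns:
            raise DataError("feature matrix TSV must carry a 'length' column")
        lengths = df.pop("length")
        return cls(df, lengths, kind)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise sample Pearson correlations."""

    data: pd.DataFrame
    degenerate_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ClusteringResult:
    """Average-linkage tree over samples plus a flat cut at k groups."""

    linkage: np.ndarray          # scipy linkage matrix over sorted samples
    sample_order: list[str]      # lexicographic order fed to linkage
    leaf_order: list[str]        # dendrogram leaf order
    labels: dict[str, int]       # sample -> flat cluster id (1..k)
    k: int

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "merges": [
                {"left": int(a), "right": int(b), "height": float(h), "size": int(n)}
                for a, b, h, n in self.linkage
            ],
            "sample_order": self.sample_order,
            "leaf_order": self.leaf_order,
            "labels": self.labels,
        }


def build_union_features(cistromes: Iterable[IntervalSet]) -> IntervalSet:
    """Merge the concatenation of peak sets into the union feature set."""
    cistromes = list(cistromes)
    if not cistromes:
        raise ConfigError("need at least one interval set")
    pooled = [iv for cs in cistromes for iv in cs]
    return merge(IntervalSet(pooled, label="union"))


def feature_ids(features: IntervalSet) -> list[str]:
    return [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in features]


def count_reads(
    features: IntervalSet,
    tracks: Mapping[str, Sequence[tuple[str, int]]],
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> FeatureMatrix:
    """Count single-position reads falling in each half-open feature.

    ``tracks`` maps sample label -> iterable of (chrom, position) reads.
    Features are merged first so each read lands in at most one feature.
    """
    feats = merge(features)
    ids = feature_ids(feats)
    lengths = pd.Series([iv.length for iv in feats], index=ids, dtype=float)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for row, iv in enumerate(feats):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, row))
    starts = {c: np.array([t[0] for t in v]) for c, v in by_chrom.items()}
    ends = {c: np.array([t[1] for t in v]) for c, v in by_chrom.items()}
    rows = {c: np.array([t[2] for t in v]) for c, v in by_chrom.items()}

    counts = np.zeros((len(ids), len(tracks)), dtype=float)
    for col, (sample, reads) in enumerate(tracks.items()):
        for chrom, pos in reads:
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise DataError(f"read on unknown chromosome {chrom!r}")
                if not 0 <= pos < chrom_lengths[chrom]:
                    raise DataError(
                        f"read at {chrom}:{pos} beyond chromosome end "
                        f"({chrom_lengths[chrom]} bp)"
                    )
            if chrom not in starts:
                continue
            idx = np.searchsorted(starts[chrom], pos, side="right") - 1
            if idx >= 0 and pos < ends[chrom][idx]:
                counts[rows[chrom][idx], col] += 1
    data = pd.DataFrame(counts, index=ids, columns=list(tracks.keys()))
    return FeatureMatrix(data, lengths, kind="counts")


def rpkm(matrix: FeatureMatrix, library_sizes: Mapping[str, float]) -> FeatureMatrix:
    """Reads per kilobase of feature per million mapped reads.

    value[f, s] = raw[f, s] * 1e9 / (length_bp[f] * library_size[s]).
    """
    if matrix.kind != "counts":
        raise ConfigError(f"RPKM expects raw counts, got kind={matrix.kind!r}")
    sizes = pd.Series(library_sizes).reindex(matrix.samples)
    if sizes.isna().any():
        raise DataError("library size missing for some samples")
    if (sizes <= 0).any():
        raise DataError("library sizes must be positive")
    values = matrix.data * 1e9
    values = values.div(matrix.lengths, axis=0).div(sizes, axis=1)
    return FeatureMatrix(values, matrix.lengths, kind="rpkm")


def quantile_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the vector of row means of the column-sorted matrix;
    tied values within a column receive the mean of the reference values
    their tied ranks span.
    """
    X = matrix.data.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        warnings.warn("quantile normalization with a single sample is a no-op")
        return FeatureMatrix(matrix.data.copy(), matrix.lengths, kind="quantile")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n_feat)
        i = 0
        while i < n_feat:
            k = i
            while k + 1 < n_feat and col[order[k + 1]] == col[order[i]]:
                k += 1
            ranked[order[i : k + 1]] = reference[i : k + 1].mean()
            i = k + 1
        out[:, j] = ranked
    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return FeatureMatrix(data, matrix.lengths, kind="quantile")


def correlation(matrix: FeatureMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlation between samples over all features.

    Zero-variance samples produce NaN entries and are reported in
    ``degenerate_samples`` rather than silently coerced.
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DataError("need >= 2 features to correlate samples")
    sds = X.std(axis=0)
    degenerate = [s for s, sd in zip(matrix.samples, sds) if sd == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    data = pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)
    return CorrelationMatrix(data, degenerate)


def hcluster(corr: CorrelationMatrix, k: int) -> ClusteringResult:
    """Agglomerative average-linkage clustering on distance 1 - r.

    Samples are ordered lexicographically before linkage so equal-distance
    merges break ties deterministically by label.
    """
    n = len(corr.samples)
    if not 2 <= k <= n:
        raise ConfigError(f"k must be in [2, {n}], got {k}")
    if corr.data.isna().any().any():
        raise DataError(
            "correlation matrix has undefined entries "
            f"(degenerate samples: {corr.degenerate_samples})"
        )
    order = sorted(corr.samples)
    dist = 1.0 - corr.data.loc[order, order].to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(Z)
    return ClusteringResult(
        linkage=Z,
        sample_order=order,
        leaf_order=[order[i] for i in leaves],
        labels={s: int(c) for s, c in zip(order, flat)},
        k=k,
    )
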