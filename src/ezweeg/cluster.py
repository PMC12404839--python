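"""Segment clustering and differential (residual) zerotree encoding.

Similar segments are grouped with K-means; each cluster's prototype is the
member segment closest to the centroid.  A segment assigned to cluster ``p``
is coded as the EZW stream of its *residual* against the prototype, with the
cluster id in an 8-bit preamble; a segment too far from every centroid stays
unclustered and is coded raw behind a reserved preamble marker.  Tighter
clusters mean smaller residuals, hence fewer significant coefficients and
fewer bits at the same distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import kmeans_plusplus

from ezweeg.signal_io import Segment
from ezweeg import ezw
from ezweeg.ezw import EZWBitstream, RAW_PREAMBLE
from ezweeg.wavelet import (
    DEFAULT_LEVELS,
    DEFAULT_WAVELET,
    dwt_multilevel,
    idwt_multilevel,
    dequantize_coeffs,
    quantize_coeffs,
)

__all__ = [
    "ClusterModel",
    "correlation_coefficient",
    "angle_similarity",
    "cluster_segments",
    "differential_encode",
    "differential_decode",
]


def correlation_coefficient(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pearson correlation between two equal-length, non-constant vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(v1, v2)[0, 1])


def angle_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle (radians, in [0, pi]) between two nonzero vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for a zero vector")
    c = np.dot(v1, v2) / (n1 * n2)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class ClusterModel:
    """Fitted segment clustering with per-cluster prototypes.

    Cluster ids are 1-based; ``assignments[i] == 0`` marks segment ``i`` as
    unclustered.  ``prototype_values[p]`` is the raw sample vector of the
    prototype for cluster ``p``.
    """

    n_clusters: int
    assignments: np.ndarray
    prototypes: dict[int, int]  # cluster id -> member segment index
    prototype_values: dict[int, np.ndarray]
    centroids: np.ndarray
    metric: str = "euclidean"
    raw_threshold: float | None = None
    objective_history: list[float] = field(default_factory=list)

    def assign(self, values: np.ndarray) -> int:
        """Cluster id for a sample vector (0 = unclustered, beyond the raw threshold)."""
        d = np.array([_distance(values, c, self.metric) for c in self.centroids])
        best = int(np.argmin(d))
        if self.raw_threshold is not None and d[best] > self.raw_threshold:
            return 0
        return best + 1

    # prototypes travel with the bitstreams as a delimited-text sidecar
    def save(self, path: str | Path) -> None:
        path = Path(path)
        lines = [f"# ezweeg cluster model: metric={self.metric} "
                 f"raw_threshold={'' if self.raw_threshold is None else self.raw_threshold}"]
        for p in sorted(self.prototype_values):
            vals = ",".join(repr(float(v)) for v in self.prototype_values[p])
            lines.append(f"{p}\t{self.prototypes[p]}\t{vals}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        path = Path(path)
        lines = path.read_text().strip().splitlines()
        head = lines[0]
        metric = head.split("metric=")[1].split()[0]
        thr_txt = head.split("raw_threshold=")[1].strip()
        raw_threshold = float(thr_txt) if thr_txt else None
        prototypes: dict[int, int] = {}
        prototype_values: dict[int, np.ndarray] = {}
        for line in lines[1:]:
            p_txt, idx_txt, vals = line.split("\t")
            p = int(p_txt)
            prototypes[p] = int(idx_txt)
            prototype_values[p] = np.array([float(v) for v in vals.split(",")])
        cents = np.vstack([prototype_values[p] for p in sorted(prototype_values)])
        return cls(
            n_clusters=len(prototypes),
            assignments=np.zeros(0, dtype=int),
            prototypes=prototypes,
            prototype_values=prototype_values,
            centroids=cents,
            metric=metric,
            raw_threshold=raw_threshold,
        )


def _distance(v: np.ndarray, c: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(v - c))
    if metric == "angle":
        return angle_similarity(v, c)
    raise ValueError(f"unknown metric {metric!r}")


def _centroid(members: np.ndarray, metric: str) -> np.ndarray:
    m = members.mean(axis=0)
    if metric == "angle":
        norm = np.linalg.norm(m)
        if norm > 0:
            m = m / norm
    return m


def _lloyd(x, init_x, n_clusters, metric, init_seed, max_iter):
    centroids, _ = kmeans_plusplus(init_x, n_clusters, random_state=init_seed)
    history: list[float] = []
    for _ in range(max_iter):
        d = _pairwise(x, centroids, metric)
        labels = d.argmin(axis=1)
        obj = float((d[np.arange(len(x)), labels] ** 2).sum())
        history.append(obj)
        new_centroids = centroids.copy()
        for p in range(n_clusters):
            members = x[labels == p]
            if len(members):
                new_centroids[p] = _centroid(members, metric)
        if np.allclose(new_centroids, centroids):
            break
        centroids = new_centroids
    return centroids, history


def cluster_segments(
    segments: Sequence[Segment],
    n_clusters: int,
    metric: str = "euclidean",
    seed: int = 0,
    raw_threshold: float | None = None,
    max_iter: int = 100,
    n_init: int = 4,
) -> ClusterModel:
    """K-means over segment sample vectors, with prototype selection.

    Lloyd iterations from seeded k-means++ initializations (best of
    ``n_init`` restarts), run to convergence or ``max_iter``; the
    within-cluster objective (sum of squared distances under the chosen
    metric) is recorded per iteration and is nonincreasing.  Ties in
    assignment and prototype choice break toward the lowest index.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(segments):
        raise ValueError("more clusters than segments")
    x = np.vstack([s.values for s in segments])
    if metric == "angle":
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("angle metric undefined for zero segments")
        init_x = x / norms
    elif metric == "euclidean":
        init_x = x
    else:
        raise ValueError(f"unknown metric {metric!r}")

    seeds = np.random.SeedSequence(seed).generate_state(max(1, n_init)) % (2**31)
    centroids, history = None, None
    for s in seeds:
        c, h = _lloyd(x, init_x, n_clusters, metric, int(s), max_iter)
        if history is None or h[-1] < history[-1]:
            centroids, history = c, h

    d = _pairwise(x, centroids, metric)
    labels = d.argmin(axis=1)
    prototypes: dict[int, int] = {}
    prototype_values: dict[int, np.ndarray] = {}
    for p in range(n_clusters):
        members = np.nonzero(labels == p)[0]
        if len(members) == 0:
            # empty cluster: fall back to the globally closest segment
            members = np.array([int(d[:, p].argmin())])
        proto = int(members[d[members, p].argmin()])
        prototypes[p + 1] = proto
        prototype_values[p + 1] = x[proto].copy()

    assignments = labels + 1
    if raw_threshold is not None:
        dist_own = d[np.arange(len(x)), labels]
        assignments = np.where(dist_own > raw_threshold, 0, assignments)
    return ClusterModel(
        n_clusters=n_clusters,
        assignments=assignments,
        prototypes=prototypes,
        prototype_values=prototype_values,
        centroids=centroids,
        metric=metric,
        raw_threshold=raw_threshold,
        objective_history=history,
    )


def _pairwise(x: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=2)
    cos = (x @ centroids.T) / (
        np.linalg.norm(x, axis=1)[:, None] * np.linalg.norm(centroids, axis=1)[None, :]
    )
    return np.arccos(np.clip(cos, -1.0, 1.0))


def differential_encode(
    seg: Segment,
    model: ClusterModel,
    max_bits: int | None = None,
    levels: int = DEFAULT_LEVELS,
    wavelet_name: str = DEFAULT_WAVELET,
    quant_step: float = 1.0,
) -> EZWBitstream:
    """Encode a segment against its cluster prototype.

    Clustered: the residual ``seg - prototype`` is wavelet-transformed,
    quantized and EZW-coded with the cluster id in the preamble.  Unclustered:
    the segment itself is coded behind the raw marker preamble.
    """
    cid = model.assign(seg.values)
    if cid == 0:
        target = seg.values
        preamble = RAW_PREAMBLE
    else:
        target = seg.values - model.prototype_values[cid]
        preamble = cid
    coeffs = quantize_coeffs(dwt_multilevel(target, levels, wavelet_name), quant_step)
    return ezw.encode(coeffs, max_bits=max_bits, cluster_preamble=preamble)


def differential_decode(stream: EZWBitstream, model: ClusterModel) -> Segment:
    """Decode a differential stream, adding the prototype back when clustered."""
    if stream.cluster_preamble is None:
        raise ValueError("stream has no cluster preamble")
    coeffs = dequantize_coeffs(ezw.decode(stream))
    values = idwt_multilevel(coeffs)
    cid = stream.cluster_preamble
    if cid != RAW_PREAMBLE:
        if cid not in model.prototype_values:
            raise KeyError(f"unknown cluster id {cid}")
        values = values + model.prototype_values[cid]
    return Segment(values=values)
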