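"""Structural distance, heterogeneity index and hierarchical clustering.

The dissimilarity between two filaments v and w is an L1 (Manhattan)
combination of a cross-sectional and a helical term,

    d_xi(v, w) = d_cs(v, w) + d_dpf(v, w)

where d_cs is the RMSD between the two 360-point tip-accessible
cross-sections (minimized over the arbitrary relative azimuthal phase,
in 1-degree steps, without reflection — reflection would flip
chirality), standardized by sigma_cs, and d_dpf = |dpf_v - dpf_w| /
sigma_dpf.  The sigmas are the sample standard deviations of the raw
components over all pairs of the analyzed dataset, so that each
component contributes on a comparable scale.

The heterogeneity index of a population is the quadratic mean of all
its pairwise distances, HI = sqrt(mean d_xi^2), with a standard error
from leave-one-filament-out jackknifing (pairs sharing a filament are
dependent, so resampling is over filaments, not pairs).  Average-linkage
agglomerative clustering under d_xi organizes the population into
polymorph classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

from .cpr import HelicalEnvelope

__all__ = [
    "DistanceMatrix", "HeterogeneityResult", "ClusterTree",
    "d_cs", "d_dpf", "raw_cs_distance", "distance_matrix",
    "cross_distances", "heterogeneity_index", "cluster",
    "extract_match_cluster",
]


# --------------------------------------------------------------------------- #
# Distances
# --------------------------------------------------------------------------- #

def raw_cs_distance(r_v: np.ndarray, r_w: np.ndarray) -> float:
    """Cross-section RMSD minimized over cyclic azimuthal shifts.

    Uses the circular cross-correlation identity
    ``rmsd^2(k) = (|v|^2 + |w|^2 - 2 c_vw(k)) / n`` so all 360 shifts
    cost one FFT; equals the exhaustive minimum exactly.
    """
    v = np.asarray(r_v, dtype=float)
    w = np.asarray(r_w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("cross-sections must share the sampling grid")
    n = len(v)
    cc = np.fft.irfft(np.fft.rfft(v) * np.conj(np.fft.rfft(w)), n)
    sq = (v @ v + w @ w - 2.0 * cc) / n
    return float(np.sqrt(max(sq.min(), 0.0)))


def d_cs(v: HelicalEnvelope | np.ndarray, w: HelicalEnvelope | np.ndarray,
         sigma_cs: float) -> float:
    """Standardized cross-section distance (registration included)."""
    if sigma_cs <= 0:
        raise ValueError("sigma_cs must be > 0")
    rv = v.r if isinstance(v, HelicalEnvelope) else v
    rw = w.r if isinstance(w, HelicalEnvelope) else w
    return raw_cs_distance(rv, rw) / sigma_cs


def d_dpf(v: HelicalEnvelope | float, w: HelicalEnvelope | float,
          sigma_dpf: float) -> float:
    """Standardized helical distance |dpf_v - dpf_w| / sigma_dpf.

    Handedness enters automatically through the sign of dpf.
    """
    if sigma_dpf <= 0:
        raise ValueError("sigma_dpf must be > 0")
    fv = v.dpf if isinstance(v, HelicalEnvelope) else float(v)
    fw = w.dpf if isinstance(w, HelicalEnvelope) else float(w)
    return abs(fv - fw) / sigma_dpf


@dataclass
class DistanceMatrix:
    """All pairwise structural distances of a filament population."""

    ids: list[str]
    d_xi: np.ndarray          # condensed (n*(n-1)/2,) standardized sums
    d_cs_raw: np.ndarray      # condensed raw RMSD components, nm
    d_dpf_raw: np.ndarray     # condensed raw |dpf| differences, 1/nm
    sigma_cs: float
    sigma_dpf: float

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        return len(self.d_xi)

    def square(self) -> np.ndarray:
        return squareform(self.d_xi)

    def submatrix_condensed(self, idx: Sequence[int]) -> np.ndarray:
        """Condensed d_xi restricted to a subset of filaments."""
        return squareform(self.square()[np.ix_(idx, idx)], checks=False)


def _pairwise_cs_raw(R: np.ndarray) -> np.ndarray:
    """Condensed registered RMSDs for the rows of R (n, 360), via FFT."""
    n, m = R.shape
    F = np.fft.rfft(R, axis=1)
    sq = np.einsum("ij,ij->i", R, R)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        cc = np.fft.irfft(F[i][None, :] * np.conj(F[i + 1:]), m, axis=1)
        d2 = (sq[i] + sq[i + 1:] - 2.0 * cc.max(axis=1)) / m
        out[k:k + n - 1 - i] = np.sqrt(np.clip(d2, 0.0, None))
        k += n - 1 - i
    return out


def distance_matrix(envelopes: Sequence[HelicalEnvelope],
                    sigma_cs: float | None = None,
                    sigma_dpf: float | None = None) -> DistanceMatrix:
    """Pairwise d_xi over a population.

    The standardization constants default to the sample SDs (n-1
    denominator) of the raw components over all pairs of this dataset;
    pass frozen sigmas to compare against an already-standardized
    reference analysis.
    """
    if len(envelopes) < 2:
        raise ValueError("need at least two envelopes")
    R = np.stack([e.r for e in envelopes])
    dpf = np.array([e.dpf for e in envelopes])
    cs_raw = _pairwise_cs_raw(R)
    i, j = np.triu_indices(len(envelopes), k=1)
    dpf_raw = np.abs(dpf[i] - dpf[j])
    s_cs = float(np.std(cs_raw, ddof=1)) if sigma_cs is None else sigma_cs
    s_dpf = float(np.std(dpf_raw, ddof=1)) if sigma_dpf is None else sigma_dpf
    if s_cs <= 0 or s_dpf <= 0:
        raise ValueError(
            "standardization SD is zero: the population is structurally "
            "identical in one component; supply frozen sigma values from a "
            "reference dataset instead")
    ids = [e.filament_id or str(k) for k, e in enumerate(envelopes)]
    return DistanceMatrix(ids=ids, d_xi=cs_raw / s_cs + dpf_raw / s_dpf,
                          d_cs_raw=cs_raw, d_dpf_raw=dpf_raw,
                          sigma_cs=s_cs, sigma_dpf=s_dpf)


def cross_distances(envelopes: Sequence[HelicalEnvelope],
                    references: Sequence[HelicalEnvelope],
                    sigma_cs: float, sigma_dpf: float) -> np.ndarray:
    """d_xi between every envelope (rows) and every reference (cols)."""
    if not envelopes or not references:
        raise ValueError("empty envelope or reference set")
    R = np.stack([e.r for e in envelopes])
    Q = np.stack([e.r for e in references])
    m = R.shape[1]
    FR = np.fft.rfft(R, axis=1)
    FQ = np.fft.rfft(Q, axis=1)
    sqR = np.einsum("ij,ij->i", R, R)
    sqQ = np.einsum("ij,ij->i", Q, Q)
    out = np.empty((len(R), len(Q)))
    for j in range(len(Q)):
        cc = np.fft.irfft(FR * np.conj(FQ[j])[None, :], m, axis=1)
        d2 = (sqR + sqQ[j] - 2.0 * cc.max(axis=1)) / m
        out[:, j] = np.sqrt(np.clip(d2, 0.0, None)) / sigma_cs
    dpfR = np.array([e.dpf for e in envelopes])[:, None]
    dpfQ = np.array([e.dpf for e in references])[None, :]
    return out + np.abs(dpfR - dpfQ) / sigma_dpf


# --------------------------------------------------------------------------- #
# Heterogeneity index
# --------------------------------------------------------------------------- #

@dataclass
class HeterogeneityResult:
    hi: float
    se: float
    n_dxi: int


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def heterogeneity_index(matrix: DistanceMatrix,
                        subset: Sequence[int] | None = None
                        ) -> HeterogeneityResult:
    """HI = RMS of the within-subset pairwise d_xi, with jackknife SE.

    The jackknife leaves out one *filament* at a time (removing all the
    pairs it participates in) and uses the standard jackknife variance
    over the n leave-one-out HI replicates.
    """
    idx = np.arange(matrix.n) if subset is None else np.asarray(subset)
    if len(idx) < 2:
        raise ValueError("subset must contain at least two filaments")
    sq = matrix.square()[np.ix_(idx, idx)]
    cond = squareform(sq, checks=False)
    hi = _rms(cond)
    n = len(idx)
    if n == 2:
        return HeterogeneityResult(hi=hi, se=np.nan, n_dxi=1)
    reps = np.empty(n)
    keep = np.arange(n)
    for k in range(n):
        sub = sq[np.ix_(keep[keep != k], keep[keep != k])]
        reps[k] = _rms(squareform(sub, checks=False))
    se = np.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2))
    return HeterogeneityResult(hi=hi, se=float(se), n_dxi=len(cond))


# --------------------------------------------------------------------------- #
# Clustering
# --------------------------------------------------------------------------- #

@dataclass
class ClusterTree:
    """Average-linkage dendrogram over a filament population."""

    linkage_matrix: np.ndarray      # scipy (n-1, 4) merge list
    ids: list[str]
    leaf_order: list[int] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths from linkage heights."""
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(root, root.dist) + ";"


def cluster(matrix: DistanceMatrix) -> ClusterTree:
    """Agglomerative clustering with the average (UPGMA) linkage.

    At each step the closest pair of clusters is merged and the
    inter-cluster distance is the unweighted mean of all cross-pair
    d_xi values, exactly the average-distance linkage function.
    """
    Z = linkage(matrix.d_xi, method="average")
    order = dendrogram(Z, no_plot=True)["leaves"]
    return ClusterTree(linkage_matrix=Z, ids=list(matrix.ids),
                       leaf_order=list(order))


def extract_match_cluster(ref_distances: np.ndarray,
                          within: DistanceMatrix | np.ndarray,
                          seed_threshold: float = 0.5,
                          member_threshold: float = 1.0) -> list[int]:
    """Members of the cluster matching one reference structure.

    Seeds are filaments closer than ``seed_threshold`` to the reference;
    further members are added (in order of increasing reference
    distance) iff they are closer than ``member_threshold`` to the
    reference *and* to every already-accepted member.  An empty list is
    a valid result (no seed).
    """
    d_ref = np.asarray(ref_distances, dtype=float)
    sq = within.square() if isinstance(within, DistanceMatrix) else \
        np.asarray(within, dtype=float)
    if sq.shape != (len(d_ref), len(d_ref)):
        raise ValueError("within-matrix does not match reference distances")
    seeds = np.nonzero(d_ref < seed_threshold)[0]
    if len(seeds) == 0:
        return []
    members: list[int] = []
    for i in np.argsort(d_ref, kind="stable"):
        if d_ref[i] >= member_threshold:
            break
        if i in seeds or all(sq[i, m] < member_threshold for m in members):
            if d_ref[i] < member_threshold:
                members.append(int(i))
    return sorted(members)
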