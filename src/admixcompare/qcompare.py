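"""Aligning and comparing ancestry matrices across runs, K values and markers.

Independent clustering runs label clusters arbitrarily (label switching), so
Q-matrices are compared after the column permutation that maximizes their
Symmetric Similarity Coefficient,

    SSC(Q1, Q2; P) = 1 - ||Q1 - Q2 P||_F / sqrt(2 N),

which is 1 exactly when the matrices are identical under the permutation and
can go negative for very dissimilar matrices. Maximizing SSC over column
permutations is a linear assignment problem on per-column squared distances,
solved exactly with the Hungarian algorithm. Matrices with different K are
compared after zero-padding the smaller one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotypes import QMatrix

__all__ = [
    "AlignmentResult",
    "ModeSet",
    "AdmixtureProfile",
    "ssc",
    "align_qmatrices",
    "exhaustive_alignment",
    "pairwise_ssc_matrix",
    "find_modes",
    "average_by_locality",
    "coefficient_of_admixture",
]


@dataclass
class AlignmentResult:
    permutation: np.ndarray  # aligned column j of Q2 = original column perm[j]
    ssc: float
    aligned_Q: QMatrix  # Q2 in Q1's column order (zero-padded if K2 < K1)


@dataclass
class ModeSet:
    """Partition of replicate runs into modes (groups of mutually similar runs)."""

    groups: list[list[int]]
    major_mode: int  # index into groups
    consensus_Q: list[QMatrix]
    mean_intra_ssc: list[float] = field(default_factory=list)


@dataclass
class AdmixtureProfile:
    ca: np.ndarray  # per-individual coefficient of admixture in [0, 1]
    mean: float
    quantiles: dict[str, float]


def _as_values(q: QMatrix | np.ndarray) -> np.ndarray:
    return q.values if isinstance(q, QMatrix) else np.asarray(q, float)


def ssc(
    q1: QMatrix | np.ndarray,
    q2: QMatrix | np.ndarray,
    permutation: np.ndarray | list[int] | None = None,
) -> float:
    """SSC of two Q-matrices under a given column permutation of ``q2``."""
    a, b = _as_values(q1), _as_values(q2)
    if permutation is not None:
        b = b[:, np.asarray(permutation)]
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    return 1.0 - float(np.linalg.norm(a - b)) / np.sqrt(2.0 * n)


def _pad(values: np.ndarray, k: int) -> np.ndarray:
    if values.shape[1] == k:
        return values
    out = np.zeros((values.shape[0], k))
    out[:, : values.shape[1]] = values
    return out


def align_qmatrices(q1: QMatrix, q2: QMatrix) -> AlignmentResult:
    """Best-SSC alignment of ``q2``'s columns onto ``q1``'s.

    Exact: the optimal permutation minimizes the Frobenius distance, which
    decomposes into independent per-column costs and is solved as an
    assignment problem. When K differs the smaller matrix is padded with
    zero columns before the search, so clusters absent at the lower K map
    onto the padding.
    """
    if q1.individual_ids != q2.individual_ids:
        raise ValueError("Q-matrices must describe the same individuals")
    k = max(q1.k, q2.k)
    a, b = _pad(q1.values, k), _pad(q2.values, k)
    cost = ((a[:, :, None] - b[:, None, :]) ** 2).sum(axis=0)  # (k1, k2)
    _, cols = linear_sum_assignment(cost)
    aligned = b[:, cols]
    return AlignmentResult(
        permutation=cols,
        ssc=1.0 - float(np.linalg.norm(a - aligned)) / np.sqrt(2.0 * a.shape[0]),
        aligned_Q=QMatrix(aligned, list(q1.individual_ids)),
    )


def exhaustive_alignment(q1: QMatrix, q2: QMatrix) -> AlignmentResult:
    """Brute-force alignment over all column permutations (small K only)."""
    if q1.individual_ids != q2.individual_ids:
        raise ValueError("Q-matrices must describe the same individuals")
    k = max(q1.k, q2.k)
    a, b = _pad(q1.values, k), _pad(q2.values, k)
    best_perm, best_ssc = None, -np.inf
    n = a.shape[0]
    for perm in itertools.permutations(range(k)):
        s = 1.0 - float(np.linalg.norm(a - b[:, perm])) / np.sqrt(2.0 * n)
        if s > best_ssc:
            best_perm, best_ssc = np.array(perm), s
    return AlignmentResult(
        permutation=best_perm,
        ssc=best_ssc,
        aligned_Q=QMatrix(b[:, best_perm], list(q1.individual_ids)),
    )


def pairwise_ssc_matrix(
    runs: list[QMatrix], labels: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of aligned SSC between all runs (diagonal 1).

    ``labels`` (e.g. ``"snp_k2_r0"``) are kept as index/columns so
    intra-marker and inter-marker subsets can be sliced out downstream.
    """
    n = len(runs)
    labels = labels or [f"run{i}" for i in range(n)]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = align_qmatrices(runs[i], runs[j]).ssc
    return pd.DataFrame(out, index=labels, columns=labels)


def find_modes(runs: list[QMatrix], threshold: float = 0.9) -> ModeSet:
    """Group replicate runs into modes by single-linkage on aligned SSC.

    Runs join the same mode whenever a chain of pairwise SSC >= threshold
    connects them. Each mode's consensus is the mean of its members after
    alignment to the mode's first member; the major mode is the largest
    (ties broken by higher mean intra-mode SSC).
    """
    if not runs:
        raise ValueError("need at least one run")
    n = len(runs)
    sim = pairwise_ssc_matrix(runs).to_numpy()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups_by_root: dict[int, list[int]] = {}
    for i in range(n):
        groups_by_root.setdefault(find(i), []).append(i)
    groups = sorted(groups_by_root.values(), key=lambda g: g[0])

    consensus, intra = [], []
    for g in groups:
        ref = runs[g[0]]
        stack = [runs[g[0]].values] + [
            align_qmatrices(ref, runs[i]).aligned_Q.values[:, : ref.k] for i in g[1:]
        ]
        mean = np.mean(stack, axis=0)
        consensus.append(QMatrix(mean / mean.sum(axis=1, keepdims=True),
                                 list(ref.individual_ids)))
        if len(g) > 1:
            vals = [sim[a, b] for a, b in itertools.combinations(g, 2)]
            intra.append(float(np.mean(vals)))
        else:
            intra.append(1.0)
    major = max(range(len(groups)), key=lambda i: (len(groups[i]), intra[i]))
    return ModeSet(groups=groups, major_mode=major, consensus_Q=consensus,
                   mean_intra_ssc=intra)


def average_by_locality(q: QMatrix, locality_ids: list[str]) -> QMatrix:
    """Arithmetic mean of member ancestries per locality (rows still sum to 1)."""
    if len(locality_ids) != q.n_individuals:
        raise ValueError("one locality per individual required")
    df = pd.DataFrame(q.values, index=pd.Index(locality_ids, name="locality"))
    means = df.groupby(level="locality", sort=True).mean()
    if means.isna().any().any():
        raise ValueError("empty locality encountered")
    return QMatrix(means.to_numpy(), [str(i) for i in means.index])


def coefficient_of_admixture(q: QMatrix, method: str = "entropy") -> AdmixtureProfile:
    """Per-individual Coefficient of Admixture (CA) on a K >= 2 Q-matrix.

    CA is 0 when all ancestry sits in a single cluster and 1 for equal
    proportions across all K clusters. The default is normalized Shannon
    entropy, CA_i = -sum_k q_ik ln q_ik / ln K (0 ln 0 := 0); the
    ``"maxdev"`` alternative, 1 - K/(K-1) (max_k q_ik - 1/K), meets the same
    endpoints and is kept for sensitivity checks.
    """
    if q.k < 2:
        raise ValueError("CA is undefined for K = 1")
    v = q.values
    if method == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(v > 0, v * np.log(v), 0.0)
        ca = -terms.sum(axis=1) / np.log(q.k)
    elif method == "maxdev":
        ca = 1.0 - q.k / (q.k - 1.0) * (v.max(axis=1) - 1.0 / q.k)
    else:
        raise ValueError(f"unknown CA method: {method!r}")
    ca = np.clip(ca, 0.0, 1.0)
    qs = np.quantile(ca, [0.25, 0.5, 0.75])
    return AdmixtureProfile(
        ca=ca,
        mean=float(ca.mean()),
        quantiles={"q25": float(qs[0]), "median": float(qs[1]), "q75": float(qs[2])},
    )
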