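"""Choosing the number of clusters K and checking run convergence.

Four complementary diagnostics over replicate clustering runs:

* Gelman–Rubin potential scale reduction on replicate log-likelihood traces
  (values below 1.05 read as good convergence);
* Pr[X|K], the harmonic-style estimator of the model evidence on the log
  scale, mean(lnL) - var(lnL)/2 per run;
* Evanno's delta-K, the absolute second difference of mean ln-probability
  across successive K scaled by its replicate standard deviation;
* a parsimony index favouring K whose replicate runs are mutually consistent
  (high pairwise SSC) and whose consensus ancestries are minimally admixed.

A model-free cross-check is provided by allele-sharing distances and a
neighbour-joining tree.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .genotypes import GenotypeMatrix, QMatrix
from .qcompare import align_qmatrices, coefficient_of_admixture

__all__ = [
    "gelman_rubin",
    "pr_x_given_k",
    "evanno_delta_k",
    "parsimony_index",
    "allele_sharing_distance",
    "neighbor_joining",
    "k_selection_table",
]


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor across replicate chains.

    With m chains of length n: W is the mean within-chain variance, B/n the
    between-chain variance of the chain means, and the pooled posterior
    variance estimate is (n-1)/n W + B/n + B/(m n); the statistic is
    sqrt(Vhat / W). Identical chains with positive variance give a value
    slightly below 1; well-mixed chains approach 1 from above.
    """
    arr = np.asarray(list(traces), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two chains")
    m, n = arr.shape
    if n < 4:
        raise ValueError("chains must have length >= 4")
    w = arr.var(axis=1, ddof=1).mean()
    b_over_n = arr.mean(axis=1).var(ddof=1)
    if w == 0.0:
        if b_over_n > 0.0:
            raise ValueError("degenerate chains: zero within-chain variance "
                             "with non-zero between-chain variance")
        return 1.0
    vhat = (n - 1) / n * w + b_over_n + b_over_n / m
    return float(np.sqrt(vhat / w))


def pr_x_given_k(loglik_trace) -> float:
    """Log model evidence estimate from a run's log-likelihood trace.

    The standard estimator mean(trace) - var(trace)/2 (plug-in variance);
    always <= the trace mean.
    """
    t = np.asarray(loglik_trace, dtype=float)
    if t.size == 0:
        raise ValueError("empty log-likelihood trace")
    return float(t.mean() - t.var(ddof=0) / 2.0)


def evanno_delta_k(
    mean_lnP: dict[int, float], sd_lnP: dict[int, float]
) -> dict[int, float]:
    """Evanno's delta-K over a contiguous K range (undefined at the ends).

    delta_K(k) = |L(k+1) - 2 L(k) + L(k-1)| / sd(k). A zero replicate
    standard deviation yields +inf with a warning rather than an error.
    """
    ks = sorted(mean_lnP)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    out: dict[int, float] = {}
    for k in ks[1:-1]:
        num = abs(mean_lnP[k + 1] - 2.0 * mean_lnP[k] + mean_lnP[k - 1])
        sd = sd_lnP[k]
        if sd == 0.0:
            warnings.warn(f"zero replicate sd at K={k}; delta-K is infinite")
            out[k] = np.inf
        else:
            out[k] = num / sd
    return out


def parsimony_index(qs: list[QMatrix]) -> float:
    """Consistency x parsimony score for the replicate runs at one K.

    Consistency is the mean pairwise aligned SSC among the replicates;
    parsimony is 1 minus the mean Coefficient of Admixture of the consensus
    (the mean of the replicates after alignment to the first). Both
    components lie in (-inf, 1]; identical, fully unadmixed runs score 1.
    With a single run the consistency factor is undefined and the parsimony
    component is returned alone (with a warning).
    """
    if not qs:
        raise ValueError("need at least one run")
    if qs[0].k < 2:
        raise ValueError("parsimony index is undefined at K = 1 (CA undefined)")
    aligned = [qs[0].values] + [
        align_qmatrices(qs[0], q).aligned_Q.values[:, : qs[0].k] for q in qs[1:]
    ]
    consensus = np.mean(aligned, axis=0)
    consensus /= consensus.sum(axis=1, keepdims=True)
    parsimony = 1.0 - coefficient_of_admixture(
        QMatrix(consensus, list(qs[0].individual_ids))
    ).mean
    if len(qs) < 2:
        warnings.warn("single run: returning the parsimony component only")
        return float(parsimony)
    sscs = [
        align_qmatrices(qs[i], qs[j]).ssc
        for i in range(len(qs))
        for j in range(i + 1, len(qs))
    ]
    return float(np.mean(sscs) * parsimony)


def allele_sharing_distance(genotypes: GenotypeMatrix) -> np.ndarray:
    """1 - mean proportion of shared alleles per co-typed diploid locus.

    Sharing at one locus is the multiset intersection of the two genotypes
    divided by 2 (0, 0.5 or 1). Symmetric with a zero diagonal; a pair with
    no co-typed loci is an error.
    """
    n = genotypes.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    coded, _, _ = genotypes.dense_coding()
    x = np.minimum(coded[:, :, 0], coded[:, :, 1]).astype(np.int64)
    y = np.maximum(coded[:, :, 0], coded[:, :, 1]).astype(np.int64)
    typed = coded[:, :, 0] >= 0
    d = np.zeros((n, n))
    for i in range(n):
        xi, yi = x[i], y[i]
        for j in range(i + 1, n):
            ok = typed[i] & typed[j]
            if not ok.any():
                raise ValueError(
                    f"individuals {genotypes.individual_ids[i]} and "
                    f"{genotypes.individual_ids[j]} share no typed loci"
                )
            xj, yj = x[j], y[j]
            hom_i, hom_j = xi == yi, xj == yj
            s = np.where(
                hom_i & hom_j,
                2.0 * (xi == xj),
                np.where(
                    hom_i,
                    ((xi == xj) | (xi == yj)).astype(float),
                    np.where(
                        hom_j,
                        ((xi == xj) | (yi == xj)).astype(float),
                        ((xi == xj) | (xi == yj)).astype(float)
                        + ((yi == xj) | (yi == yj)).astype(float),
                    ),
                ),
            )
            d[i, j] = d[j, i] = 1.0 - (s[ok] / 2.0).mean()
    return d


def neighbor_joining(distances: np.ndarray, ids: list[str] | None = None):
    """Saitou–Nei neighbour joining; returns an (unrooted) skbio TreeNode.

    Negative branch lengths are clamped to zero. On an additive matrix the
    tree's patristic distances reproduce the input exactly.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValueError("need a square distance matrix over >= 3 taxa")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    ids = ids or [f"t{i}" for i in range(d.shape[0])]
    return nj(DistanceMatrix(d, ids), neg_as_zero=True)


def k_selection_table(runs: dict[tuple[int, int], "object"]) -> pd.DataFrame:
    """Summarize replicate runs into the K-selection table.

    ``runs`` maps (K, replicate) to a StructureRun. Per K: the mean and sd
    over replicates of each run's Pr[X|K] estimate, Evanno's delta-K,
    the parsimony index of the replicate Q-matrices (NaN at K = 1), and
    Gelman–Rubin on the replicate log-likelihood traces.
    """
    ks = sorted({k for k, _ in runs})
    rows = []
    lnp_mean: dict[int, float] = {}
    lnp_sd: dict[int, float] = {}
    for k in ks:
        reps = [runs[key] for key in sorted(runs) if key[0] == k]
        lnps = [pr_x_given_k(r.loglik_trace) for r in reps]
        lnp_mean[k] = float(np.mean(lnps))
        lnp_sd[k] = float(np.std(lnps, ddof=1)) if len(lnps) > 1 else 0.0
        if len(reps) > 1:
            min_len = min(len(r.loglik_trace) for r in reps)
            gr = gelman_rubin([r.loglik_trace[:min_len] for r in reps])
        else:
            gr = np.nan
        pi = parsimony_index([r.Q for r in reps]) if k > 1 else np.nan
        rows.append(
            {"K": k, "mean_lnP": lnp_mean[k], "sd_lnP": lnp_sd[k],
             "pr_x_given_k": lnp_mean[k], "parsimony_index": pi,
             "gelman_rubin": gr}
        )
    table = pd.DataFrame(rows).set_index("K")
    table["delta_k"] = np.nan
    if len(ks) >= 3 and ks == list(range(ks[0], ks[-1] + 1)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dk = evanno_delta_k(lnp_mean, lnp_sd)
        for k, v in dk.items():
            table.loc[k, "delta_k"] = v
    return table.reset_index()
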