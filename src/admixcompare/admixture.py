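"""Bayesian admixture-model clustering via Gibbs sampling.

The model is the classic admixture model for multilocus genotypes: each
individual i has ancestry proportions q_i over K clusters, each allele copy
at locus l originates from cluster k with probability q_ik and is then drawn
from that cluster's allele frequencies p_kl. Priors are q_i ~ Dirichlet(a)
with a single shared alpha under a uniform prior, and either

* uncorrelated frequencies: p_kl ~ Dirichlet(lambda), or
* correlated frequencies (the F-model, the default): p_kl ~
  Dirichlet(pi_l (1 - F_k) / F_k) with ancestral frequencies
  pi_l ~ Dirichlet(lambda) and per-cluster drift F_k ~ Uniform(0, 1).

The sampler alternates Gibbs updates of the latent allele origins z, the
ancestries q and the frequencies p with random-walk Metropolis updates of
alpha, F (logit scale) and pi (Dirichlet independence proposal), plus an
optional Metropolis update of lambda (used to estimate lambda at K = 1).
Missing allele copies are simply skipped — they enter neither the
likelihood nor the origin updates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .genotypes import GenotypeMatrix, QMatrix

__all__ = [
    "MICROSAT_OPTIONS",
    "McmcOptions",
    "StructureRun",
    "log_likelihood",
    "run_admixture_mcmc",
    "estimate_lambda",
    "replicate_runs",
]

_PI_FLOOR = 1e-6  # keeps ancestral frequencies off the simplex boundary

try:  # compiled inner kernel; the numpy path below is the reference
    from numba import njit

    @njit(cache=False)
    def _categorical_counts(q, ptf, u, obs_ind, flat_base, n, k, lj):
        """Per copy c: weights w_j = q[i,j] * p[j, locus, allele]; sample one
        origin from them and tally per-individual and per-allele counts."""
        zc = np.zeros((n, k))
        ac = np.zeros((k, lj))
        w = np.empty(k)
        for c in range(u.size):
            i = obs_ind[c]
            b = flat_base[c]
            tot = 0.0
            for j in range(k):
                w[j] = q[i, j] * ptf[b, j]
                tot += w[j]
            t = u[c] * tot
            acc = 0.0
            kk = k - 1
            for j in range(k):
                acc += w[j]
                if t <= acc:
                    kk = j
                    break
            zc[i, kk] += 1.0
            ac[kk, b] += 1.0
        return zc, ac

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is available in supported envs
    _HAVE_NUMBA = False


def _categorical_counts_numpy(q, ptf, u, obs_ind, flat_base, n, k, lj):
    probs = q[obs_ind] * ptf[flat_base]
    cum = np.cumsum(probs, axis=1)
    z = np.minimum(((u * cum[:, -1])[:, None] > cum).sum(axis=1), k - 1)
    zc = np.bincount(obs_ind * k + z, minlength=n * k).reshape(n, k).astype(float)
    ac = np.bincount(z * lj + flat_base, minlength=k * lj).reshape(k, lj).astype(float)
    return zc, ac


@dataclass
class McmcOptions:
    """Run-length and prior settings for one sampler run.

    ``iterations`` counts post-burnin sweeps; every ``record_interval``-th
    one contributes to the posterior means and the recorded traces.
    ``lambda_`` is either a fixed positive value or ``"estimate"`` to give
    lambda a Metropolis update under a uniform prior on (0, lambda_prior_max].

    Defaults are the standard SNP run lengths (30,000 burnin, 10,000
    sampling sweeps, recording every 50); :data:`MICROSAT_OPTIONS` holds the
    conventional microsatellite lengths (500,000 / 1,000,000, recording
    every 5,000, lambda fixed to 1). Scale these down for exploratory work.
    """

    burnin: int = 30_000
    iterations: int = 10_000
    record_interval: int = 50
    lambda_: float | str = 1.0
    alpha_init: float = 1.0
    alpha_proposal_sd: float = 0.05
    alpha_prior_max: float = 10.0
    freq_model: str = "correlated"  # or "uncorrelated"
    init: str = "kmeans"  # or "random"
    f_init: float = 0.1
    f_proposal_sd: float = 0.1  # logit-scale random walk
    pi_proposal_conc: float = 100.0
    lambda_proposal_sd: float = 0.3
    lambda_prior_max: float = 10.0
    keep_q_draws: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.iterations < self.record_interval or self.record_interval < 1:
            raise ValueError("need burnin >= 0 and iterations >= record_interval >= 1")
        if self.lambda_ != "estimate" and not float(self.lambda_) > 0:
            raise ValueError("lambda must be positive or 'estimate'")
        if self.freq_model not in ("correlated", "uncorrelated"):
            raise ValueError("freq_model must be 'correlated' or 'uncorrelated'")
        if self.init not in ("kmeans", "random"):
            raise ValueError("init must be 'kmeans' or 'random'")

    def with_seed(self, seed: int) -> "McmcOptions":
        return replace(self, seed=seed)


#: Conventional long microsatellite run lengths (lambda fixed to 1).
MICROSAT_OPTIONS = McmcOptions(
    burnin=500_000, iterations=1_000_000, record_interval=5_000, lambda_=1.0
)


@dataclass
class StructureRun:
    """One MCMC replicate: posterior means plus recorded traces."""

    K: int
    Q: QMatrix
    P: np.ndarray  # (K, L, J_max) posterior-mean frequencies, dense coding
    n_alleles: np.ndarray  # J_l per locus (masks the padding in P)
    alpha_trace: np.ndarray
    lambda_: float
    lambda_trace: np.ndarray
    loglik_trace: np.ndarray
    f_trace: np.ndarray | None
    burnin_steps: int
    sample_steps: int
    record_interval: int
    seed: int
    q_draws: np.ndarray | None = None  # (n_records, N, K) if requested

    @property
    def alpha_mean(self) -> float:
        return float(self.alpha_trace.mean())

    @property
    def lambda_mean(self) -> float:
        return float(self.lambda_trace.mean())


def _observed_copies(genotypes: GenotypeMatrix):
    coded, n_alleles, _ = genotypes.dense_coding()
    ind, loc, copy = np.nonzero(coded >= 0)
    return coded, n_alleles, ind, loc, coded[ind, loc, copy]


def log_likelihood(
    genotypes: GenotypeMatrix, q: QMatrix | np.ndarray, p: np.ndarray
) -> float:
    """ln Pr(X | Q, P): sum over non-missing allele copies of ln sum_k q_ik p_kla.

    ``p`` has shape (K, L, J_max) indexed by the dense allele coding of
    ``genotypes`` (see :meth:`GenotypeMatrix.dense_coding`).
    """
    qv = q.values if isinstance(q, QMatrix) else np.asarray(q, float)
    p = np.asarray(p, float)
    _, _, ind, loc, allele = _observed_copies(genotypes)
    if ind.size == 0:
        return 0.0
    if qv.shape != (genotypes.n_individuals, p.shape[0]) or p.shape[1] != genotypes.n_loci:
        raise ValueError("dimension mismatch between genotypes, Q and P")
    mix = np.einsum("ck,ck->c", qv[ind], p[:, loc, allele].T)
    if np.any(mix <= 0):
        raise ValueError("zero mixture probability for an observed allele "
                         "(P does not support the data)")
    return float(np.log(mix).sum())


def _dirichlet_logpdf(x_log: np.ndarray, shape: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Row-wise log Dirichlet density over the valid-allele mask.

    ``x_log``/``shape`` are (..., J); returns (...,) with the convention that
    invalid (padding) entries contribute nothing.
    """
    sh = np.where(valid, shape, 1.0)
    term = np.where(valid, (shape - 1.0) * x_log - gammaln(sh), 0.0).sum(axis=-1)
    total = np.where(valid, shape, 0.0).sum(axis=-1)
    return gammaln(total) + term


def run_admixture_mcmc(
    genotypes: GenotypeMatrix, K: int, opts: McmcOptions | None = None
) -> StructureRun:
    """Run one Gibbs-sampler replicate at a fixed number of clusters K.

    Reproducible: the same genotypes, K and options (including seed) give an
    identical run. At K = 1 the frequency model reduces to the uncorrelated
    prior (there is no between-cluster correlation to model).
    """
    opts = opts or McmcOptions()
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > genotypes.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    n, L = genotypes.n_individuals, genotypes.n_loci
    if n == 0 or L == 0:
        raise ValueError("empty genotype matrix")
    rng = np.random.default_rng(opts.seed)
    coded, n_alleles, obs_ind, obs_loc, obs_allele = _observed_copies(genotypes)
    jmax = int(n_alleles.max())
    valid = np.arange(jmax)[None, :] < n_alleles[:, None]  # (L, J)
    correlated = opts.freq_model == "correlated" and K > 1

    estimate_lambda_flag = opts.lambda_ == "estimate"
    lam = 1.0 if estimate_lambda_flag else float(opts.lambda_)
    alpha = float(opts.alpha_init)
    f = np.full(K, opts.f_init)

    # init: pi from sample frequencies; a rough hard clustering seeds the
    # cluster labels (shortens burnin considerably; the stationary
    # distribution is unaffected, and init="random" recovers a cold start)
    counts0 = np.bincount(obs_loc * jmax + obs_allele, minlength=L * jmax)
    counts0 = counts0.reshape(L, jmax).astype(float)
    pi = np.where(valid, counts0 + lam, 0.0)
    pi = pi / pi.sum(axis=1, keepdims=True)
    pi = _floor_simplex(pi, valid)
    soft = _initial_soft_assignment(K, n, counts0, obs_ind, obs_loc, obs_allele,
                                    jmax, opts.init, rng)
    # sample each copy's starting origin from the soft weights, so genuinely
    # intermediate individuals begin with mixed labels rather than pure ones
    cum = np.cumsum(soft[obs_ind], axis=1)
    u0 = rng.random(obs_ind.size) * cum[:, -1]
    z0 = np.minimum((u0[:, None] > cum).sum(axis=1), K - 1)
    ac0 = np.bincount(z0 * (L * jmax) + obs_loc * jmax + obs_allele,
                      minlength=K * L * jmax).reshape(K, L, jmax)
    p = _sample_simplex_3d(np.where(valid[None], lam + ac0, 0.0), valid, rng)
    zc0 = np.bincount(obs_ind * K + z0, minlength=n * K).reshape(n, K)
    q = _sample_rows(alpha + zc0, rng)

    n_records = opts.iterations // opts.record_interval
    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L, jmax))
    ll_trace = np.empty(n_records)
    a_trace = np.empty(n_records)
    lam_trace = np.empty(n_records)
    f_trace = np.empty((n_records, K)) if correlated else None
    q_draws = np.empty((n_records, n, K)) if opts.keep_q_draws else None

    flat_base = obs_loc * jmax + obs_allele
    count_fn = _categorical_counts if _HAVE_NUMBA else _categorical_counts_numpy
    rec = 0
    for sweep in range(opts.burnin + opts.iterations):
        # -- z: latent origin of each observed allele copy, with per-cluster
        # tallies for the q and p updates done in the same pass
        ptf = np.ascontiguousarray(p.transpose(1, 2, 0)).reshape(L * jmax, K)
        u = rng.random(obs_ind.size)
        zc, ac = count_fn(q, ptf, u, obs_ind, flat_base, n, K, L * jmax)

        # -- q | z
        q = _sample_rows(alpha + zc, rng)

        # -- p | z
        ac = ac.reshape(K, L, jmax)
        if correlated:
            prior = pi[None, :, :] * ((1.0 - f) / f)[:, None, None]
        else:
            prior = np.where(valid, lam, 0.0)[None, :, :]
        p = _sample_simplex_3d(np.where(valid[None], prior + ac, 0.0), valid, rng)

        logp = np.log(np.clip(p, 1e-300, None))
        if correlated:
            f = _update_f(f, pi, logp, valid, opts.f_proposal_sd, rng)
            pi = _update_pi(pi, f, logp, valid, lam, opts.pi_proposal_conc, rng)

        alpha = _update_alpha(alpha, q, opts, rng)
        if estimate_lambda_flag:
            # under the F-model lambda is the prior on pi; otherwise on each p_k
            logx = np.log(np.clip(pi, 1e-300, None))[None] if correlated else logp
            lam = _update_lambda(lam, logx, valid, opts, rng)

        if sweep >= opts.burnin and (sweep - opts.burnin) % opts.record_interval == opts.record_interval - 1:
            ptf = np.ascontiguousarray(p.transpose(1, 2, 0)).reshape(L * jmax, K)
            mix = np.einsum("ck,ck->c", q[obs_ind], ptf[flat_base])
            ll_trace[rec] = np.log(np.clip(mix, 1e-300, None)).sum()
            a_trace[rec] = alpha
            lam_trace[rec] = lam
            if f_trace is not None:
                f_trace[rec] = f
            q_sum += q
            p_sum += p
            if q_draws is not None:
                q_draws[rec] = q
            rec += 1

    q_mean = q_sum / max(rec, 1)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    p_mean = p_sum / max(rec, 1)
    return StructureRun(
        K=K,
        Q=QMatrix(q_mean, list(genotypes.individual_ids)),
        P=p_mean,
        n_alleles=n_alleles,
        alpha_trace=a_trace[:rec],
        lambda_=lam if estimate_lambda_flag else float(lam),
        lambda_trace=lam_trace[:rec],
        loglik_trace=ll_trace[:rec],
        f_trace=None if f_trace is None else f_trace[:rec],
        burnin_steps=opts.burnin,
        sample_steps=opts.iterations,
        record_interval=opts.record_interval,
        seed=opts.seed,
        q_draws=q_draws[:rec] if q_draws is not None else None,
    )


def _initial_soft_assignment(
    K: int, n: int, counts0: np.ndarray, obs_ind, obs_loc, obs_allele,
    jmax: int, method: str, rng: np.random.Generator,
) -> np.ndarray:
    """Soft individual-to-cluster start (n x K weights) from PCA + k-means.

    The collapsed "no structure" state is strongly self-trapping under the
    correlated-frequencies model (a collapse drives F towards 0, whose tight
    prior then pins every cluster to the ancestral frequencies), so a decent
    initial partition matters far more than in the uncorrelated model. The
    leading principal components of the centred one-hot dosage matrix carry
    the population signal; k-means with several restarts on them places the
    cluster centres, and a Gaussian kernel on the centre distances turns the
    labels into soft weights, so intermediate individuals start mixed instead
    of being forced into one cluster. ``method="random"`` gives uniform
    weights (a cold start).
    """
    if K == 1:
        return np.ones((n, 1))
    if method == "kmeans":
        L = counts0.shape[0]
        dosage = np.bincount((obs_ind * L + obs_loc) * jmax + obs_allele,
                             minlength=n * L * jmax).reshape(n, L * jmax).astype(float)
        x = dosage - dosage.mean(axis=0)
        try:
            from scipy.cluster.vq import kmeans2

            n_pc = min(max(K - 1, 2), min(x.shape) - 1)
            u, s, _ = np.linalg.svd(x, full_matrices=False)
            pcs = u[:, :n_pc] * s[:n_pc]
            best, best_inertia = None, np.inf
            for _ in range(10):
                cent, assign = kmeans2(pcs, K, minit="++", seed=rng, iter=30)
                inertia = float(((pcs - cent[assign]) ** 2).sum())
                if inertia < best_inertia and np.unique(assign).size == K:
                    best, best_inertia = (cent, assign), inertia
            if best is not None:
                cent, assign = best
                d2 = ((pcs[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
                scale = max(0.25 * best_inertia / n, 1e-12)  # sharpened within-cluster scale
                w = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * scale))
                return w / w.sum(axis=1, keepdims=True)
        except Exception:
            pass
    return np.full((n, K), 1.0 / K)


def _sample_rows(shapes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    g = rng.gamma(np.clip(shapes, 1e-12, None))
    s = g.sum(axis=1, keepdims=True)
    bad = s[:, 0] <= 0
    if np.any(bad):
        g[bad] = 1.0
        s = g.sum(axis=1, keepdims=True)
    return g / s


def _floor_simplex(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    x = np.where(valid, np.clip(x, _PI_FLOOR, None), 0.0)
    return x / x.sum(axis=-1, keepdims=True)


def _sample_simplex(shapes: np.ndarray, valid: np.ndarray, rng) -> np.ndarray:
    g = np.where(valid, rng.gamma(np.clip(shapes, 1e-12, None) * valid + ~valid), 0.0)
    s = g.sum(axis=-1, keepdims=True)
    bad = s[..., 0] <= 0
    if np.any(bad):
        g[bad] = valid[bad].astype(float)
        s = g.sum(axis=-1, keepdims=True)
    out = g / s
    # keep sampled frequencies strictly positive on the support
    return _floor_simplex(out, valid) if np.any(out[valid] <= 0) else out


def _sample_simplex_3d(shapes: np.ndarray, valid: np.ndarray, rng) -> np.ndarray:
    return _sample_simplex(shapes, np.broadcast_to(valid, shapes.shape), rng)


def _f_logdensity(conc: float, pi: np.ndarray, logp_k: np.ndarray, valid: np.ndarray) -> float:
    return float(_dirichlet_logpdf(logp_k, np.where(valid, conc * pi, 1.0), valid).sum())


def _update_f(f, pi, logp, valid, step_sd, rng) -> np.ndarray:
    """Logit-scale random-walk Metropolis on each cluster's drift F_k."""
    out = f.copy()
    for k in range(f.size):
        cur = out[k]
        logit = np.log(cur / (1.0 - cur)) + rng.normal(0.0, step_sd)
        prop = 1.0 / (1.0 + np.exp(-logit))
        if not (0.0 < prop < 1.0):
            continue
        ld_cur = _f_logdensity((1.0 - cur) / cur, pi, logp[k], valid)
        ld_prop = _f_logdensity((1.0 - prop) / prop, pi, logp[k], valid)
        # uniform prior on F; Jacobian of the logit transform
        log_acc = ld_prop - ld_cur + np.log(prop * (1 - prop)) - np.log(cur * (1 - cur))
        if np.log(rng.random()) < log_acc:
            out[k] = prop
    return out


def _update_pi(pi, f, logp, valid, lam, conc0, rng) -> np.ndarray:
    """Per-locus Metropolis-Hastings on the ancestral frequencies pi_l."""
    prop = _sample_simplex(np.where(valid, conc0 * pi + 0.1, 0.0), valid, rng)
    prop = _floor_simplex(prop, valid)
    log_pi, log_prop = np.log(pi + ~valid), np.log(prop + ~valid)
    conc = (1.0 - f) / f  # (K,)

    def target(x, logx):
        t = _dirichlet_logpdf(logx, np.where(valid, lam, 1.0), valid)  # prior
        for k in range(f.size):
            t = t + _dirichlet_logpdf(logp[k], np.where(valid, conc[k] * x, 1.0), valid)
        return t

    fwd = _dirichlet_logpdf(log_prop, np.where(valid, conc0 * pi + 0.1, 1.0), valid)
    bwd = _dirichlet_logpdf(log_pi, np.where(valid, conc0 * prop + 0.1, 1.0), valid)
    log_acc = target(prop, log_prop) - target(pi, log_pi) + bwd - fwd
    accept = np.log(rng.random(pi.shape[0])) < log_acc
    out = np.where(accept[:, None], prop, pi)
    return out


def _update_alpha(alpha, q, opts, rng, n_steps: int = 10) -> float:
    """Random-walk Metropolis on the shared Dirichlet concentration alpha.

    Several sub-steps per sweep (the sufficient statistic of q is fixed
    within a sweep, so extra steps are nearly free and shorten the slow
    random walk from the initial value).
    """
    n, k = q.shape
    s = np.log(np.clip(q, 1e-300, None)).sum()

    def ld(a):
        return n * (gammaln(k * a) - k * gammaln(a)) + (a - 1.0) * s

    ld_cur = ld(alpha)
    for _ in range(n_steps):
        prop = alpha + rng.normal(0.0, opts.alpha_proposal_sd)
        if not (0.0 < prop <= opts.alpha_prior_max):
            continue
        ld_prop = ld(prop)
        if np.log(rng.random()) < ld_prop - ld_cur:
            alpha, ld_cur = prop, ld_prop
    return alpha


def _update_lambda(lam, logx, valid, opts, rng) -> float:
    """Metropolis on the Dirichlet concentration of the frequency prior.

    ``logx`` is (R, L, J): the simplexes the prior applies to (each cluster's
    p under the uncorrelated model; pi under the correlated model).
    """
    prop = lam + rng.normal(0.0, opts.lambda_proposal_sd)
    if not (0.0 < prop <= opts.lambda_prior_max):
        return lam
    v = np.broadcast_to(valid, logx.shape)

    def ld(a):
        return float(_dirichlet_logpdf(logx, np.where(v, a, 1.0), v).sum())

    return prop if np.log(rng.random()) < ld(prop) - ld(lam) else lam


def estimate_lambda(
    genotypes: GenotypeMatrix,
    opts: McmcOptions | None = None,
    n_replicates: int = 3,
) -> float:
    """Estimate the allele-frequency prior concentration lambda at K = 1.

    Runs the K = 1 sampler with lambda under a Metropolis update and a
    uniform prior on (0, lambda_prior_max], and averages the posterior-mean
    lambda across replicate runs (distinct seeds derived from opts.seed).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    opts = opts or McmcOptions()
    estimates = []
    for r in range(n_replicates):
        o = replace(opts.with_seed(opts.seed + r), lambda_="estimate")
        run = run_admixture_mcmc(genotypes, K=1, opts=o)
        estimates.append(run.lambda_mean)
    return float(np.mean(estimates))


def replicate_runs(
    genotypes: GenotypeMatrix,
    K_range: list[int] | range,
    n_replicates: int = 10,
    opts: McmcOptions | None = None,
) -> dict[tuple[int, int], StructureRun]:
    """Independent replicate runs over a range of K, keyed by (K, replicate).

    Seeds are derived deterministically from ``opts.seed`` so the whole grid
    is reproducible while replicates stay independent.
    """
    ks = list(K_range)
    if not ks:
        raise ValueError("K_range must be non-empty")
    opts = opts or McmcOptions()
    runs: dict[tuple[int, int], StructureRun] = {}
    for i, k in enumerate(ks):
        for r in range(n_replicates):
            runs[(k, r)] = run_admixture_mcmc(
                genotypes, k, opts.with_seed(opts.seed + 1000 * i + r)
            )
    return runs
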