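"""Paired SNP/microsatellite data simulator with known admixture truth.

The generative model mirrors the admixture model with correlated allele
frequencies (the F-model): per locus an ancestral frequency vector pi_l is
drawn from a symmetric Dirichlet(lambda_sim); each of K populations drifts
around it, p_kl ~ Dirichlet(pi_l * (1 - F_k) / F_k); each individual i has
ancestry q_i ~ Dirichlet(alpha, ..., alpha); every allele copy picks an
origin population from q_i and then an allele from that population's
frequencies. Both marker panels (biallelic SNPs and multiallelic
microsatellites) are generated from the SAME individual ancestries, which is
what makes cross-marker comparisons of inferred structure meaningful.

A spatial diversity cline (southern refugium, northward expansion) is
emulated by serial founder events: localities are ordered along a latitude
axis and each locality's allele frequencies are a drifted resample of its
southern neighbour's, so expected heterozygosity declines northwards at a
configurable per-degree rate. This is a deliberately simple stand-in for a
range expansion, not a coalescent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, QMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "ContaminationPlan",
    "simulate_dataset",
    "inject_missing",
    "make_dart_report",
    "plant_low_maf",
]


@dataclass
class SimConfig:
    """Generative parameters for one paired-marker dataset.

    ``alpha_sim`` is the Dirichlet concentration of individual admixture
    (small values give near-pure individuals); ``F_k`` are per-population
    drift parameters of the correlated-frequencies model, each in (0, 1) and
    roughly equal to the expected FST of that population from the ancestral
    pool. ``gradient_slope`` is the expected change in standardized
    heterozygosity per degree latitude (negative = poorer in the north);
    0 disables the founder-event cline so the data follow the plain F-model.
    """

    K_true: int = 2
    n_individuals: int = 60
    n_snp_loci: int = 300
    n_microsat_loci: int = 15
    alpha_sim: float = 0.1
    F_k: tuple[float, ...] | None = None
    microsat_allele_count: int = 8
    missing_rate: float = 0.0
    n_localities: int = 6
    gradient_slope: float = 0.0
    lambda_sim: float = 1.0
    lat_south: float = 36.0
    lat_north: float = 44.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if min(self.n_individuals, self.n_snp_loci, self.n_microsat_loci) < 1:
            raise ValueError("sizes must be positive")
        if self.F_k is None:
            self.F_k = tuple([0.1] * self.K_true)
        self.F_k = tuple(float(f) for f in self.F_k)
        if len(self.F_k) != self.K_true:
            raise ValueError("F_k must have one entry per population")
        if any(not (0.0 < f < 1.0) for f in self.F_k):
            raise ValueError("all F_k must lie in the open interval (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.microsat_allele_count < 2:
            raise ValueError("microsat_allele_count must be >= 2")
        if self.n_localities < 1 or self.n_localities > self.n_individuals:
            raise ValueError("need 1 <= n_localities <= n_individuals")
        if self.alpha_sim <= 0 or self.lambda_sim <= 0:
            raise ValueError("alpha_sim and lambda_sim must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for parameter-recovery tests.

    ``ancestral_freqs`` and ``population_freqs`` are keyed by marker
    (``"snp"``/``"microsat"``); population frequencies are those of the
    base (southernmost) locality. ``locality_freqs`` holds the per-locality
    drifted frequencies, shape (n_localities, K, L, J).
    """

    true_Q: QMatrix
    ancestral_freqs: dict[str, np.ndarray]
    population_freqs: dict[str, np.ndarray]
    locality_freqs: dict[str, np.ndarray]
    coordinates: pd.DataFrame  # per locality: locality, latitude, longitude
    locality_ids: list[str] = field(default_factory=list)
    config: SimConfig | None = None


def _dirichlet_rows(shape_params: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample Dirichlet draws row-wise from an array of shape parameters.

    Zero shape parameters yield exact zeros (that allele is already lost),
    which is the correct degenerate limit for founder resampling.
    """
    g = rng.gamma(np.clip(shape_params, 0.0, None))
    totals = g.sum(axis=-1, keepdims=True)
    # guard: a row that underflowed entirely keeps its previous mass pattern
    bad = totals[..., 0] <= 0.0
    if np.any(bad):
        g[bad] = shape_params[bad]
        totals = g.sum(axis=-1, keepdims=True)
    return g / totals


def _population_freqs(
    pi: np.ndarray, F_k: tuple[float, ...], rng: np.random.Generator
) -> np.ndarray:
    """Draw p_kl ~ Dirichlet(pi_l (1-F_k)/F_k) -> shape (K, L, J)."""
    out = np.empty((len(F_k),) + pi.shape)
    for k, f in enumerate(F_k):
        out[k] = _dirichlet_rows(pi * ((1.0 - f) / f), rng)
    return out


def _founder_cline(
    base: np.ndarray,
    latitudes: np.ndarray,
    slope: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Serial founder events northward: shape (M, K, L, J).

    Each locality's frequencies are a Dirichlet resample of its southern
    neighbour's with drift tuned so expected heterozygosity shrinks by a
    factor (1 - |slope|) per degree of latitude (on the standardized scale
    where dataset-mean heterozygosity is ~1, the fitted linear slope then
    recovers ``slope``).
    """
    m = latitudes.size
    out = np.empty((m,) + base.shape)
    out[0] = base
    rate = abs(slope)
    for i in range(1, m):
        gap = latitudes[i] - latitudes[i - 1]
        keep = (1.0 - rate) ** gap  # expected-het retention across the gap
        if keep >= 1.0:
            out[i] = out[i - 1]
            continue
        f_step = 1.0 - keep
        conc = (1.0 - f_step) / f_step
        out[i] = _dirichlet_rows(out[i - 1] * conc, rng)
    return out


def _sample_genotypes(
    q: np.ndarray,
    loc_freqs: np.ndarray,
    locality_index: np.ndarray,
    allele_labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (N, L, 2) genotypes: origin k ~ q_i, allele ~ p^{loc(i)}_{kl}."""
    n, k = q.shape
    _, _, l, j = loc_freqs.shape
    # population of origin for each of the 2L copies of each individual
    u = rng.random((n, l, 2))
    qcum = np.cumsum(q, axis=1)
    z = (u[..., None] > qcum[:, None, None, :]).sum(axis=-1)
    z = np.minimum(z, k - 1)
    # allele draw from the locality-specific population frequencies
    li = locality_index[:, None, None] * np.ones((1, l, 2), dtype=int)
    lj = np.arange(l)[None, :, None] * np.ones((n, 1, 2), dtype=int)
    probs = loc_freqs[li, z, lj, :]  # (N, L, 2, J)
    pcum = np.cumsum(probs, axis=-1)
    pcum /= pcum[..., -1:]
    u2 = rng.random((n, l, 2))
    a = (u2[..., None] > pcum).sum(axis=-1)
    a = np.minimum(a, j - 1)
    return allele_labels[a]


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate one paired SNP/microsatellite dataset.

    Returns ``(snp_genotypes, microsat_genotypes, dart_report, truth)``.
    Both genotype matrices share individuals and true ancestries; the DArT
    locus report is clean (no planted quality violations) — use
    :func:`make_dart_report` with a :class:`ContaminationPlan` to plant
    filter-rule violations with known identities.
    """
    rng = np.random.default_rng(config.seed)
    k = config.K_true
    n = config.n_individuals

    # localities along the expansion (latitude) axis, south to north
    m = config.n_localities
    if m == 1:
        lats = np.array([config.lat_south])
    else:
        lats = np.linspace(config.lat_south, config.lat_north, m)
    lons = rng.uniform(-9.0, 2.0, size=m)
    locality_names = [f"L{i:02d}" for i in range(m)]
    blocks = np.array_split(np.arange(n), m)
    locality_index = np.empty(n, dtype=int)
    for i, b in enumerate(blocks):
        locality_index[b] = i
    locality_ids = [locality_names[i] for i in locality_index]

    # individual ancestries, shared by both marker panels
    q = rng.dirichlet([config.alpha_sim] * k, size=n) if k > 1 else np.ones((n, 1))
    true_q = QMatrix(q, [f"ind{i:03d}" for i in range(n)])

    panels: dict[str, dict] = {}
    for marker, n_loci, j, labels in (
        ("snp", config.n_snp_loci, 2, np.array([0, 1])),
        (
            "microsat",
            config.n_microsat_loci,
            config.microsat_allele_count,
            8 + np.arange(config.microsat_allele_count),
        ),
    ):
        pi = rng.dirichlet([config.lambda_sim] * j, size=n_loci)
        p = _population_freqs(pi, config.F_k, rng)
        if config.gradient_slope != 0.0 and m > 1:
            loc_freqs = _founder_cline(p, lats, config.gradient_slope, rng)
        else:
            loc_freqs = np.broadcast_to(p, (m,) + p.shape).copy()
        alleles = _sample_genotypes(q, loc_freqs, locality_index, labels, rng)
        panels[marker] = {"pi": pi, "p": p, "loc": loc_freqs, "alleles": alleles}

    snp = GenotypeMatrix(
        panels["snp"]["alleles"],
        list(true_q.individual_ids),
        [f"snp{i:05d}" for i in range(config.n_snp_loci)],
        locality_ids=locality_ids,
        marker_type="snp",
    )
    msat = GenotypeMatrix(
        panels["microsat"]["alleles"],
        list(true_q.individual_ids),
        [f"ms{i:03d}" for i in range(config.n_microsat_loci)],
        locality_ids=locality_ids,
        marker_type="microsat",
    )
    if config.missing_rate > 0:
        snp = inject_missing(snp, config.missing_rate, seed=int(rng.integers(2**31)))
        msat = inject_missing(msat, config.missing_rate, seed=int(rng.integers(2**31)))

    report = make_dart_report(snp, ContaminationPlan(), seed=int(rng.integers(2**31)))
    truth = SimTruth(
        true_Q=true_q,
        ancestral_freqs={mk: panels[mk]["pi"] for mk in panels},
        population_freqs={mk: panels[mk]["p"] for mk in panels},
        locality_freqs={mk: panels[mk]["loc"] for mk in panels},
        coordinates=pd.DataFrame(
            {"locality": locality_names, "latitude": lats, "longitude": lons}
        ),
        locality_ids=locality_ids,
        config=config,
    )
    return snp, msat, report, truth


def inject_missing(genotypes: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each genotype call (both allele copies) missing with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must be in [0, 1)")
    out = genotypes.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((out.n_individuals, out.n_loci)) < rate
    out.alleles[mask] = MISSING
    return out


@dataclass
class ContaminationPlan:
    """Planted quality violations for a synthetic DArT locus report.

    Each field names the loci (by id) that will violate one filter rule,
    with values chosen on the failing side of the default threshold; all
    other loci get clean values (RepAvg 0.99, balanced reads 0.5, coverage
    equal to the report median). ``contig_groups`` lists groups of loci
    placed on a shared contig with strictly decreasing RepAvg (first member
    highest), so the expected survivor of the one-SNP-per-contig rule is the
    group's first element.
    """

    low_repavg: list[str] = field(default_factory=list)
    unbalanced: list[str] = field(default_factory=list)
    high_coverage: list[str] = field(default_factory=list)
    contig_groups: list[list[str]] = field(default_factory=list)
    repavg_value: float = 0.90
    unbalanced_value: float = 0.10
    base_coverage: float = 20.0
    coverage_value: float = 80.0  # > 3.5 x the 20.0 median


def make_dart_report(
    genotypes: GenotypeMatrix,
    plan: ContaminationPlan | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate a per-locus DArT-style quality report for a SNP panel.

    Columns: ``locus_id, contig_id, rep_avg, locus_call_rate, mean_coverage,
    allele_read_proportion``. Call rate is computed from the genotypes; all
    other fields are clean defaults unless the plan plants a violation.
    """
    if genotypes.marker_type != "snp":
        raise ValueError("DArT locus reports apply to SNP panels only")
    plan = plan or ContaminationPlan()
    rng = np.random.default_rng(seed)
    ids = list(genotypes.locus_ids)
    known = set(ids)
    for group in ([plan.low_repavg, plan.unbalanced, plan.high_coverage]
                  + list(plan.contig_groups)):
        stray = set(group) - known
        if stray:
            raise ValueError(f"plan references unknown loci: {sorted(stray)}")

    df = pd.DataFrame(
        {
            "locus_id": ids,
            "contig_id": [f"ctg_{i}" for i in ids],
            "rep_avg": 0.99,
            "locus_call_rate": genotypes.locus_call_rate(),
            "mean_coverage": plan.base_coverage,
            "allele_read_proportion": 0.5,
        }
    ).set_index("locus_id", drop=False)

    df.loc[plan.low_repavg, "rep_avg"] = plan.repavg_value
    df.loc[plan.unbalanced, "allele_read_proportion"] = plan.unbalanced_value
    df.loc[plan.high_coverage, "mean_coverage"] = plan.coverage_value
    for g, group in enumerate(plan.contig_groups):
        df.loc[group, "contig_id"] = f"shared_{g}"
        # strictly decreasing RepAvg, all above the RepAvg threshold
        df.loc[group, "rep_avg"] = [0.99 - 0.005 * i for i in range(len(group))]
    # small clean jitter on coverage keeps the median at base_coverage
    jitter = rng.uniform(-0.5, 0.5, size=len(ids))
    clean = ~df["locus_id"].isin(plan.high_coverage)
    df.loc[clean, "mean_coverage"] = plan.base_coverage + jitter[clean.to_numpy()]
    return df.reset_index(drop=True)


def plant_low_maf(
    genotypes: GenotypeMatrix, locus_ids: list[str], minor_copies: int = 1
) -> GenotypeMatrix:
    """Rewrite loci so they carry exactly ``minor_copies`` minor-allele copies.

    Used to plant known minor-allele-frequency violations: with N diploid
    individuals the resulting MAF is ``minor_copies / (2 N)``. Calls at the
    planted loci are made fully observed.
    """
    out = genotypes.copy()
    pos = {lid: i for i, lid in enumerate(out.locus_ids)}
    for lid in locus_ids:
        l = pos[lid]
        out.alleles[:, l, :] = 0
        for c in range(minor_copies):
            out.alleles[c // 2, l, c % 2] = 1
    return out
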