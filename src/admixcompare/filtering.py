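"""DArT-style SNP quality filtering with a per-step audit trail.

The chain reproduces a standard reduced-representation cleanup, applied in
this order: individual call rate, locus repeatability (RepAvg), allele
read-balance, excess coverage (paralog screen), locus call rate (recomputed
after the individual filter), one SNP per contig (keeping the most
repeatable), and minor-allele frequency. Threshold comparisons are strict
where the rule is phrased as an inequality: individuals are kept when call
rate > 0.35, loci when RepAvg > 0.95, read balance is kept on the closed
interval [0.15, 0.85], loci are dropped when coverage > 3.5 x the median,
when call rate < 0.8, or when MAF < 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "FilterParams",
    "FilterStep",
    "FilterReport",
    "filter_individual_callrate",
    "apply_locus_filters",
    "full_filter_chain",
]


@dataclass
class FilterParams:
    """Thresholds of the filter chain (defaults are the standard ones)."""

    individual_callrate: float = 0.35
    rep_avg: float = 0.95
    balance: tuple[float, float] = (0.15, 0.85)
    coverage_multiplier: float = 3.5
    locus_callrate: float = 0.8
    maf: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.individual_callrate <= 1.0):
            raise ValueError("individual_callrate must be in (0, 1]")
        lo, hi = self.balance
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("balance window must satisfy 0 <= lo < hi <= 1")


@dataclass
class FilterStep:
    name: str
    n_individuals_before: int
    n_individuals_after: int
    n_loci_before: int
    n_loci_after: int
    removed_ids: list[str]


@dataclass
class FilterReport:
    """Ordered audit of the chain; counts never increase along it."""

    steps: list[FilterStep] = field(default_factory=list)

    def removed(self, step_name: str) -> list[str]:
        for s in self.steps:
            if s.name == step_name:
                return list(s.removed_ids)
        raise KeyError(step_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.name for s in self.steps],
                "n_individuals_before": [s.n_individuals_before for s in self.steps],
                "n_individuals_after": [s.n_individuals_after for s in self.steps],
                "n_loci_before": [s.n_loci_before for s in self.steps],
                "n_loci_after": [s.n_loci_after for s in self.steps],
                "removed_ids": [";".join(s.removed_ids) for s in self.steps],
            }
        )


def filter_individual_callrate(
    genotypes: GenotypeMatrix, threshold: float = 0.35
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep individuals whose proportion of called loci is strictly > threshold."""
    if genotypes.n_individuals == 0 or genotypes.n_loci == 0:
        raise ValueError("empty genotype matrix")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    rates = genotypes.individual_call_rate()
    keep = rates > threshold
    removed = [genotypes.individual_ids[i] for i in np.flatnonzero(~keep)]
    return genotypes.subset(individuals=np.flatnonzero(keep)), removed


def _drop(
    genotypes: GenotypeMatrix,
    drop_ids: set[str],
    name: str,
    report: FilterReport,
) -> GenotypeMatrix:
    keep_idx = [i for i, lid in enumerate(genotypes.locus_ids) if lid not in drop_ids]
    out = genotypes.subset(loci=keep_idx)
    report.steps.append(
        FilterStep(
            name=name,
            n_individuals_before=genotypes.n_individuals,
            n_individuals_after=out.n_individuals,
            n_loci_before=genotypes.n_loci,
            n_loci_after=out.n_loci,
            removed_ids=sorted(drop_ids),
        )
    )
    return out


def apply_locus_filters(
    genotypes: GenotypeMatrix,
    report: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the locus-level filter chain in its canonical order.

    ``report`` must carry one record per genotyped locus with columns
    ``locus_id, contig_id, rep_avg, mean_coverage, allele_read_proportion``.
    Locus call rate and MAF are recomputed from the genotype matrix passed
    in (i.e., after any individual filtering), not taken from the report.
    """
    params = params or FilterParams()
    meta = report.set_index("locus_id")
    missing = [lid for lid in genotypes.locus_ids if lid not in meta.index]
    if missing:
        raise ValueError(f"no report record for loci: {missing[:5]}...")
    audit = FilterReport()
    g = genotypes

    # 1. repeatability
    rep = meta.loc[g.locus_ids, "rep_avg"].to_numpy(float)
    g = _drop(g, {lid for lid, r in zip(g.locus_ids, rep) if not r > params.rep_avg},
              "rep_avg", audit)

    # 2. allele read balance, kept on the closed window
    lo, hi = params.balance
    bal = meta.loc[g.locus_ids, "allele_read_proportion"].to_numpy(float)
    g = _drop(g, {lid for lid, b in zip(g.locus_ids, bal) if not (lo <= b <= hi)},
              "read_balance", audit)

    # 3. excess coverage relative to the median of loci still in play
    cov = meta.loc[g.locus_ids, "mean_coverage"].to_numpy(float)
    cutoff = params.coverage_multiplier * float(np.median(cov))
    g = _drop(g, {lid for lid, c in zip(g.locus_ids, cov) if c > cutoff},
              "coverage", audit)

    # 4. locus call rate, recomputed on the current matrix
    cr = g.locus_call_rate()
    g = _drop(g, {lid for lid, c in zip(g.locus_ids, cr) if c < params.locus_callrate},
              "locus_callrate", audit)

    # 5. one SNP per contig: keep greatest rep_avg; ties -> call rate, then id
    cr = dict(zip(g.locus_ids, g.locus_call_rate()))
    by_contig: dict[str, list[str]] = {}
    for lid in g.locus_ids:
        by_contig.setdefault(str(meta.at[lid, "contig_id"]), []).append(lid)
    drop: set[str] = set()
    for members in by_contig.values():
        if len(members) > 1:
            best = min(members, key=lambda lid: (-meta.at[lid, "rep_avg"], -cr[lid], lid))
            drop.update(m for m in members if m != best)
    g = _drop(g, drop, "one_snp_per_contig", audit)

    # 6. minor-allele frequency from non-missing allele copies
    maf = g.minor_allele_frequency()
    g = _drop(g, {lid for lid, f in zip(g.locus_ids, maf) if np.isfinite(f) and f < params.maf},
              "maf", audit)
    return g, audit


def full_filter_chain(
    genotypes: GenotypeMatrix,
    report: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Individual call-rate filter followed by the locus chain, one audit."""
    params = params or FilterParams()
    kept, removed_inds = filter_individual_callrate(genotypes, params.individual_callrate)
    filtered, audit = apply_locus_filters(kept, report, params)
    audit.steps.insert(
        0,
        FilterStep(
            name="individual_callrate",
            n_individuals_before=genotypes.n_individuals,
            n_individuals_after=kept.n_individuals,
            n_loci_before=genotypes.n_loci,
            n_loci_after=genotypes.n_loci,
            removed_ids=removed_inds,
        ),
    )
    return filtered, audit
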