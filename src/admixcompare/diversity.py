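"""Individual heterozygosity and its spatial distribution.

Standardized multilocus heterozygosity (sMLH) is the proportion of an
individual's typed loci that are heterozygous, divided by the mean dataset
heterozygosity of those same loci; with complete data the individual values
average exactly 1, so sMLH expresses diversity relative to the panel.
Locality medians, the SNP-vs-microsatellite Pearson correlation, and linear
latitude/longitude gradient models summarize its geography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "GradientFit",
    "smlh",
    "locality_medians",
    "marker_correlation",
    "spatial_gradient",
]


@dataclass
class GradientFit:
    """OLS fit of sMLH ~ intercept + latitude + longitude (decimal degrees)."""

    beta_latitude: float
    beta_longitude: float
    p_latitude: float
    p_longitude: float
    intercept: float
    n: int
    r_squared: float


def smlh(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-individual standardized multilocus heterozygosity.

    sMLH_i = (fraction of i's typed loci heterozygous) / (mean over i's
    typed loci of the dataset heterozygosity h_l), where h_l is the fraction
    of typed individuals heterozygous at locus l. Loci with h_l = 0
    (monomorphic in the sample) carry no information and are excluded.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least two individuals")
    het = genotypes.heterozygous()  # (N, L) with NaN for missing
    with np.errstate(invalid="ignore"):
        h_l = np.nanmean(het, axis=0)
    informative = np.nan_to_num(h_l) > 0.0
    if not informative.any():
        raise ValueError("all loci are monomorphic; sMLH undefined")
    het = het[:, informative]
    h_l = h_l[informative]
    typed = ~np.isnan(het)
    if (typed.sum(axis=1) == 0).any():
        bad = [genotypes.individual_ids[i]
               for i in np.flatnonzero(typed.sum(axis=1) == 0)]
        raise ValueError(f"individuals typed at no informative loci: {bad}")
    num = np.nansum(het, axis=1) / typed.sum(axis=1)
    denom = (typed * h_l).sum(axis=1) / typed.sum(axis=1)
    return num / denom


def locality_medians(values: np.ndarray, locality_ids: list[str]) -> pd.Series:
    """Median value per locality (even counts -> midpoint of central pair)."""
    s = pd.Series(np.asarray(values, float), index=pd.Index(locality_ids, name="locality"))
    return s.groupby(level="locality", sort=True).median()


def marker_correlation(smlh_a: np.ndarray, smlh_b: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p between paired per-individual sMLH vectors."""
    a, b = np.asarray(smlh_a, float), np.asarray(smlh_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero variance in an sMLH vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def spatial_gradient(
    values: np.ndarray, latitudes: np.ndarray, longitudes: np.ndarray
) -> GradientFit:
    """OLS of a diversity measure on latitude and longitude.

    Coefficients are in sMLH units per decimal degree, with two-sided
    t-test p-values; a rank-deficient (collinear) design is an error.
    """
    y = np.asarray(values, float)
    x = np.column_stack([np.asarray(latitudes, float), np.asarray(longitudes, float)])
    if y.size < 4 or x.shape[0] != y.size:
        raise ValueError("need n >= 4 with matching coordinates")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear coordinates: gradient model is singular")
    fit = sm.OLS(y, design).fit()
    return GradientFit(
        beta_latitude=float(fit.params[1]),
        beta_longitude=float(fit.params[2]),
        p_latitude=float(fit.pvalues[1]),
        p_longitude=float(fit.pvalues[2]),
        intercept=float(fit.params[0]),
        n=int(y.size),
        r_squared=float(fit.rsquared),
    )
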