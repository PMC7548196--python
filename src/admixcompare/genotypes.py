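"""Core containers: diploid genotype matrices and ancestry (Q) matrices.

A :class:`GenotypeMatrix` stores diploid allele calls for N individuals at
L loci as an integer array of shape (N, L, 2). Allele labels are arbitrary
integers (0/1 for biallelic SNPs, repeat counts for microsatellites); the
missing code is ``-9`` (STRUCTURE convention) and always applies to both
copies of a call. A :class:`QMatrix` stores N x K ancestry proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -9


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for N individuals x L loci.

    Parameters
    ----------
    alleles
        Integer array (N, L, 2) of allele labels; ``-9`` marks a missing call.
    individual_ids, locus_ids
        Unique string labels for rows and loci.
    locality_ids
        Optional per-individual sampling-locality labels.
    marker_type
        ``"snp"`` or ``"microsat"``; drives format defaults and filters.
    """

    alleles: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    locality_ids: list[str] | None = None
    marker_type: str = "snp"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (N, L, 2)")
        n, l, _ = self.alleles.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if len(self.locus_ids) != l:
            raise ValueError("locus_ids length mismatch")
        if self.locality_ids is not None and len(self.locality_ids) != n:
            raise ValueError("locality_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_calls(self) -> np.ndarray:
        """Boolean (N, L): True where the call is missing (either copy -9)."""
        return (self.alleles == MISSING).any(axis=2)

    def individual_call_rate(self) -> np.ndarray:
        """Proportion of loci with a call, per individual."""
        return 1.0 - self.missing_calls().mean(axis=1)

    def locus_call_rate(self) -> np.ndarray:
        """Proportion of individuals with a call, per locus."""
        return 1.0 - self.missing_calls().mean(axis=0)

    def heterozygous(self) -> np.ndarray:
        """Float (N, L): 1.0 heterozygous, 0.0 homozygous, NaN missing."""
        het = (self.alleles[:, :, 0] != self.alleles[:, :, 1]).astype(float)
        het[self.missing_calls()] = np.nan
        return het

    def allele_frequencies(self, locus: int) -> dict[int, float]:
        """Frequencies of observed alleles at one locus (missing skipped)."""
        copies = self.alleles[:, locus, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            return {}
        labels, counts = np.unique(copies, return_counts=True)
        return {int(a): c / copies.size for a, c in zip(labels, counts)}

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-locus MAF from non-missing allele copies (NaN if no calls).

        For loci with more than two alleles this is the frequency of the
        rarest observed allele; monomorphic loci have MAF 0.
        """
        maf = np.full(self.n_loci, np.nan)
        for l in range(self.n_loci):
            freqs = self.allele_frequencies(l)
            if not freqs:
                continue
            maf[l] = 0.0 if len(freqs) == 1 else min(freqs.values())
        return maf

    def dense_coding(self) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
        """Recode allele labels as dense per-locus indices 0..J_l-1.

        Returns ``(coded, n_alleles, labels)`` where ``coded`` is (N, L, 2)
        with ``-1`` for missing, ``n_alleles[l] = J_l`` and ``labels[l]``
        maps the dense index back to the original label. Loci where only one
        allele was observed keep J_l = max(observed, 1).
        """
        coded = np.full_like(self.alleles, -1)
        n_alleles = np.zeros(self.n_loci, dtype=np.int64)
        labels: list[np.ndarray] = []
        for l in range(self.n_loci):
            copies = self.alleles[:, l, :]
            observed = np.unique(copies[copies != MISSING])
            labels.append(observed)
            n_alleles[l] = max(observed.size, 1)
            ok = copies != MISSING
            coded[:, l, :][ok] = np.searchsorted(observed, copies[ok])
        return coded, n_alleles, labels

    def subset(
        self,
        individuals: np.ndarray | list[int] | None = None,
        loci: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset of individuals and/or loci (copies data)."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            alleles=self.alleles[np.ix_(ind, loc)].copy(),
            individual_ids=[self.individual_ids[i] for i in ind],
            locus_ids=[self.locus_ids[j] for j in loc],
            locality_ids=None
            if self.locality_ids is None
            else [self.locality_ids[i] for i in ind],
            marker_type=self.marker_type,
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(self, alleles=self.alleles.copy())


@dataclass
class QMatrix:
    """N x K matrix of individual ancestry proportions.

    Rows sum to one; columns are interchangeable cluster labels (label
    switching between runs is resolved by :mod:`admixcompare.qcompare`).
    """

    values: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Q must be 2-D (N x K)")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.values.shape[0])]
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("individual_ids length mismatch")
        if (self.values < -1e-12).any():
            raise ValueError("ancestry proportions must be non-negative")
        rows = self.values.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1 within 1e-9")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def permute_columns(self, perm: np.ndarray | list[int]) -> "QMatrix":
        """Return a copy with column ``j`` taken from input column ``perm[j]``."""
        perm = np.asarray(perm)
        return QMatrix(self.values[:, perm].copy(), list(self.individual_ids))
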