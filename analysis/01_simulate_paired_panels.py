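#!/usr/bin/env python
"""Generate the reference paired-marker dataset used by the later steps.

Two marker panels for the same 60 individuals from a two-population system
(drift F = 0.05 per population, Dirichlet(0.05) admixture, 6 localities,
5% missing calls): 300 biallelic SNPs with a DArT-style locus report, and
12 eight-allele microsatellite loci. Writes STRUCTURE files, the locus
report, the locality table and the true ancestry matrix under results/data/.
"""

from pathlib import Path

from admixcompare import SimConfig, simulate_dataset
from admixcompare.io import (
    write_localities,
    write_locus_report,
    write_qmatrix,
    write_structure_file,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

config = SimConfig(
    K_true=2, n_individuals=60, n_snp_loci=300, n_microsat_loci=12,
    alpha_sim=0.05, F_k=(0.05, 0.05), microsat_allele_count=8,
    missing_rate=0.05, n_localities=6, seed=20,
)


def main() -> None:
    snp, msat, report, truth = simulate_dataset(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_structure_file(snp, OUT / "snp_genotypes.str")
    write_structure_file(msat, OUT / "microsat_genotypes.str")
    write_locus_report(report, OUT / "locus_report.csv")
    write_localities(truth.coordinates, OUT / "localities.csv")
    write_qmatrix(truth.true_Q, OUT / "true_Q.txt")
    print(f"simulated {snp.n_individuals} individuals: "
          f"{snp.n_loci} SNPs ({snp.missing_calls().mean():.1%} missing), "
          f"{msat.n_loci} microsatellite loci "
          f"({msat.missing_calls().mean():.1%} missing)")
    print(f"true K = {config.K_true}; outputs in {OUT}")


if __name__ == "__main__":
    main()
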