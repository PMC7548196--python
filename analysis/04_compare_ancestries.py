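#!/usr/bin/env python
"""Align replicate Q-matrices within and across markers; SSC, modes and CA.

Reads the clustering runs from step 03 and, at each K: computes all pairwise
aligned SSC values (intra-SNP, intra-microsatellite and cross-marker),
detects modes among replicates, averages the major-mode consensus per
locality, and computes the Coefficient of Admixture. Writes a long-format
SSC table, a mode summary and per-individual CA under results/comparison/.
"""

import json
from collections import defaultdict
from pathlib import Path

import pandas as pd

from admixcompare.io import read_qmatrix, read_structure_file
from admixcompare.qcompare import (
    average_by_locality,
    coefficient_of_admixture,
    find_modes,
    pairwise_ssc_matrix,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    runs = defaultdict(list)  # (marker, K) -> [QMatrix]
    for path in sorted((ROOT / "clustering" / "runs").glob("*_Q.txt")):
        marker, ktag, _, _ = path.stem.split("_")
        runs[(marker, int(ktag[1:]))].append(read_qmatrix(path))
    out = ROOT / "comparison"
    out.mkdir(parents=True, exist_ok=True)

    rows, ca_rows, mode_summary = [], [], {}
    ks = sorted({k for _, k in runs if k >= 2})
    for k in ks:
        qs, labels, markers = [], [], []
        for marker in ("snp", "microsat"):
            for i, q in enumerate(runs[(marker, k)]):
                qs.append(q)
                labels.append(f"{marker}_r{i}")
                markers.append(marker)
        sim = pairwise_ssc_matrix(qs, labels)
        for i in range(len(qs)):
            for j in range(i + 1, len(qs)):
                rows.append({"K": k, "run_a": labels[i], "run_b": labels[j],
                             "marker_a": markers[i], "marker_b": markers[j],
                             "ssc": float(sim.iloc[i, j])})
        for marker in ("snp", "microsat"):
            modes = find_modes(runs[(marker, k)], threshold=0.9)
            mode_summary[f"{marker}_k{k}"] = {
                "n_modes": len(modes.groups),
                "major_mode_size": len(modes.groups[modes.major_mode]),
            }
            consensus = modes.consensus_Q[modes.major_mode]
            for ind, ca in zip(consensus.individual_ids,
                               coefficient_of_admixture(consensus).ca):
                ca_rows.append({"marker": marker, "K": k, "individual": ind,
                                "ca": float(ca)})

    ssc = pd.DataFrame(rows)
    ssc.to_csv(out / "ssc_pairs.csv", index=False)
    pd.DataFrame(ca_rows).to_csv(out / "ca_individuals.csv", index=False)
    (out / "modes.json").write_text(json.dumps(mode_summary, indent=2, sort_keys=True))

    # locality-averaged consensus at the smallest multi-cluster K
    k0 = ks[0]
    snp_modes = find_modes(runs[("snp", k0)], threshold=0.9)
    consensus = snp_modes.consensus_Q[snp_modes.major_mode]
    snp = read_structure_file(ROOT / "data" / "snp_genotypes.str", has_locality=True)
    loc_q = average_by_locality(consensus, list(snp.locality_ids))
    pd.DataFrame(loc_q.values, index=loc_q.individual_ids).to_csv(
        out / f"snp_k{k0}_locality_mean_ancestry.csv")

    same = ssc[(ssc.marker_a == ssc.marker_b)]
    cross = ssc[(ssc.marker_a != ssc.marker_b)]
    print("intra-marker SSC:  min %.2f  median %.2f" % (same.ssc.min(), same.ssc.median()))
    print("inter-marker SSC:  min %.2f  median %.2f" % (cross.ssc.min(), cross.ssc.median()))
    for key, v in sorted(mode_summary.items()):
        print(f"{key}: {v['n_modes']} mode(s), major mode holds {v['major_mode_size']} runs")


if __name__ == "__main__":
    main()
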