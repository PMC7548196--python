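#!/usr/bin/env python
"""sMLH per marker, locality medians, cross-marker correlation and gradients.

Computes standardized multilocus heterozygosity on a dedicated cline dataset
(southern-refugium founder expansion, expected slope -0.08 sMLH units per
degree latitude) for both marker panels, correlates the two, and fits the
latitude/longitude linear model. Writes tables under results/diversity/.
"""

import json
from pathlib import Path

import pandas as pd

from admixcompare import SimConfig, simulate_dataset
from admixcompare.diversity import locality_medians, marker_correlation, smlh, spatial_gradient

ROOT = Path(__file__).resolve().parents[1] / "results"

config = SimConfig(
    K_true=1, n_individuals=90, n_snp_loci=500, n_microsat_loci=12,
    microsat_allele_count=8, n_localities=9, gradient_slope=-0.08, seed=33,
)


def main() -> None:
    snp, msat, _, truth = simulate_dataset(config)
    coords = truth.coordinates.set_index("locality")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    results = {}
    values = {}
    for marker, geno in (("snp", snp), ("microsat", msat)):
        v = smlh(geno)
        values[marker] = v
        pd.DataFrame({"individual": geno.individual_ids, "smlh": v}).to_csv(
            out / f"smlh_{marker}.csv", index=False)
        locality_medians(v, geno.locality_ids).rename("median_smlh").to_csv(
            out / f"smlh_medians_{marker}.csv")
        fit = spatial_gradient(
            v,
            coords.loc[list(geno.locality_ids), "latitude"].to_numpy(float),
            coords.loc[list(geno.locality_ids), "longitude"].to_numpy(float),
        )
        results[marker] = fit.__dict__
        print(f"{marker}: beta_lat = {fit.beta_latitude:+.3f} (p = {fit.p_latitude:.2g}), "
              f"beta_lon = {fit.beta_longitude:+.3f} (p = {fit.p_longitude:.2g})")

    r, p = marker_correlation(values["snp"], values["microsat"])
    results["cross_marker"] = {"pearson_r": r, "p_value": p, "n": len(values["snp"])}
    print(f"cross-marker sMLH correlation: r = {r:.2f} (p = {p:.2g})")
    (out / "gradients.json").write_text(json.dumps(results, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
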