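"""End-to-end pipeline: filter -> cluster -> K selection -> comparison -> diversity.

The pipeline is configured by a single mapping (usually loaded from YAML,
see ``load_config``) and writes every artifact under an output directory
with a JSON manifest of parameters and seeds. A single top-level seed
deterministically derives all per-run seeds, so replicate runs are
independent but the whole analysis reproduces byte-identically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import McmcOptions, estimate_lambda, replicate_runs
from .diversity import locality_medians, marker_correlation, smlh, spatial_gradient
from .filtering import FilterParams, full_filter_chain
from .io import (
    read_localities,
    read_locus_report,
    read_structure_file,
    write_localities,
    write_locus_report,
    write_qmatrix,
    write_structure_file,
)
from .kselect import k_selection_table
from .qcompare import coefficient_of_admixture, find_modes, pairwise_ssc_matrix
from .simulate import SimConfig, simulate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure; earlier artifacts are kept on disk."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``simulate`` holds :class:`SimConfig` parameters (synthetic
    input, written to the output directory first), or the four input paths
    point at existing files. MCMC settings are per marker; the K grid and
    replicate count apply to both markers.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict | None = None
    snp_genotypes: str | None = None
    microsat_genotypes: str | None = None
    locus_report: str | None = None
    localities: str | None = None
    filter_params: dict = field(default_factory=dict)
    snp_mcmc: dict = field(default_factory=lambda: {"burnin": 300, "iterations": 300,
                                                    "record_interval": 5})
    microsat_mcmc: dict = field(default_factory=lambda: {"burnin": 300, "iterations": 300,
                                                         "record_interval": 5,
                                                         "lambda_": 1.0})
    k_min: int = 1
    k_max: int = 4
    n_replicates: int = 3
    mode_threshold: float = 0.9
    estimate_snp_lambda: bool = True
    lambda_replicates: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max <= 20):
            raise ValueError("K range must satisfy 1 <= k_min <= k_max <= 20")
        if self.simulate is None:
            for name in ("snp_genotypes", "microsat_genotypes", "locus_report"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path {name!r} missing or unresolvable: {p}")

    @classmethod
    def from_mapping(cls, cfg: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full comparison pipeline; returns artifact paths.

    Stages: load/simulate -> SNP filtering -> lambda estimation ->
    replicate clustering over the K grid for both markers -> K-selection
    table (GR, Pr[X|K], delta-K, parsimony index) -> mode detection ->
    cross-marker SSC -> coefficient of admixture -> sMLH, cross-marker
    correlation and spatial gradients. Any stage failure raises
    :class:`PipelineError` tagged with the stage name; artifacts written by
    earlier stages stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    snp, msat, report, localities = _load_inputs(config, out, artifacts)
    snp_f, audit = _filter_stage(config, snp, report, out, artifacts)
    lam = _lambda_stage(config, snp_f, artifacts, out)
    runs = _cluster_stage(config, snp_f, msat, lam, out, artifacts)
    tables = _kselect_stage(runs, out, artifacts)
    _compare_stage(config, runs, out, artifacts)
    _diversity_stage(config, snp_f, msat, localities, out, artifacts)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "artifacts": artifacts,
        "n_runs": len(runs),
        "k_range": [config.k_min, config.k_max],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


@_stage("load")
def _load_inputs(config: PipelineConfig, out: Path, artifacts: dict):
    if config.simulate is not None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
        snp, msat, report, truth = simulate_dataset(sim_cfg)
        write_structure_file(snp, out / "snp_genotypes.str")
        write_structure_file(msat, out / "microsat_genotypes.str")
        write_locus_report(report, out / "locus_report.csv")
        write_localities(truth.coordinates, out / "localities.csv")
        write_qmatrix(truth.true_Q, out / "true_Q.txt")
        artifacts.update(
            snp_genotypes=str(out / "snp_genotypes.str"),
            microsat_genotypes=str(out / "microsat_genotypes.str"),
            locus_report=str(out / "locus_report.csv"),
            localities=str(out / "localities.csv"),
            true_Q=str(out / "true_Q.txt"),
        )
        localities = truth.coordinates
        return snp, msat, report, localities
    snp = read_structure_file(config.snp_genotypes, has_locality=True, marker_type="snp")
    msat = read_structure_file(config.microsat_genotypes, has_locality=True,
                               marker_type="microsat")
    report = read_locus_report(config.locus_report)
    localities = None  # loaded lazily at the diversity stage
    return snp, msat, report, localities


@_stage("filter")
def _filter_stage(config: PipelineConfig, snp, report, out: Path, artifacts: dict):
    params = FilterParams(**config.filter_params)
    filtered, audit = full_filter_chain(snp, report, params)
    write_structure_file(filtered, out / "snp_filtered.str")
    audit.to_frame().to_csv(out / "filter_report.csv", index=False)
    artifacts["snp_filtered"] = str(out / "snp_filtered.str")
    artifacts["filter_report"] = str(out / "filter_report.csv")
    return filtered, audit


@_stage("lambda")
def _lambda_stage(config: PipelineConfig, snp_f, artifacts: dict, out: Path) -> float:
    if not config.estimate_snp_lambda:
        lam = float(config.snp_mcmc.get("lambda_", 1.0))
    else:
        opts = McmcOptions(**{**config.snp_mcmc, "seed": config.seed + 17})
        lam = estimate_lambda(snp_f, opts, n_replicates=config.lambda_replicates)
    (out / "lambda.json").write_text(json.dumps({"snp_lambda": lam}))
    artifacts["lambda"] = str(out / "lambda.json")
    return lam


@_stage("cluster")
def _cluster_stage(config, snp_f, msat, lam, out: Path, artifacts: dict):
    runs: dict[str, dict] = {}
    run_dir = out / "runs"
    run_dir.mkdir(exist_ok=True)
    grids = {
        "snp": (snp_f, McmcOptions(**{**config.snp_mcmc, "lambda_": lam,
                                      "seed": config.seed + 1000})),
        "microsat": (msat, McmcOptions(**{**config.microsat_mcmc,
                                          "seed": config.seed + 2000})),
    }
    for marker, (geno, opts) in grids.items():
        grid = replicate_runs(geno, range(config.k_min, config.k_max + 1),
                              n_replicates=config.n_replicates, opts=opts)
        runs[marker] = grid
        for (k, r), run in grid.items():
            write_qmatrix(run.Q, run_dir / f"{marker}_k{k}_r{r}_Q.txt")
            pd.DataFrame(
                {"step": np.arange(len(run.loglik_trace)) * run.record_interval,
                 "loglik": run.loglik_trace, "alpha": run.alpha_trace}
            ).to_csv(run_dir / f"{marker}_k{k}_r{r}_trace.csv", index=False)
    artifacts["runs_dir"] = str(run_dir)
    return runs


@_stage("kselect")
def _kselect_stage(runs, out: Path, artifacts: dict):
    tables = {}
    for marker, grid in runs.items():
        table = k_selection_table(grid)
        table.to_csv(out / f"kselect_{marker}.csv", index=False)
        artifacts[f"kselect_{marker}"] = str(out / f"kselect_{marker}.csv")
        tables[marker] = table
    return tables


@_stage("compare")
def _compare_stage(config, runs, out: Path, artifacts: dict):
    rows = []
    ca_rows = []
    for k in range(max(config.k_min, 2), config.k_max + 1):
        qs, labels, markers = [], [], []
        for marker, grid in runs.items():
            for (kk, r), run in sorted(grid.items()):
                if kk == k:
                    qs.append(run.Q)
                    labels.append(f"{marker}_k{k}_r{r}")
                    markers.append(marker)
        sim = pairwise_ssc_matrix(qs, labels)
        for i in range(len(qs)):
            for j in range(i + 1, len(qs)):
                rows.append({"K": k, "run_a": labels[i], "run_b": labels[j],
                             "marker_a": markers[i], "marker_b": markers[j],
                             "ssc": sim.iloc[i, j]})
        # per-marker modes and consensus CA at this K
        for marker, grid in runs.items():
            member_qs = [run.Q for (kk, r), run in sorted(grid.items()) if kk == k]
            modes = find_modes(member_qs, threshold=config.mode_threshold)
            consensus = modes.consensus_Q[modes.major_mode]
            profile = coefficient_of_admixture(consensus)
            for ind, ca in zip(consensus.individual_ids, profile.ca):
                ca_rows.append({"marker": marker, "K": k, "individual": ind, "ca": ca})
    pd.DataFrame(rows).to_csv(out / "ssc_pairs.csv", index=False)
    pd.DataFrame(ca_rows).to_csv(out / "ca_individuals.csv", index=False)
    artifacts["ssc_pairs"] = str(out / "ssc_pairs.csv")
    artifacts["ca_individuals"] = str(out / "ca_individuals.csv")


@_stage("diversity")
def _diversity_stage(config, snp_f, msat, localities, out: Path, artifacts: dict):
    if localities is None:
        if config.localities is None or not Path(config.localities).exists():
            raise ValueError(
                f"locality table not found: {config.localities!r} — "
                "diversity stage needs locality coordinates"
            )
        localities = read_localities(config.localities)
    coords = localities.set_index("locality")
    results = {}
    values = {}
    for marker, geno in (("snp", snp_f), ("microsat", msat)):
        v = smlh(geno)
        values[marker] = (geno, v)
        pd.DataFrame({"individual": geno.individual_ids, "smlh": v}).to_csv(
            out / f"smlh_{marker}.csv", index=False
        )
        artifacts[f"smlh_{marker}"] = str(out / f"smlh_{marker}.csv")
        if geno.locality_ids is None:
            raise ValueError(f"{marker} genotypes carry no locality labels")
        med = locality_medians(v, geno.locality_ids)
        med.rename("median_smlh").to_csv(out / f"smlh_medians_{marker}.csv")
        lats = coords.loc[list(geno.locality_ids), "latitude"].to_numpy(float)
        lons = coords.loc[list(geno.locality_ids), "longitude"].to_numpy(float)
        fit = spatial_gradient(v, lats, lons)
        results[marker] = asdict(fit)
    shared = sorted(
        set(values["snp"][0].individual_ids) & set(values["microsat"][0].individual_ids)
    )
    if len(shared) >= 3:
        a = pd.Series(values["snp"][1], index=values["snp"][0].individual_ids)[shared]
        b = pd.Series(values["microsat"][1],
                      index=values["microsat"][0].individual_ids)[shared]
        r, p = marker_correlation(a.to_numpy(), b.to_numpy())
        results["cross_marker"] = {"pearson_r": r, "p_value": p, "n": len(shared)}
    (out / "diversity.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    artifacts["diversity"] = str(out / "diversity.json")
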