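"""Readers and writers for the on-disk formats.

STRUCTURE genotype text (two-row and one-row-per-individual dialects,
missing code -9), CLUMPP-style Q-matrix text, CSV locus reports and
locality tables, and YAML pipeline configuration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, QMatrix

__all__ = [
    "read_structure_file",
    "write_structure_file",
    "read_qmatrix",
    "write_qmatrix",
    "read_locus_report",
    "write_locus_report",
    "read_localities",
    "write_localities",
    "load_config",
]


def write_structure_file(
    genotypes: GenotypeMatrix, path: str | Path, dialect: str = "two-row"
) -> None:
    """Write a STRUCTURE-format genotype file.

    Two-row dialect: one line per allele copy (two per individual), columns
    ``id [locality] locus1 ... locusL``. One-row dialect: one line per
    individual with the two copies of each locus in adjacent columns.
    The locality column is written when the matrix carries locality ids.
    A locus-name header row (L tokens, the common STRUCTURE convention) is
    written first so locus identities survive the round trip.
    """
    if dialect not in ("two-row", "one-row"):
        raise ValueError("dialect must be 'two-row' or 'one-row'")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(" ".join(genotypes.locus_ids) + "\n")
        for i, ind in enumerate(genotypes.individual_ids):
            prefix = [ind]
            if genotypes.locality_ids is not None:
                prefix.append(genotypes.locality_ids[i])
            if dialect == "two-row":
                for c in (0, 1):
                    row = genotypes.alleles[i, :, c]
                    fh.write(" ".join(prefix + [str(int(a)) for a in row]) + "\n")
            else:
                flat = genotypes.alleles[i].reshape(-1)  # l1c1 l1c2 l2c1 ...
                fh.write(" ".join(prefix + [str(int(a)) for a in flat]) + "\n")


def read_structure_file(
    path: str | Path,
    dialect: str = "two-row",
    has_locality: bool = False,
    marker_type: str = "snp",
) -> GenotypeMatrix:
    """Parse a STRUCTURE-format genotype file written by either dialect."""
    if dialect not in ("two-row", "one-row"):
        raise ValueError("dialect must be 'two-row' or 'one-row'")
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty STRUCTURE file: {path}")
    locus_names: list[str] | None = None
    if len(lines) > 1 and len(lines[0]) != len(lines[1]):
        locus_names = lines.pop(0)  # optional locus-name header row
    widths = {len(ln) for ln in lines}
    if len(widths) != 1:
        raise ValueError("ragged rows in STRUCTURE file")
    meta_cols = 2 if has_locality else 1
    n_tokens = widths.pop() - meta_cols
    if n_tokens < 1:
        raise ValueError("no genotype columns found")

    ids: list[str] = []
    locs: list[str] | None = [] if has_locality else None
    rows: list[list[int]] = []
    for ln in lines:
        ids.append(ln[0])
        if has_locality:
            locs.append(ln[1])  # type: ignore[union-attr]
        try:
            rows.append([int(t) for t in ln[meta_cols:]])
        except ValueError as err:
            raise ValueError(f"non-integer genotype token in {path}: {err}") from None

    data = np.asarray(rows, dtype=np.int64)
    if dialect == "two-row":
        if len(lines) % 2:
            raise ValueError("two-row dialect requires an even number of rows")
        n = len(lines) // 2
        for i in range(n):
            if ids[2 * i] != ids[2 * i + 1]:
                raise ValueError(f"row pair mismatch for individual {ids[2 * i]!r}")
        alleles = np.stack([data[0::2], data[1::2]], axis=2)
        ind_ids = ids[0::2]
        localities = locs[0::2] if locs is not None else None
        n_loci = n_tokens
        if locus_names is not None and len(locus_names) != n_loci:
            raise ValueError("locus-name header width does not match genotype columns")
    else:
        if n_tokens % 2:
            raise ValueError("one-row dialect requires an even number of genotype columns")
        n_loci = n_tokens // 2
        alleles = data.reshape(len(lines), n_loci, 2)
        ind_ids = ids
        localities = locs
        if locus_names is not None and len(locus_names) != n_loci:
            raise ValueError("locus-name header width does not match genotype columns")
    return GenotypeMatrix(
        alleles=alleles,
        individual_ids=ind_ids,
        locus_ids=locus_names or [f"locus{i:05d}" for i in range(n_loci)],
        locality_ids=localities,
        marker_type=marker_type,
    )


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    """Write one row per individual: id then K ancestry proportions."""
    with Path(path).open("w") as fh:
        for ind, row in zip(q.individual_ids, q.values):
            fh.write(ind + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_qmatrix(path: str | Path) -> QMatrix:
    """Read Q-matrix text; a leading non-numeric column is taken as ids."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty Q-matrix file: {path}")

    def _is_float(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_ids = not _is_float(lines[0][0])
    ids = [ln[0] for ln in lines] if has_ids else []
    vals = np.array([[float(t) for t in ln[1 if has_ids else 0:]] for ln in lines])
    vals = vals / vals.sum(axis=1, keepdims=True)  # absorb rounding from text
    return QMatrix(vals, ids or [f"ind{i}" for i in range(len(lines))])


_REPORT_COLUMNS = [
    "locus_id", "contig_id", "rep_avg", "locus_call_rate",
    "mean_coverage", "allele_read_proportion",
]


def write_locus_report(report: pd.DataFrame, path: str | Path) -> None:
    report[_REPORT_COLUMNS].to_csv(path, index=False)


def read_locus_report(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a DArT-style locus report CSV.

    ``column_map`` maps canonical names (e.g. ``"rep_avg"``) to the column
    names used in the file, for vendor exports with different headers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus report missing columns: {missing}")
    return df[_REPORT_COLUMNS]


def write_localities(coords: pd.DataFrame, path: str | Path) -> None:
    coords[["locality", "latitude", "longitude"]].to_csv(path, index=False)


def read_localities(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("locality", "latitude", "longitude") if c not in df.columns]
    if missing:
        raise ValueError(f"locality table missing columns: {missing}")
    df["locality"] = df["locality"].astype(str)
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration into a plain mapping."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg
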