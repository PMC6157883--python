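"""Readers and writers for UMI tables and result files.

The canonical input is a three-column TSV (gene, umi, reads).  A per-read
"umi-group" format — one row per read, as exported by UMI-grouping tools —
is collapsed to per-UMI read counts on input.  All outputs are TSV with
headers and floats at 6 significant digits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pipeline import GENE_COLUMNS, FitDiagnostics

__all__ = ["read_umitable", "write_umitable", "write_results"]

FLOAT_FORMAT = "%.6g"


def _fail(path, line, msg):
    where = f"{path}:{line}" if line is not None else str(path)
    raise ValueError(f"{where}: {msg}")


def read_umitable(path, format: str = "canonical-tsv") -> pd.DataFrame:
    """Read a per-UMI read-count table.

    ``canonical-tsv`` expects columns gene, umi, reads (one row per UMI);
    duplicated (gene, umi) pairs are summed with a warning.
    ``umi-group-tsv`` expects one row per read with a gene column and a
    ``final_umi`` (or ``umi``) column; rows are counted per (gene, umi).
    """
    if format not in ("canonical-tsv", "umi-group-tsv"):
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        _fail(path, None, "empty file")
    if format == "umi-group-tsv":
        umi_col = "final_umi" if "final_umi" in df.columns else "umi"
        missing = {"gene", umi_col} - set(df.columns)
        if missing:
            _fail(path, 1, f"missing columns {sorted(missing)}")
        out = (
            df.groupby(["gene", umi_col], sort=True)
            .size()
            .reset_index(name="reads")
            .rename(columns={umi_col: "umi"})
        )
        return out

    missing = {"gene", "umi", "reads"} - set(df.columns)
    if missing:
        _fail(path, 1, f"missing columns {sorted(missing)}")
    reads = pd.to_numeric(df["reads"], errors="coerce")
    bad = reads.isna() | (reads != reads.round())
    if bad.any():
        _fail(path, int(bad.idxmax()) + 2, "non-integer read count")
    df = df.assign(reads=reads.astype(np.int64))
    nonpos = df["reads"] < 1
    if nonpos.any():
        _fail(path, int(nonpos.idxmax()) + 2, "read count must be >= 1")
    dup = df.duplicated(["gene", "umi"])
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate (gene, umi) rows summed",
            stacklevel=2,
        )
        df = df.groupby(["gene", "umi"], sort=True, as_index=False)["reads"].sum()
    return df[["gene", "umi", "reads"]].reset_index(drop=True)


def write_umitable(table: pd.DataFrame, path) -> None:
    """Write the canonical (gene, umi, reads) TSV; truth labels dropped."""
    table[["gene", "umi", "reads"]].to_csv(path, sep="\t", index=False)


def write_results(
    genes: pd.DataFrame,
    summary: dict,
    diagnostics: FitDiagnostics | None,
    genes_path=None,
    summary_path=None,
    plot_data_path=None,
) -> None:
    """Write the per-gene table, library summary and diagnostics TSVs."""
    if genes_path is not None:
        genes[GENE_COLUMNS].to_csv(
            genes_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
    if summary_path is not None:
        pd.DataFrame([summary]).to_csv(
            summary_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
    if plot_data_path is not None and diagnostics is not None:
        diagnostics.histogram.to_csv(
            plot_data_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
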