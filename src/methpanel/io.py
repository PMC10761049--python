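"""Readers and writers for the pipeline's on-disk formats.

Beta matrices travel as TSV (rows = CpG IDs, columns = sample IDs, header
row) with a sidecar sample sheet (sample_id, group[, batch]); WGBS counts
as Bismark CpG-report TSV (7 columns, no header); Ct tables and clinical
metadata as CSV; gene models as BED6 (0-based half-open, converted to
1-based inclusive on read) or a TSV with an explicit TSS column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, GeneModel

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_cpg_report",
    "write_cpg_report",
    "read_bed_genes",
    "read_ct_csv",
    "read_clinical_csv",
    "write_json",
]

_REPORT_COLUMNS = [
    "chromosome",
    "position",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


def read_beta_tsv(path, sample_sheet) -> BetaMatrix:
    """Read a beta matrix TSV plus its sample sheet into a BetaMatrix.

    Values must parse as reals in [0, 1]; the token ``NA`` (or an empty
    cell) marks a missing entry. Duplicate site or sample IDs and samples
    missing from the sheet are rejected.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    arr = values.to_numpy()
    bad = np.argwhere(
        ~np.isnan(arr.astype(float)) & ((arr.astype(float) < 0) | (arr.astype(float) > 1))
    )
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"beta value out of [0, 1] at site {values.index[r]!r}, "
            f"sample {values.columns[c]!r}: {arr[r, c]}"
        )
    sheet = pd.read_csv(sample_sheet, sep="\t")
    unknown = set(sheet["sample_id"]) - set(values.columns)
    if unknown:
        raise ValueError(f"sample sheet lists unknown samples: {sorted(unknown)[:5]}")
    groups = sheet.set_index("sample_id")["group"]
    missing = values.columns.difference(groups.index)
    if len(missing):
        raise ValueError(f"sample sheet does not cover: {list(missing)[:5]}")
    return BetaMatrix(values, groups)


def write_beta_tsv(matrix: BetaMatrix, path, sample_sheet) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="site_id", na_rep="NA")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": matrix.groups.values}
    ).to_csv(sample_sheet, sep="\t", index=False)


def read_cpg_report(path, cpg_only: bool = False) -> pd.DataFrame:
    """Read a Bismark-dialect CpG report (7-column TSV, no header)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_REPORT_COLUMNS)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_REPORT_COLUMNS)
    for col in ("count_methylated", "count_unmethylated"):
        counts = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0) | (counts % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"malformed {col} at line {int(bad[0]) + 1} of {path}"
            )
        df[col] = counts.astype(int)
    bad_strand = df.index[~df["strand"].isin(["+", "-"])]
    if len(bad_strand):
        raise ValueError(f"malformed strand at line {int(bad_strand[0]) + 1} of {path}")
    df["position"] = pd.to_numeric(df["position"]).astype(int)
    if cpg_only:
        df = df[df["context"] == "CpG"].reset_index(drop=True)
    return df


def write_cpg_report(df: pd.DataFrame, path) -> None:
    df[_REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed_genes(path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, name, score, strand)."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{i}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chromosome=chrom,
                    strand=strand,
                    gene_start=int(start) + 1,  # 0-based half-open -> 1-based
                    gene_end=int(end),
                )
            )
    return genes


def read_ct_csv(path) -> pd.DataFrame:
    """Read a Ct table CSV; an empty ct cell means undetermined (NaN)."""
    df = pd.read_csv(path)
    required = {"plate_id", "sample_id", "gene", "well_role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    determined = df["ct"].dropna()
    if (determined <= 0).any():
        raise ValueError("determined Ct values must be positive")
    return df


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if "group" not in df or "sample_id" not in df:
        raise ValueError("clinical table needs sample_id and group columns")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
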