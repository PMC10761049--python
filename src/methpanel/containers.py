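"""Core in-memory containers shared across pipeline stages.

The central container is :class:`BetaMatrix`, a sites x samples matrix of
array methylation beta values (fraction methylated, in [0, 1]) together with
a per-sample group label. Downstream stages exchange plain pandas objects
(DataFrames of per-CpG counts, Ct tables, clinical tables) plus the small
record dataclasses defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "DmcRecord",
    "DmrRecord",
    "GeneModel",
    "StandardCurveFit",
    "RocCurve",
]


class BetaMatrix:
    """Sites x samples matrix of methylation beta values with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by CpG site ID, columns by sample ID. Entries are
        beta values in [0, 1]; NaN marks a missing measurement.
    groups : pandas.Series
        Per-sample group label (e.g. ``tumour`` / ``normal`` / ``blood`` or a
        cancer-type code), indexed by sample ID. Must cover every column.
    """

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        values = pd.DataFrame(values)
        groups = pd.Series(groups)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site IDs: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        missing = values.columns.difference(groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {list(missing)[:5]}")
        arr = values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        self.values = values
        self.groups = groups.reindex(values.columns)

    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_sites(self, site_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(site_ids)], self.groups)

    def __repr__(self) -> str:  # pragma: no cover
        n_sites, n_samples = self.shape
        return f"BetaMatrix({n_sites} sites x {n_samples} samples)"


@dataclass
class DmcRecord:
    """A differentially methylated CpG site from the array screen."""

    site_id: str
    p_value: float
    fold_change: float
    direction: str  # "hyper" | "hypo"
    mean_tumour: float
    mean_normal: float
    q_value: float = float("nan")
    blood_mean: float = float("nan")
    hyper_set: frozenset = field(default_factory=frozenset)


@dataclass
class DmrRecord:
    """A differentially methylated region: >= 2 nearby same-direction DMCs."""

    chromosome: str
    start: int  # 1-based inclusive position of the first member DMC
    end: int  # 1-based inclusive position of the last member DMC
    n_dmcs: int
    mean_delta: float  # mean (tumour beta - normal beta) over member DMCs
    direction: str
    short_span: bool = False  # span below the minimum reporting span

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Minimal gene interval with a strand-aware transcription start site."""

    gene_id: str
    chromosome: str
    strand: str
    gene_start: int  # 1-based inclusive
    gene_end: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.gene_start > self.gene_end:
            raise ValueError(f"gene_start > gene_end for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end


@dataclass
class StandardCurveFit:
    """Least-squares fit of Ct on log10(copies) for a qPCR dilution series.

    Amplification efficiency (percent) is ``(10 ** (-1 / slope) - 1) * 100``;
    a perfect doubling per cycle gives slope -1/log10(2) and 100% efficiency.
    """

    copies: np.ndarray
    cts: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    accepted: bool
    reason: str = ""


@dataclass
class RocCurve:
    """Empirical ROC with AUC (percent), DeLong 95% CI and Youden cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float  # percent, in [0, 100]
    ci_low: float
    ci_high: float
    youden_cutoff: float
    youden_sens: float  # percent
    youden_spec: float  # percent

    @property
    def youden_index(self) -> float:
        return (self.youden_sens + self.youden_spec) / 100.0 - 1.0
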