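"""Methylation-expression correlation and median-split survival analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = ["meth_expr_correlation", "km_survival", "KmResult"]


def meth_expr_correlation(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation of per-CpG methylation with target-gene expression.

    ``methylation`` is sites x samples (beta), ``expression`` genes x
    samples (log-scale expected); samples must match and be ordered
    identically. Returns (coefficients, p_values) as sites x genes frames.
    Spearman (rank) correlation is the primary statistic; Pearson is
    available via ``method="pearson"``. A constant vector has undefined
    correlation and is reported NA.
    """
    if list(methylation.columns) != list(expression.columns):
        raise ValueError("methylation and expression must share sample order")
    if methylation.shape[1] < 3:
        raise ValueError("need >= 3 complete sample pairs")
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown method {method!r}")
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr

    coef = pd.DataFrame(index=methylation.index, columns=expression.index, dtype=float)
    pval = coef.copy()
    for site in methylation.index:
        x = methylation.loc[site].to_numpy(dtype=float)
        for gene in expression.index:
            y = expression.loc[gene].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined, stays NaN
            r, p = corr_fn(x, y)
            coef.loc[site, gene] = r
            pval.loc[site, gene] = p
    return coef, pval


@dataclass
class KmResult:
    """Median-split Kaplan-Meier comparison."""

    groups: pd.Series  # "high" / "low" per sample
    median: float
    logrank_p: float
    curves: dict  # group -> survival-function DataFrame (index time, col S(t))

    @property
    def significant(self) -> bool:
        return self.logrank_p < 0.05


def km_survival(records: pd.DataFrame) -> KmResult:
    """Kaplan-Meier comparison of high vs low methylation groups.

    ``records`` columns: sample_id, time, event, meth_value. Samples above
    the median methylation form the high group; ties at the median go to
    the low group. Overall survival curves are estimated per group and
    compared with a two-sided log-rank test (p < 0.05 declared
    significant by convention).
    """
    for col in ("time", "event", "meth_value"):
        if col not in records:
            raise ValueError(f"records missing column {col!r}")
    if (records["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if int(records["event"].sum()) < 2:
        raise ValueError("need >= 2 events in total")
    median = float(records["meth_value"].median())
    groups = pd.Series(
        np.where(records["meth_value"] > median, "high", "low"),
        index=records.index,
    )
    if groups.nunique() < 2:
        raise ValueError("methylation is constant: cannot form two groups")

    high = records[groups == "high"]
    low = records[groups == "low"]
    curves = {}
    for name, sub in (("high", high), ("low", low)):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=name)
        curves[name] = kmf.survival_function_
    res = logrank_test(
        high["time"], low["time"],
        event_observed_A=high["event"], event_observed_B=low["event"],
    )
    return KmResult(
        groups=groups, median=median, logrank_p=float(res.p_value), curves=curves
    )
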