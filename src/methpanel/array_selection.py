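"""Array-based DMC screening cascade for blood-detectable tumour markers.

The cascade selects CpG sites hypermethylated in tumour tissue that are
also usable in plasma: (1) KNN-impute missing beta values; (2) per-site
rank-sum differential test plus a fold-change filter (tumour/normal mean
ratio >= 2) on each dataset; (3) intersect the candidate lists across
datasets; (4) keep the candidates with the lowest methylation in healthy
whole blood (leukocyte background); (5) keep sites hypermethylated (mean
beta > 0.3) in at most ``max_hyper_cancer_types`` cancer types, one of
which must be the required type (liver, LIHC) — tissue specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, DmcRecord

__all__ = [
    "SelectionConfig",
    "impute_knn",
    "adjust_batches",
    "find_dmcs",
    "intersect_dmcs",
    "rank_by_blood",
    "pancancer_filter",
    "select_markers",
]

_LOGIT_EPS = 1e-6


@dataclass
class SelectionConfig:
    """Thresholds of the screening cascade (defaults as printed)."""

    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    blood_top_n: int = 30
    pancancer_beta_threshold: float = 0.3
    max_hyper_cancer_types: int = 2
    required_cancer_type: str = "LIHC"
    knn_k: int = 10
    epsilon_guard: float = 1e-3

    def __post_init__(self):
        for name in ("p_threshold", "fc_threshold", "pancancer_beta_threshold",
                     "epsilon_guard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.blood_top_n < 1:
            raise ValueError("blood_top_n must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def impute_knn(matrix: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing beta values from the k nearest CpG sites.

    A missing entry (site, sample) is replaced by the mean value of that
    sample at the ``k`` sites nearest to the target site (nan-aware
    Euclidean distance over shared observed samples). Observed entries are
    unchanged; imputed values are clipped to [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.values
    all_missing = values.index[values.isna().all(axis=1)]
    if len(all_missing):
        raise ValueError(
            f"sites with no observed values cannot be imputed: "
            f"{list(all_missing)[:10]}"
        )
    if not values.isna().any().any():
        return matrix
    if len(values) - 1 < k:
        raise ValueError(
            f"k={k} exceeds the {len(values) - 1} available neighbour sites"
        )
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed = imputer.fit_transform(values.to_numpy(dtype=float))
    imputed = np.clip(imputed, 0.0, 1.0)
    # restore observed entries untouched (KNNImputer leaves them, but be safe)
    observed = ~values.isna().to_numpy()
    imputed[observed] = values.to_numpy()[observed]
    return BetaMatrix(
        pd.DataFrame(imputed, index=values.index, columns=values.columns),
        matrix.groups,
    )


def _logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(x / (1.0 - x))


def _inv_logit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def adjust_batches(matrices: list[BetaMatrix]) -> BetaMatrix:
    """Merge batches after removing per-batch location/scale differences.

    Sites are restricted to the intersection across batches. On the logit
    scale, each batch's per-site values are standardised to the pooled
    per-site mean and standard deviation, then transformed back. Sample IDs
    are prefixed with the batch index to keep them unique.
    """
    if len(matrices) < 2:
        raise ValueError("adjust_batches needs at least two batches")
    common = matrices[0].site_ids
    for m in matrices[1:]:
        common = common.intersection(m.site_ids)
    if len(common) == 0:
        raise ValueError("batches share no site IDs")
    common = sorted(common)

    logits = [ _logit(m.values.loc[common].to_numpy(dtype=float)) for m in matrices ]
    pooled = np.concatenate(logits, axis=1)
    pooled_mean = np.nanmean(pooled, axis=1, keepdims=True)
    pooled_sd = np.nanstd(pooled, axis=1, ddof=1, keepdims=True)

    adjusted_blocks, columns, groups = [], [], []
    for i, (m, z) in enumerate(zip(matrices, logits), start=1):
        b_mean = np.nanmean(z, axis=1, keepdims=True)
        b_sd = np.nanstd(z, axis=1, ddof=1, keepdims=True)
        scale = np.where(b_sd > 0, np.divide(pooled_sd, np.where(b_sd > 0, b_sd, 1.0)), 0.0)
        adjusted_blocks.append(_inv_logit(pooled_mean + scale * (z - b_mean)))
        cols = [f"b{i}_{c}" for c in m.values.loc[common].columns]
        columns.extend(cols)
        groups.extend(m.groups.loc[m.values.columns].tolist())
    values = pd.DataFrame(
        np.concatenate(adjusted_blocks, axis=1), index=common, columns=columns
    )
    return BetaMatrix(values, pd.Series(groups, index=columns))


def find_dmcs(
    matrix: BetaMatrix,
    cfg: SelectionConfig | None = None,
    tumour_group: str = "tumour",
    normal_group: str = "normal",
    return_all: bool = False,
) -> list[DmcRecord]:
    """Per-site rank-sum test plus fold-change filter for hypermethylated DMCs.

    A site is retained when its two-sided Wilcoxon rank-sum p-value is below
    ``p_threshold`` and the tumour/normal mean-beta ratio is at least
    ``fc_threshold``. Hypomethylated sites (the symmetric ratio rule) are
    detected and reported with direction ``hypo`` when ``return_all`` is
    set, but only hypermethylated sites continue down the cascade. Records
    are sorted by p ascending. Benjamini-Hochberg q-values over all tested
    sites are attached for information only; the retention rule uses raw p.
    """
    cfg = cfg or SelectionConfig()
    t_samples = matrix.samples_in_group(tumour_group)
    n_samples = matrix.samples_in_group(normal_group)
    if len(t_samples) < 2 or len(n_samples) < 2:
        raise ValueError(
            "rank-sum test undefined: each group needs >= 2 samples "
            f"(tumour={len(t_samples)}, normal={len(n_samples)})"
        )
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")

    t = values[t_samples].to_numpy(dtype=float)
    n = values[n_samples].to_numpy(dtype=float)
    method = "exact" if max(t.shape[1], n.shape[1]) <= 6 else "asymptotic"
    res = stats.mannwhitneyu(t, n, axis=1, alternative="two-sided", method=method)
    pvals = np.atleast_1d(res.pvalue)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    mean_t = t.mean(axis=1)
    mean_n = n.mean(axis=1)
    eps = cfg.epsilon_guard
    fc_hyper = mean_t / np.maximum(mean_n, eps)
    fc_hypo = mean_n / np.maximum(mean_t, eps)

    records = []
    for i, site in enumerate(values.index):
        hyper = mean_t[i] > mean_n[i]
        direction = "hyper" if hyper else "hypo"
        fc = fc_hyper[i] if hyper else fc_hypo[i]
        retained = pvals[i] < cfg.p_threshold and fc >= cfg.fc_threshold
        if not retained and not return_all:
            continue
        if direction == "hypo" and not return_all:
            continue
        records.append(
            DmcRecord(
                site_id=str(site),
                p_value=float(pvals[i]),
                fold_change=float(fc_hyper[i]),
                direction=direction,
                mean_tumour=float(mean_t[i]),
                mean_normal=float(mean_n[i]),
                q_value=float(qvals[i]),
            )
        )
    if not return_all:
        records = [
            r
            for r in records
            if r.direction == "hyper"
            and r.p_value < cfg.p_threshold
            and r.fold_change >= cfg.fc_threshold
        ]
    records.sort(key=lambda r: (r.p_value, r.site_id))
    return records


def intersect_dmcs(
    list_a: list[DmcRecord], list_b: list[DmcRecord]
) -> list[DmcRecord]:
    """Sites present in both candidate lists with matching direction.

    Annotation (p, fold change, means) is kept from ``list_a``; order
    follows ``list_a``.
    """
    b_dirs = {r.site_id: r.direction for r in list_b}
    return [r for r in list_a if b_dirs.get(r.site_id) == r.direction]


def rank_by_blood(
    dmcs: list[DmcRecord], blood: BetaMatrix, top_n: int = 30
) -> list[DmcRecord]:
    """Keep the ``top_n`` DMCs with the lowest mean beta in whole blood.

    Lower leukocyte methylation means less background signal in plasma.
    Ties are broken by site ID (lexicographic).
    """
    missing = [r.site_id for r in dmcs if r.site_id not in blood.site_ids]
    if missing:
        raise ValueError(f"sites absent from blood matrix: {missing[:10]}")
    blood_means = blood.values.mean(axis=1)
    annotated = []
    for r in dmcs:
        r.blood_mean = float(blood_means[r.site_id])
        annotated.append(r)
    annotated.sort(key=lambda r: (r.blood_mean, r.site_id))
    return annotated[:top_n]


def pancancer_filter(
    dmcs: list[DmcRecord],
    pancancer: dict[str, BetaMatrix],
    cfg: SelectionConfig | None = None,
) -> list[DmcRecord]:
    """Tissue-specificity filter against a pan-cancer beta-matrix panel.

    For each site, the set of cancer types with mean beta above
    ``pancancer_beta_threshold`` is computed; the site is retained iff that
    hyper-set has at most ``max_hyper_cancer_types`` members and contains
    the required type.
    """
    cfg = cfg or SelectionConfig()
    if cfg.required_cancer_type not in pancancer:
        raise ValueError(
            f"required cancer type {cfg.required_cancer_type!r} absent from "
            f"pan-cancer matrix set"
        )
    for code, m in pancancer.items():
        absent = [r.site_id for r in dmcs if r.site_id not in m.site_ids]
        if absent:
            raise ValueError(f"sites absent from {code} matrix: {absent[:10]}")
    means = {code: m.values.mean(axis=1) for code, m in pancancer.items()}
    retained = []
    for r in dmcs:
        hyper_set = frozenset(
            code
            for code in pancancer
            if means[code][r.site_id] > cfg.pancancer_beta_threshold
        )
        if (
            len(hyper_set) <= cfg.max_hyper_cancer_types
            and cfg.required_cancer_type in hyper_set
        ):
            r.hyper_set = hyper_set
            retained.append(r)
    return retained


def select_markers(
    datasets: list[BetaMatrix],
    blood: BetaMatrix,
    pancancer: dict[str, BetaMatrix],
    cfg: SelectionConfig | None = None,
) -> list[DmcRecord]:
    """Run the full screening cascade over one or more tumour/normal datasets.

    Each dataset is imputed and screened independently; candidate lists are
    intersected in order, then filtered by leukocyte background and
    pan-cancer specificity.
    """
    cfg = cfg or SelectionConfig()
    lists = []
    for matrix in datasets:
        if matrix.values.isna().any().any():
            matrix = impute_knn(matrix, cfg.knn_k)
        lists.append(find_dmcs(matrix, cfg))
    dmcs = lists[0]
    for other in lists[1:]:
        dmcs = intersect_dmcs(dmcs, other)
    dmcs = rank_by_blood(dmcs, blood, cfg.blood_top_n)
    return pancancer_filter(dmcs, pancancer, cfg)


def dmc_table(records: list[DmcRecord]) -> pd.DataFrame:
    """Flatten DMC records to the tabular report layout."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
            "fold_change": [r.fold_change for r in records],
            "direction": [r.direction for r in records],
            "mean_tumour": [r.mean_tumour for r in records],
            "mean_normal": [r.mean_normal for r in records],
            "blood_mean": [r.blood_mean for r in records],
            "hyper_set": [",".join(sorted(r.hyper_set)) for r in records],
        }
    )
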