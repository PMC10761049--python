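"""WGBS analysis from per-CpG cytosine counts.

The pipeline starts at Bismark-style CpG-report counts (the alignment
chain is upstream and out of scope): conversion-rate QC from an
unmethylated lambda spike-in, strand-combined methylation calling
(beta = m / (m + u) over both strands of a CpG dyad), pooled-count DMC
testing, greedy DMR clustering, gene-overlap DMG annotation, and
genomic-context classification of DMC positions relative to gene models.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DmrRecord, GeneModel

__all__ = [
    "conversion_rate",
    "call_methylation",
    "find_wgbs_dmcs",
    "call_dmrs",
    "annotate_dmgs",
    "classify_genomic_context",
]

logger = logging.getLogger(__name__)


def conversion_rate(lambda_counts: pd.DataFrame) -> float:
    """Bisulfite conversion rate from an unmethylated lambda spike-in.

    The spike-in genome carries no methylation, so every methylated call on
    it is a conversion failure. The rate is the fraction of unmethylated
    counts over all lambda CpG counts: ``sum(u) / sum(m + u)``.
    """
    cpg = lambda_counts[lambda_counts["context"] == "CpG"]
    m = int(cpg["count_methylated"].sum())
    u = int(cpg["count_unmethylated"].sum())
    if m + u == 0:
        raise ValueError("lambda spike-in has zero CpG coverage")
    return u / (m + u)


def call_methylation(counts: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Strand-combined methylation calls for CpG dyads.

    The + strand cytosine at position p and the - strand cytosine at p + 1
    belong to one CpG dyad anchored at p; their counts are summed and
    beta = (m+ + m-) / (m+ + m- + u+ + u-). A - strand record with no +
    partner is emitted as its own dyad anchored at p - 1 (logged), never
    silently dropped. Dyads with coverage below ``min_coverage`` are
    removed.

    Returns a DataFrame with columns chromosome, cpg_start, m, u, coverage,
    beta, sorted by (chromosome, cpg_start).
    """
    cpg = counts[counts["context"] == "CpG"]
    merged: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    plus_anchors = set()
    for chrom, pos, strand in zip(cpg["chromosome"], cpg["position"], cpg["strand"]):
        if strand == "+":
            plus_anchors.add((chrom, int(pos)))
    n_orphans = 0
    for chrom, pos, strand, m, u in zip(
        cpg["chromosome"], cpg["position"], cpg["strand"],
        cpg["count_methylated"], cpg["count_unmethylated"],
    ):
        pos = int(pos)
        if strand == "+":
            anchor = (chrom, pos)
        else:
            anchor = (chrom, pos - 1)
            if anchor not in plus_anchors:
                n_orphans += 1
        merged[anchor][0] += int(m)
        merged[anchor][1] += int(u)
    if n_orphans:
        logger.info("%d minus-strand CpG records had no plus-strand partner", n_orphans)

    rows = [
        (chrom, pos, m, u, m + u)
        for (chrom, pos), (m, u) in merged.items()
        if m + u >= min_coverage
    ]
    out = pd.DataFrame(
        rows, columns=["chromosome", "cpg_start", "m", "u", "coverage"]
    ).sort_values(["chromosome", "cpg_start"], ignore_index=True)
    out["beta"] = np.where(out["coverage"] > 0, out["m"] / out["coverage"], np.nan)
    return out


def find_wgbs_dmcs(
    tumour_calls: list[pd.DataFrame],
    normal_calls: list[pd.DataFrame],
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Pooled-count Fisher's exact test per CpG dyad, tumour vs normal.

    Per dyad, methylated/unmethylated counts are pooled across samples in
    each group and tested in a 2x2 table (two-sided Fisher). Dyads covered
    in only one group are skipped and tallied in the returned skip report.

    Returns ``(dmcs, skip_report)``: dmcs has columns chromosome,
    cpg_start, p, beta_tumour, beta_normal, delta, direction, restricted to
    p < p_threshold and sorted by (chromosome, cpg_start).
    """

    def pool(calls: list[pd.DataFrame]) -> pd.DataFrame:
        cat = pd.concat(calls, ignore_index=True)
        return cat.groupby(["chromosome", "cpg_start"], as_index=True)[["m", "u"]].sum()

    t = pool(tumour_calls)
    n = pool(normal_calls)
    shared = t.index.intersection(n.index)
    skip_report = {
        "tumour_only": int(len(t.index.difference(n.index))),
        "normal_only": int(len(n.index.difference(t.index))),
        "tested": int(len(shared)),
    }
    t = t.loc[shared]
    n = n.loc[shared]

    rows = []
    for (chrom, pos), (tm, tu), (nm, nu) in zip(
        shared, t[["m", "u"]].itertuples(index=False), n[["m", "u"]].itertuples(index=False)
    ):
        _, p = stats.fisher_exact([[tm, tu], [nm, nu]], alternative="two-sided")
        if p >= p_threshold:
            continue
        bt = tm / (tm + tu)
        bn = nm / (nm + nu)
        rows.append(
            (chrom, pos, p, bt, bn, bt - bn, "hyper" if bt > bn else "hypo")
        )
    dmcs = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "cpg_start", "p", "beta_tumour", "beta_normal",
            "delta", "direction",
        ],
    ).sort_values(["chromosome", "cpg_start"], ignore_index=True)
    return dmcs, skip_report


def call_dmrs(
    dmcs: pd.DataFrame, max_gap: int = 150, min_span: int = 50
) -> list[DmrRecord]:
    """Greedy clustering of same-direction DMCs into regions.

    Within each (chromosome, direction), consecutive DMCs join a cluster
    while the inter-DMC distance is at most ``max_gap`` bp; clusters with at
    least two members are emitted. Clusters spanning fewer than ``min_span``
    bp are emitted with a ``short_span`` flag rather than removed, so both
    readings of the span rule remain available downstream. Output is sorted
    by (chromosome, start).
    """
    if len(dmcs) == 0:
        return []
    sort_keys = list(zip(dmcs["chromosome"], dmcs["cpg_start"]))
    if sort_keys != sorted(sort_keys):
        raise ValueError("DMCs must be sorted by (chromosome, position)")

    records: list[DmrRecord] = []

    def flush(cluster: list[tuple]) -> None:
        if len(cluster) < 2:
            return
        positions = [c[1] for c in cluster]
        deltas = [c[2] for c in cluster]
        span = positions[-1] - positions[0]
        records.append(
            DmrRecord(
                chromosome=cluster[0][0],
                start=positions[0],
                end=positions[-1],
                n_dmcs=len(cluster),
                mean_delta=float(np.mean(deltas)),
                direction=cluster[0][3],
                short_span=span < min_span,
            )
        )

    for (_chrom, _direction), sub in dmcs.groupby(
        ["chromosome", "direction"], sort=True
    ):
        cluster: list[tuple] = []
        for row in sub.itertuples(index=False):
            item = (row.chromosome, int(row.cpg_start), float(row.delta), row.direction)
            if cluster and item[1] - cluster[-1][1] > max_gap:
                flush(cluster)
                cluster = []
            cluster.append(item)
        flush(cluster)
    records.sort(key=lambda r: (r.chromosome, r.start))
    return records


def annotate_dmgs(
    dmrs: list[DmrRecord], genes: list[GeneModel]
) -> list[tuple[str, list[DmrRecord]]]:
    """Differentially methylated genes: genes overlapping at least one DMR.

    Overlap is 1-based inclusive interval intersection between the DMR span
    and [gene_start, gene_end]. Output is sorted by gene ID.
    """
    hits: dict[str, list[DmrRecord]] = defaultdict(list)
    for gene in genes:
        for dmr in dmrs:
            if (
                dmr.chromosome == gene.chromosome
                and dmr.start <= gene.gene_end
                and dmr.end >= gene.gene_start
            ):
                hits[gene.gene_id].append(dmr)
    return sorted(hits.items())


def classify_genomic_context(
    chromosome: str,
    position: int,
    genes: list[GeneModel],
    upstream_bp: int = 2000,
    downstream_bp: int = 200,
) -> str:
    """Classify a position as intragenic / downstream / upstream / intergenic.

    Strand-aware offsets from the TSS: "downstream" is 0-200 bp 3' of the
    TSS, "upstream" 0-2000 bp 5' of the TSS. When labels conflict across
    genes the precedence is intragenic > downstream > upstream > intergenic.
    """
    labels = set()
    for gene in genes:
        if gene.chromosome != chromosome:
            continue
        if gene.gene_start <= position <= gene.gene_end:
            labels.add("intragenic")
            continue
        offset = position - gene.tss if gene.strand == "+" else gene.tss - position
        if 0 <= offset <= downstream_bp:
            labels.add("downstream")
        elif -upstream_bp <= offset < 0:
            labels.add("upstream")
    for label in ("intragenic", "downstream", "upstream"):
        if label in labels:
            return label
    return "intergenic"


def context_distribution(
    dmcs: pd.DataFrame, genes: list[GeneModel]
) -> dict[str, dict[str, int]]:
    """Counts of DMC genomic contexts, split by direction (hyper/hypo)."""
    out: dict[str, dict[str, int]] = {
        "hyper": defaultdict(int),
        "hypo": defaultdict(int),
    }
    for row in dmcs.itertuples(index=False):
        label = classify_genomic_context(row.chromosome, int(row.cpg_start), genes)
        out[row.direction][label] += 1
    return {d: dict(v) for d, v in out.items()}
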