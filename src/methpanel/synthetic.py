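"""Synthetic cohort generators for every pipeline input.

These generators emulate the statistical structure the analysis assumes so
the whole pipeline is testable without any external download:

* 450k-style beta matrices for a tumour/normal screen, with planted
  hypermethylated DMCs, leukocyte (whole-blood) background, and a
  pan-cancer specificity structure;
* WGBS per-CpG cytosine counts for paired tumour/NAT samples with planted
  DMRs and an unmethylated lambda spike-in carrying a configurable
  bisulfite-conversion failure rate;
* plasma MSP Ct tables for HCC / chronic-liver-disease / healthy cohorts
  with per-group delta-Ct distributions, plate controls, and clinical
  metadata (CNLC stage, tumour size/number, AFP, survival).

Beta noise uses Beta distributions parameterised by (mean, concentration),
which respects the [0, 1] support of array beta values. Every generator
takes an explicit seed and is reproducible for a fixed configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix

__all__ = [
    "SimArrayConfig",
    "SimWgbsConfig",
    "SimCohortConfig",
    "TCGA_CANCER_TYPES",
    "simulate_array_cohort",
    "simulate_blood_and_pancancer",
    "simulate_wgbs_pairs",
    "simulate_msp_cohort",
]

#: The 32 TCGA cancer-type codes used for the pan-cancer specificity screen.
TCGA_CANCER_TYPES = (
    "ACC BLCA BRCA CESC CHOL COAD DLBC ESCA GBM HNSC KICH KIRC KIRP LGG "
    "LIHC LUAD LUSC MESO OV PAAD PCPG PRAD READ SARC SKCM STAD TGCT THCA "
    "THYM UCEC UCS UVM"
).split()


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _beta_draw(rng, mean, concentration, size):
    """Draw from Beta with given mean and concentration (a + b)."""
    mean = np.asarray(mean, dtype=float)
    a = np.clip(mean * concentration, 1e-6, None)
    b = np.clip((1.0 - mean) * concentration, 1e-6, None)
    return rng.beta(a, b, size=size)


# --------------------------------------------------------------------------
# 450k-style array cohorts


@dataclass
class SimArrayConfig:
    """Configuration for a tumour/normal array-screen beta matrix.

    Defaults emulate the TCGA-LIHC screening cohort (377 tumours, 50
    normals) with strong planted hypermethylation (tumour mean 0.5 vs
    normal mean 0.05) against a moderate background.
    """

    n_sites: int = 1000
    n_tumour: int = 377
    n_normal: int = 50
    n_planted: int = 50
    planted_effect: tuple[float, float] = (0.5, 0.05)  # (tumour, normal) mean
    background_mean: float = 0.2
    concentration: float = 30.0
    na_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ConfigurationError("n_sites must be positive")
        if self.n_tumour < 0 or self.n_normal < 0:
            raise ConfigurationError("n_tumour/n_normal must be non-negative")
        if not 0 <= self.n_planted <= self.n_sites:
            raise ConfigurationError("n_planted must be in [0, n_sites]")
        for name, v in (("planted_effect[0]", self.planted_effect[0]),
                        ("planted_effect[1]", self.planted_effect[1])):
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.background_mean < 1.0:
            raise ConfigurationError("background_mean must lie in (0, 1)")
        if not 0.0 <= self.na_rate < 1.0:
            raise ConfigurationError("na_rate must lie in [0, 1)")
        if self.concentration <= 0:
            raise ConfigurationError("concentration must be positive")


def _site_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def simulate_array_cohort(config: SimArrayConfig) -> tuple[BetaMatrix, list[str]]:
    """Generate a tumour/normal beta matrix with planted hypermethylated DMCs.

    Returns the matrix and the ground-truth list of planted site IDs (the
    first ``n_planted`` sites). Non-planted sites share a common background
    mean in both groups; ``na_rate`` entries are set missing completely at
    random.
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_ids(config.n_sites)
    planted = sites[: config.n_planted]

    n_samples = config.n_tumour + config.n_normal
    means = np.full((config.n_sites, n_samples), config.background_mean)
    t_mean, n_mean = config.planted_effect
    means[: config.n_planted, : config.n_tumour] = t_mean
    means[: config.n_planted, config.n_tumour:] = n_mean

    values = _beta_draw(rng, means, config.concentration, means.shape)
    if config.na_rate > 0:
        mask = rng.random(values.shape) < config.na_rate
        values = np.where(mask, np.nan, values)

    samples = [f"T{i:04d}" for i in range(config.n_tumour)] + [
        f"N{i:04d}" for i in range(config.n_normal)
    ]
    groups = pd.Series(
        ["tumour"] * config.n_tumour + ["normal"] * config.n_normal,
        index=samples,
    )
    matrix = BetaMatrix(pd.DataFrame(values, index=sites, columns=samples), groups)
    return matrix, planted


def simulate_blood_and_pancancer(
    config: SimArrayConfig,
    n_cancer_types: int = 32,
    hyper_assignment: dict[str, set[str]] | None = None,
    n_blood: int = 100,
    n_per_cancer: int = 30,
    hyper_mean: float = 0.5,
    nonhyper_mean: float = 0.1,
    marker_blood_mean: float = 0.05,
    background_blood_mean: float = 0.2,
) -> tuple[BetaMatrix, dict[str, BetaMatrix]]:
    """Generate the leukocyte-background and pan-cancer specificity matrices.

    ``hyper_assignment`` maps a site ID to the set of cancer-type codes in
    which it is hypermethylated (mean beta above 0.3); unassigned sites are
    drawn below 0.3 in every type. Sites appearing in ``hyper_assignment``
    are treated as candidate markers and drawn near zero in the blood
    matrix; all other sites get the ordinary blood background.
    """
    hyper_assignment = hyper_assignment or {}
    types = TCGA_CANCER_TYPES[:n_cancer_types]
    known = set(types)
    for site, assigned in hyper_assignment.items():
        unknown = set(assigned) - known
        if unknown:
            raise ConfigurationError(
                f"hyper_assignment for {site} names unknown cancer types: "
                f"{sorted(unknown)}"
            )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sites = _site_ids(config.n_sites)
    marker = np.array([s in hyper_assignment for s in sites])

    blood_means = np.where(marker, marker_blood_mean, background_blood_mean)
    blood_vals = _beta_draw(
        rng, blood_means[:, None], config.concentration, (config.n_sites, n_blood)
    )
    blood_samples = [f"B{i:04d}" for i in range(n_blood)]
    blood = BetaMatrix(
        pd.DataFrame(blood_vals, index=sites, columns=blood_samples),
        pd.Series("blood", index=blood_samples),
    )

    pancancer: dict[str, BetaMatrix] = {}
    for code in types:
        site_means = np.array(
            [
                hyper_mean if code in hyper_assignment.get(s, ()) else nonhyper_mean
                for s in sites
            ]
        )
        vals = _beta_draw(
            rng, site_means[:, None], config.concentration,
            (config.n_sites, n_per_cancer),
        )
        cols = [f"{code}{i:03d}" for i in range(n_per_cancer)]
        pancancer[code] = BetaMatrix(
            pd.DataFrame(vals, index=sites, columns=cols),
            pd.Series(code, index=cols),
        )
    return blood, pancancer


# --------------------------------------------------------------------------
# WGBS paired tumour/NAT counts


@dataclass
class SimWgbsConfig:
    """Configuration for paired tumour/NAT WGBS cytosine-report tables."""

    n_pairs: int = 12
    n_cpgs: int = 500  # CpG dyads per chromosome
    chromosomes: tuple[str, ...] = ("chr1",)
    cpg_spacing: int = 60  # bp between consecutive CpG dyads
    planted_dmrs: list[tuple[str, int, int, float, float]] = field(
        default_factory=list
    )  # (chrom, start, end, tumour_meth_prob, normal_meth_prob)
    background_meth_prob: float = 0.25
    depth_mean: float = 30.0
    n_lambda_cpgs: int = 500
    conversion_failure_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise ConfigurationError("n_pairs must be positive")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        if not 0.0 <= self.conversion_failure_rate < 1.0:
            raise ConfigurationError("conversion_failure_rate must lie in [0, 1)")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, tp, npr in self.planted_dmrs:
            if chrom not in self.chromosomes:
                raise ConfigurationError(
                    f"planted_dmrs: {chrom} not among simulated chromosomes"
                )
            if start > end:
                raise ConfigurationError(f"planted_dmrs: start > end on {chrom}")
            for p in (tp, npr):
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        "planted_dmrs: methylation probabilities must lie in [0, 1]"
                    )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in itertools.pairwise(spans):
                if s2 <= e1:
                    raise ConfigurationError(
                        f"planted_dmrs overlap on {chrom}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )


_REPORT_COLUMNS = [
    "chromosome",
    "position",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


def _cpg_report(chroms, positions, strands, m, u) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "strand": strands,
            "count_methylated": m,
            "count_unmethylated": u,
            "context": "CpG",
            "trinucleotide": "CGG",
        },
        columns=_REPORT_COLUMNS,
    )


def simulate_wgbs_pairs(
    config: SimWgbsConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate Bismark-dialect CpG-report tables for tumour/NAT pairs.

    Each CpG dyad is emitted on both strands (the + strand cytosine at
    position p, the - strand cytosine at p + 1), with per-strand coverage
    Poisson(depth_mean / 2) and per-read methylation Bernoulli at the
    planted-DMR probability inside planted regions, else at the common
    background probability. The lambda spike-in is fully unmethylated except
    for the configured conversion-failure rate.

    Returns ``(tables, lambda_table)`` where ``tables`` maps sample names
    ``tumour_01 ... normal_12`` to report DataFrames.
    """
    rng = np.random.default_rng(config.seed)

    positions = {
        chrom: 1 + config.cpg_spacing * np.arange(config.n_cpgs)
        for chrom in config.chromosomes
    }

    def site_prob(chrom: str, pos: int, tumour: bool) -> float:
        for c, start, end, tp, npr in config.planted_dmrs:
            if c == chrom and start <= pos <= end:
                return tp if tumour else npr
        return config.background_meth_prob

    tables: dict[str, pd.DataFrame] = {}
    for pair in range(1, config.n_pairs + 1):
        for tumour in (True, False):
            chroms_out, pos_out, strand_out, m_out, u_out = [], [], [], [], []
            for chrom in config.chromosomes:
                probs = np.array(
                    [site_prob(chrom, p, tumour) for p in positions[chrom]]
                )
                for strand, offset in (("+", 0), ("-", 1)):
                    cov = rng.poisson(config.depth_mean / 2.0, size=config.n_cpgs)
                    m = rng.binomial(cov, probs)
                    chroms_out.extend([chrom] * config.n_cpgs)
                    pos_out.extend(positions[chrom] + offset)
                    strand_out.extend([strand] * config.n_cpgs)
                    m_out.extend(m)
                    u_out.extend(cov - m)
            name = f"{'tumour' if tumour else 'normal'}_{pair:02d}"
            tables[name] = _cpg_report(chroms_out, pos_out, strand_out, m_out, u_out)

    lam_pos = 1 + 50 * np.arange(config.n_lambda_cpgs)
    chroms_out, pos_out, strand_out, m_out, u_out = [], [], [], [], []
    for strand, offset in (("+", 0), ("-", 1)):
        cov = rng.poisson(config.depth_mean / 2.0, size=config.n_lambda_cpgs)
        m = rng.binomial(cov, config.conversion_failure_rate)
        chroms_out.extend(["lambda"] * config.n_lambda_cpgs)
        pos_out.extend(lam_pos + offset)
        strand_out.extend([strand] * config.n_lambda_cpgs)
        m_out.extend(m)
        u_out.extend(cov - m)
    lambda_table = _cpg_report(chroms_out, pos_out, strand_out, m_out, u_out)
    return tables, lambda_table


# --------------------------------------------------------------------------
# Plasma MSP cohort


def _default_dct_params() -> dict[str, dict[str, tuple[float, float]]]:
    # Per-group (mean, sd) of delta-Ct = Ct_target - Ct_ACTB. Lower delta-Ct
    # means more methylated template. Chosen for qualitative HCC vs CLD vs
    # healthy separation with the HCC distribution broad (tumour-fraction
    # heterogeneity) and control distributions tight near the assay floor.
    return {
        "HCC": {"GNB4": (8.0, 3.0), "Riplet": (9.5, 3.5)},
        "CLD": {"GNB4": (13.5, 2.5), "Riplet": (15.0, 2.5)},
        "Normal": {"GNB4": (14.5, 2.0), "Riplet": (15.5, 2.0)},
    }


def _default_afp_params() -> dict[str, tuple[float, float]]:
    # Log-normal (mu, sigma) of AFP in ng/ml: HCC median ~55 with a heavy
    # tail (a large AFP-negative fraction), controls near the healthy range.
    return {"HCC": (4.0, 2.5), "CLD": (1.5, 1.0), "Normal": (1.0, 0.7)}


@dataclass
class SimCohortConfig:
    """Configuration for the plasma MSP cohort (Ct table + clinical table).

    Cohort-size defaults match the plasma validation cohorts (173 HCC, 199
    chronic liver disease, 98 healthy). The CNLC stage distribution and
    tumour number/size frequencies follow the clinical table of that cohort.
    """

    n_hcc: int = 173
    n_cld: int = 199
    n_normal: int = 98
    genes: tuple[str, ...] = ("GNB4", "Riplet")
    dct_params: dict = field(default_factory=_default_dct_params)
    dct_sd_actb: float = 1.0
    actb_mean: float = 27.0
    detect_floor: float = 50.0  # plasma MSP cycle cap
    afp_params: dict = field(default_factory=_default_afp_params)
    stage_probs: dict = field(
        default_factory=lambda: {"I": 0.38, "II": 0.18, "III-IV": 0.44}
    )
    plate_size: int = 40
    seed: int = 0

    def __post_init__(self):
        for name in ("n_hcc", "n_cld", "n_normal"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.detect_floor <= 0:
            raise ConfigurationError("detect_floor must be positive")
        if abs(sum(self.stage_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("stage_probs must sum to 1")
        for group in ("HCC", "CLD", "Normal"):
            if group not in self.dct_params:
                raise ConfigurationError(f"dct_params missing group {group}")
            for gene in self.genes:
                if gene not in self.dct_params[group]:
                    raise ConfigurationError(
                        f"dct_params[{group}] missing gene {gene}"
                    )


def simulate_msp_cohort(
    config: SimCohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a plasma MSP Ct table and matching clinical-record table.

    The Ct table has one row per well with columns ``plate_id, well,
    sample_id, gene, well_role, ct`` (ct empty/NaN = undetermined). Each
    plate carries a HepG2 positive-control well per gene and a no-template
    control per gene. Group separation is governed solely by
    ``dct_params``; a target whose simulated amplification exceeds
    ``detect_floor`` cycles is recorded as undetermined.

    The clinical table has one row per sample: group, CNLC stage, tumour
    count and single-tumour size (HCC only), AFP (ng/ml) and overall
    survival time (days) / event.
    """
    rng = np.random.default_rng(config.seed)
    groups = (
        ["HCC"] * config.n_hcc + ["CLD"] * config.n_cld + ["Normal"] * config.n_normal
    )
    n = len(groups)
    sample_ids = [f"P{i:04d}" for i in range(n)]

    ct_rows = []
    clin_rows = []
    # plates are filled in randomised order so per-plate calibrator noise is
    # not confounded with group (cohorts are generated group-contiguous)
    plate_order = rng.permutation(n)
    plate_of = {
        sample_ids[j]: f"plate{(i // config.plate_size) + 1:02d}"
        for i, j in enumerate(plate_order)
    }

    for sid, group in zip(sample_ids, groups):
        actb = rng.normal(config.actb_mean, config.dct_sd_actb)
        ct_rows.append(
            dict(plate_id=plate_of[sid], well="", sample_id=sid, gene="ACTB",
                 well_role="sample", ct=round(actb, 3))
        )
        for gene in config.genes:
            mean, sd = config.dct_params[group][gene]
            target = actb + rng.normal(mean, sd)
            ct = np.nan if target > config.detect_floor else round(target, 3)
            ct_rows.append(
                dict(plate_id=plate_of[sid], well="", sample_id=sid, gene=gene,
                     well_role="sample", ct=ct)
            )

        stage = tumour_count = tumour_size = ""
        if group == "HCC":
            stages = list(config.stage_probs)
            stage = rng.choice(stages, p=[config.stage_probs[s] for s in stages])
            multi = rng.random() < 0.41  # ~67/163 multi-tumour
            tumour_count = 2 if multi else 1
            if not multi:
                tumour_size = "<=3cm" if rng.random() < 0.25 else ">3cm"
        afp_mu, afp_sigma = config.afp_params[group]
        afp = float(np.round(rng.lognormal(afp_mu, afp_sigma), 2))
        time_days = float(np.round(rng.exponential(900.0 if group == "HCC" else 2500.0), 1))
        event = int(rng.random() < (0.6 if group == "HCC" else 0.1))
        clin_rows.append(
            dict(sample_id=sid, group=group, cnlc_stage=stage,
                 tumour_count=tumour_count, single_tumour_size=tumour_size,
                 afp_ng_ml=afp, time_days=time_days, event=event)
        )

    # plate controls: one HepG2 positive control and one NTC per gene per plate
    for plate in sorted(set(plate_of.values())):
        for gene in list(config.genes) + ["ACTB"]:
            ct_rows.append(
                dict(plate_id=plate, well="PC", sample_id=f"{plate}_HepG2",
                     gene=gene, well_role="positive_control",
                     ct=round(rng.normal(27.0, 0.5), 3))
            )
            ct_rows.append(
                dict(plate_id=plate, well="NTC", sample_id=f"{plate}_NTC",
                     gene=gene, well_role="ntc", ct=np.nan)
            )

    ct_table = pd.DataFrame(ct_rows)
    clinical = pd.DataFrame(clin_rows)
    return ct_table, clinical
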