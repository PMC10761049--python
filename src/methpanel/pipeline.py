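"""End-to-end synthetic pipeline runner with a reproducibility manifest.

Stages mirror the discovery-to-validation workflow: array screening
(tumour/normal datasets -> DMC cascade), WGBS confirmation (counts ->
DMC/DMR/DMG), plasma MSP quantification, panel evaluation against AFP, and
the association analyses. Every stochastic stage derives its seed from the
single pipeline seed; the manifest records seeds, thresholds, per-stage
record counts and output checksums, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, msp, panel_eval, synthetic, wgbs
from .array_selection import SelectionConfig, dmc_table, select_markers
from .io import write_beta_tsv, write_cpg_report, write_json
from .synthetic import (
    SimArrayConfig,
    SimCohortConfig,
    SimWgbsConfig,
    simulate_array_cohort,
    simulate_blood_and_pancancer,
    simulate_msp_cohort,
    simulate_wgbs_pairs,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Structured configuration for the full synthetic run."""

    seed: int = 0
    array: SimArrayConfig = field(default_factory=SimArrayConfig)
    wgbs_sim: SimWgbsConfig = field(default_factory=SimWgbsConfig)
    cohort: SimCohortConfig = field(default_factory=SimCohortConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_exclusive_lihc: int = 7  # planted sites assigned to LIHC only
    combine_method: str = "logistic"
    min_coverage: int = 5
    max_gap: int = 150
    min_span: int = 50
    run_array: bool = True
    run_wgbs: bool = True
    run_msp: bool = True
    run_assoc: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sub = {
            "array": SimArrayConfig,
            "wgbs_sim": SimWgbsConfig,
            "cohort": SimCohortConfig,
            "selection": SelectionConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                extra = set(value) - set(sub[key].__dataclass_fields__)
                if extra:
                    raise ValueError(f"unknown {key} config keys: {sorted(extra)}")
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def default_hyper_assignment(
    planted: list[str], n_exclusive: int
) -> dict[str, set[str]]:
    """Pan-cancer assignment: the first ``n_exclusive`` planted sites are
    hypermethylated only in LIHC; the rest either lack LIHC or are shared
    with two further types, so the specificity filter removes them."""
    assignment: dict[str, set[str]] = {}
    for i, site in enumerate(planted):
        if i < n_exclusive:
            assignment[site] = {"LIHC"}
        elif i % 2 == 0:
            assignment[site] = {"LIHC", "CHOL", "STAD"}
        else:
            assignment[site] = {"CHOL"}
    return assignment


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every enabled stage on synthetic inputs; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "seed": config.seed,
        "config": {
            "selection": asdict(config.selection),
            "combine_method": config.combine_method,
            "min_coverage": config.min_coverage,
            "max_gap": config.max_gap,
            "min_span": config.min_span,
        },
        "stages": {},
    }

    selected_sites: list[str] = []
    if config.run_array:
        cfg_a = SimArrayConfig(**{**asdict(config.array),
                                  "seed": _derive_seed(config.seed, "array_a")})
        cfg_b = SimArrayConfig(**{**asdict(config.array),
                                  "seed": _derive_seed(config.seed, "array_b")})
        mat_a, planted = simulate_array_cohort(cfg_a)
        mat_b, _ = simulate_array_cohort(cfg_b)
        assignment = default_hyper_assignment(planted, config.n_exclusive_lihc)
        blood, pancancer = simulate_blood_and_pancancer(
            cfg_a, hyper_assignment=assignment
        )
        selected = select_markers([mat_a, mat_b], blood, pancancer, config.selection)
        selected_sites = [r.site_id for r in selected]
        table = dmc_table(selected)
        table.to_csv(out / "selected_dmcs.tsv", sep="\t", index=False)
        write_beta_tsv(mat_a, out / "array_datasetA.tsv", out / "array_datasetA.samples.tsv")
        manifest["stages"]["array"] = {
            "seed_a": cfg_a.seed,
            "seed_b": cfg_b.seed,
            "n_planted": len(planted),
            "n_selected": len(selected),
            "selected_sites": selected_sites,
        }
    else:
        manifest["stages"]["array"] = {"skipped": True}

    if config.run_wgbs:
        cfg_w = SimWgbsConfig(**{**asdict(config.wgbs_sim),
                                 "seed": _derive_seed(config.seed, "wgbs")})
        tables, lam = simulate_wgbs_pairs(cfg_w)
        rate = wgbs.conversion_rate(lam)
        calls = {
            name: wgbs.call_methylation(tab, config.min_coverage)
            for name, tab in tables.items()
        }
        tumour = [c for n, c in calls.items() if n.startswith("tumour")]
        normal = [c for n, c in calls.items() if n.startswith("normal")]
        dmcs, skip = wgbs.find_wgbs_dmcs(tumour, normal)
        dmrs = wgbs.call_dmrs(dmcs, config.max_gap, config.min_span)
        genes = [
            wgbs.GeneModel(
                gene_id=f"gene{i}", chromosome=chrom, strand="+",
                gene_start=start, gene_end=end,
            )
            for i, (chrom, start, end, *_rest) in enumerate(cfg_w.planted_dmrs)
        ]
        dmgs = wgbs.annotate_dmgs(dmrs, genes)
        context = wgbs.context_distribution(dmcs, genes)
        write_cpg_report(lam, out / "lambda_report.tsv")
        dmcs.to_csv(out / "wgbs_dmcs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (d.chromosome, d.start, d.end, d.n_dmcs, d.mean_delta,
                 d.direction, d.short_span)
                for d in dmrs
            ],
            columns=["chromosome", "start", "end", "n_dmcs", "mean_delta",
                     "direction", "short_span"],
        ).to_csv(out / "wgbs_dmrs.tsv", sep="\t", index=False)
        write_json(context, out / "wgbs_context.json")
        manifest["stages"]["wgbs"] = {
            "seed": cfg_w.seed,
            "conversion_rate": rate,
            "n_samples": len(tables),
            "n_dmcs": int(len(dmcs)),
            "n_dmrs": len(dmrs),
            "n_dmgs": len(dmgs),
            "skip_report": skip,
        }
    else:
        manifest["stages"]["wgbs"] = {"skipped": True}

    if config.run_msp:
        cfg_c = SimCohortConfig(**{**asdict(config.cohort),
                                   "seed": _derive_seed(config.seed, "cohort")})
        ct_table, clinical = simulate_msp_cohort(cfg_c)
        quant = msp.quantify_cohort(ct_table, genes=cfg_c.genes)
        ct_table.to_csv(out / "ct_table.csv", index=False)
        quant.to_csv(out / "quantification.csv", index=False)

        wide = quant[quant["valid"]].pivot(
            index="sample_id", columns="gene", values="level"
        ).dropna()
        clinical = clinical.set_index("sample_id").loc[wide.index].reset_index()
        clinical = panel_eval.split_cohort(
            clinical, seed=_derive_seed(config.seed, "split")
        )
        labels = (clinical["group"] == "HCC").to_numpy()
        train = (clinical["split"] == "training").to_numpy()
        g1, g2 = cfg_c.genes[0], cfg_c.genes[1]
        X = wide[[g1, g2]].to_numpy()
        est = panel_eval.MarkerPanelClassifier(method=config.combine_method)
        est.fit(X[train], labels[train])
        scores = est.decision_function(X)

        evaluation: dict = {}
        for name, mask in (
            ("training", train), ("validation", ~train),
            ("all", np.ones(len(labels), bool)),
        ):
            block = {}
            for marker, vals in ((g1, X[:, 0]), (g2, X[:, 1]), ("panel", scores)):
                roc = panel_eval.roc_analysis(vals[mask], labels[mask])
                block[marker] = {
                    "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                    "cutoff": roc.youden_cutoff,
                    "sens": roc.youden_sens, "spec": roc.youden_spec,
                }
            evaluation[name] = block
        panel_roc = panel_eval.roc_analysis(scores, labels)
        calls = panel_eval.classify(scores, panel_roc.youden_cutoff)
        perf = panel_eval.subgroup_performance(calls, clinical)
        perf.to_csv(out / "panel_performance.tsv", sep="\t", index=False)
        afp_mask = clinical["group"].isin(["HCC", "CLD"]).to_numpy()
        afp_report = panel_eval.compare_afp(
            clinical.loc[afp_mask, "afp_ng_ml"].to_numpy(),
            clinical.loc[afp_mask].reset_index(drop=True),
            fixed_cutoffs=(20.0,),
            matched_spec_target=float(
                perf.loc[perf["stratum"] == "non-HCC combined", "percent"].iloc[0]
            ),
        )
        afp_report.to_csv(out / "afp_comparison.tsv", sep="\t", index=False)
        clinical.to_csv(out / "clinical.csv", index=False)
        write_json(evaluation, out / "roc_evaluation.json")
        manifest["stages"]["msp_eval"] = {
            "seed": cfg_c.seed,
            "n_samples": int(len(clinical)),
            "n_valid": int(len(wide)),
            "panel_auc": panel_roc.auc,
            "panel_cutoff": panel_roc.youden_cutoff,
        }

        if config.run_assoc:
            hcc = clinical[clinical["group"] == "HCC"]
            surv = pd.DataFrame(
                {
                    "sample_id": hcc["sample_id"],
                    "time": hcc["time_days"],
                    "event": hcc["event"],
                    "meth_value": wide.loc[hcc["sample_id"], g1].to_numpy(),
                }
            )
            km = assoc.km_survival(surv)
            write_json(
                {"median": km.median, "logrank_p": km.logrank_p,
                 "n_high": int((km.groups == "high").sum()),
                 "n_low": int((km.groups == "low").sum())},
                out / "survival.json",
            )
            manifest["stages"]["assoc"] = {"logrank_p": km.logrank_p}
        else:
            manifest["stages"]["assoc"] = {"skipped": True}
    else:
        manifest["stages"]["msp_eval"] = {"skipped": True}
        manifest["stages"]["assoc"] = {"skipped": True}

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
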