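"""Methylation-specific qPCR (MSP) quantification and QC.

Relative methylation is quantified as 2^-ddCt against the ACTB internal
reference and a methylated-cell-line (HepG2) positive-control calibrator
run on each plate:

    ddCt = (Ct_target - Ct_ACTB)_sample - (Ct_target - Ct_ACTB)_positive control

Sample validity is gated on the ACTB Ct (< 35 cycles); plates must show a
clean no-template control and an amplifying positive control. Standard
curves (Ct on log10 copies) validate primer efficiency, which must fall in
[90%, 110%].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import StandardCurveFit

__all__ = [
    "qc_sample",
    "qc_plate",
    "PlateQcReport",
    "fit_standard_curve",
    "compute_ddct",
    "quantify_cohort",
]

ACTB_CT_THRESHOLD = 35.0


def _undetermined(ct) -> bool:
    return ct is None or (isinstance(ct, float) and math.isnan(ct))


def qc_sample(actb_ct: float | None, threshold: float = ACTB_CT_THRESHOLD) -> bool:
    """A sample's DNA is valid iff its ACTB Ct is determined and below 35."""
    return (not _undetermined(actb_ct)) and actb_ct < threshold


@dataclass
class PlateQcReport:
    plate_id: str
    passed: bool
    reasons: list[str]


def qc_plate(records: pd.DataFrame) -> PlateQcReport:
    """Plate-level controls: NTCs must not amplify, positive controls must.

    ``records`` holds the wells of one plate with columns gene, well_role,
    ct. Failure reasons: ``contamination`` (an NTC amplified),
    ``missing_ntc`` / ``missing_positive_control``, and
    ``positive_control_failed:<gene>`` (a control target did not amplify).
    """
    plate_ids = records["plate_id"].unique() if "plate_id" in records else ["?"]
    plate_id = str(plate_ids[0])
    reasons = []
    ntc = records[records["well_role"] == "ntc"]
    pc = records[records["well_role"] == "positive_control"]
    if len(ntc) == 0:
        reasons.append("missing_ntc")
    elif ntc["ct"].notna().any():
        reasons.append("contamination")
    if len(pc) == 0:
        reasons.append("missing_positive_control")
    else:
        for gene, sub in pc.groupby("gene"):
            if sub["ct"].isna().all():
                reasons.append(f"positive_control_failed:{gene}")
    return PlateQcReport(plate_id=plate_id, passed=not reasons, reasons=reasons)


def fit_standard_curve(copies, cts) -> StandardCurveFit:
    """Fit Ct on log10(copies) and derive amplification efficiency.

    Efficiency (percent) = (10^(-1/slope) - 1) * 100; a perfect assay
    doubles template each cycle, slope = -1/log10(2) ~ -3.3219, efficiency
    100%. Accepted iff 90.0 <= efficiency <= 110.0. A non-negative slope
    (Ct not decreasing with concentration) is rejected outright.
    """
    copies = np.asarray(copies, dtype=float)
    cts = np.asarray(cts, dtype=float)
    levels = np.unique(copies)
    if len(levels) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentration levels")
    if np.log10(levels.max() / levels.min()) < 2.0:
        raise ValueError("standard curve must span >= 2 log10 units")
    x = np.log10(copies)
    slope, intercept = np.polyfit(x, cts, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((cts - fitted) ** 2))
    ss_tot = float(np.sum((cts - cts.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if slope >= 0:
        return StandardCurveFit(
            copies=copies, cts=cts, slope=float(slope), intercept=float(intercept),
            r_squared=r_squared, efficiency=float("nan"), accepted=False,
            reason="non_monotone: Ct does not decrease with concentration",
        )
    efficiency = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    accepted = 90.0 <= efficiency <= 110.0
    reason = "" if accepted else f"efficiency {efficiency:.1f}% outside [90, 110]"
    return StandardCurveFit(
        copies=copies, cts=cts, slope=float(slope), intercept=float(intercept),
        r_squared=r_squared, efficiency=float(efficiency), accepted=accepted,
        reason=reason,
    )


def compute_ddct(
    ct_target: float | None,
    ct_ref: float,
    control_ct_target: float,
    control_ct_ref: float,
) -> tuple[float, float, str]:
    """ddCt and 2^-ddCt for one (sample, gene) against the plate calibrator.

    The caller must have passed the sample and plate QC gates first. An
    undetermined target Ct in a valid sample means no methylated template
    was detected: the level is 0 with an ``undetected`` flag (ddCt +inf).

    Returns ``(ddct, level, flag)`` with flag "" or "undetected".
    """
    if _undetermined(ct_ref):
        raise ValueError("sample failed ACTB QC; filter before quantification")
    if _undetermined(control_ct_target) or _undetermined(control_ct_ref):
        raise ValueError("positive-control Ct undetermined")
    if _undetermined(ct_target):
        return float("inf"), 0.0, "undetected"
    ddct = (ct_target - ct_ref) - (control_ct_target - control_ct_ref)
    return float(ddct), float(2.0 ** (-ddct)), ""


def quantify_cohort(ct_table: pd.DataFrame, genes=("GNB4", "Riplet")) -> pd.DataFrame:
    """Quantify every valid sample on every passing plate.

    ``ct_table`` columns: plate_id, sample_id, gene, well_role, ct.
    Replicate wells are averaged on the Ct scale before ddCt. Samples on a
    failed plate are refused (dropped with flag in the QC columns); samples
    failing the ACTB gate are emitted with valid=False and no level.

    Returns a long DataFrame: sample_id, gene, ddct, level, valid, flags.
    """
    out_rows = []
    for plate_id, plate in ct_table.groupby("plate_id"):
        report = qc_plate(plate)
        samples = plate[plate["well_role"] == "sample"]
        pc = plate[plate["well_role"] == "positive_control"]

        def mean_ct(frame: pd.DataFrame) -> float:
            vals = frame["ct"].dropna()
            return float(vals.mean()) if len(vals) else float("nan")

        control_ref = mean_ct(pc[pc["gene"] == "ACTB"]) if report.passed else float("nan")
        for sample_id, sub in samples.groupby("sample_id"):
            actb = mean_ct(sub[sub["gene"] == "ACTB"])
            valid = qc_sample(actb)
            for gene in genes:
                if not report.passed:
                    out_rows.append(
                        dict(sample_id=sample_id, gene=gene, ddct=np.nan,
                             level=np.nan, valid=False,
                             flags="plate_failed:" + ",".join(report.reasons))
                    )
                    continue
                if not valid:
                    out_rows.append(
                        dict(sample_id=sample_id, gene=gene, ddct=np.nan,
                             level=np.nan, valid=False, flags="actb_qc_failed")
                    )
                    continue
                target_wells = sub[sub["gene"] == gene]
                target = mean_ct(target_wells)
                control_target = mean_ct(pc[pc["gene"] == gene])
                ddct, level, flag = compute_ddct(
                    target if not np.isnan(target) else None,
                    actb, control_target, control_ref,
                )
                out_rows.append(
                    dict(sample_id=sample_id, gene=gene, ddct=ddct, level=level,
                         valid=True, flags=flag)
                )
    return pd.DataFrame(out_rows).sort_values(["sample_id", "gene"], ignore_index=True)
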