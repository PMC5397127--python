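"""Region-of-interest statistics for the striatal iron analysis.

Per-subject mean R2* is extracted from a region mask (the ground-truth
striatal mask in simulations; any NIfTI mask for real data — the published
ventral-striatum atlas mask is not bundled), groups are compared by one-way
ANOVA or a covariate-adjusted GLM, and ROI values are correlated with
covariates by Spearman rank correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .glm import design_from_records, glm_fit, spearman_rho
from .phantom import SubjectRecord

__all__ = ["roi_mean", "roi_table", "group_compare", "covariate_correlations"]

log = logging.getLogger(__name__)


def roi_mean(
    value_map: np.ndarray, roi_mask: np.ndarray, valid_mask: np.ndarray | None = None
) -> float | None:
    """Mean of a map over ROI intersect valid voxels.

    Returns ``None`` (caller excludes the subject) when the intersection is
    empty; the exclusion is logged.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if valid_mask is not None:
        roi = roi & np.asarray(valid_mask, dtype=bool)
    if not roi.any():
        log.warning("ROI does not intersect the valid mask; subject excluded")
        return None
    return float(np.mean(np.asarray(value_map, dtype=float)[roi]))


def roi_table(
    records: list[SubjectRecord],
    maps: list[np.ndarray],
    roi_masks: list[np.ndarray] | np.ndarray,
    valid_masks: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-subject ROI means with covariates; excluded subjects dropped.

    ``roi_masks`` may be a single shared mask or one per subject.
    """
    if isinstance(roi_masks, np.ndarray):
        roi_masks = [roi_masks] * len(records)
    rows = []
    for i, (rec, m, roi) in enumerate(zip(records, maps, roi_masks)):
        valid = None if valid_masks is None else valid_masks[i]
        mean = roi_mean(m, roi, valid)
        if mean is None:
            log.warning("subject %s excluded from ROI table", rec.id)
            continue
        rows.append(
            {
                "id": rec.id,
                "group": rec.group,
                "roi_mean": mean,
                "age": rec.age,
                "tiv": rec.tiv,
                "bdi": rec.bdi,
                "stai": rec.stai,
                "med_months": rec.med_months,
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    table: pd.DataFrame, covariates: tuple[str, ...] = ()
) -> dict[str, float]:
    """Compare ROI means between groups.

    Unadjusted mode (no covariates) is the one-way ANOVA; the adjusted
    mode fits the GLM with the requested nuisance covariates.  Returns a
    dict with F, df1, df2, p and the raw group difference
    (patient - control).
    """
    records = [
        SubjectRecord(
            id=r.id, group=r.group, age=r.age, tiv=r.tiv, bdi=r.bdi,
            stai=r.stai, med_months=r.med_months,
        )
        for r in table.itertuples()
    ]
    design = design_from_records(records, covariates=covariates)
    y = table["roi_mean"].to_numpy()[None, :]
    res = glm_fit(y, design, kind="F")
    means = table.groupby("group")["roi_mean"].mean()
    diff = float(means.get("patient", np.nan) - means.get("control", np.nan))
    return {
        "F": float(res.values[0]),
        "df1": res.df[0],
        "df2": res.df[1],
        "p": float(res.p[0]),
        "group_difference": diff,
    }


def covariate_correlations(
    table: pd.DataFrame, covariates: tuple[str, ...] = ("age", "med_months")
) -> pd.DataFrame:
    """Spearman correlation of ROI mean with each covariate.

    Medication duration is correlated within the patient group only (it is
    identically zero in controls); other covariates use all subjects.
    """
    rows = []
    for cov in covariates:
        sub = table if cov != "med_months" else table[table["group"] == "patient"]
        if len(sub) < 4:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = spearman_rho(sub[cov].to_numpy(), sub["roi_mean"].to_numpy())
        rows.append({"covariate": cov, "rho": rho, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
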