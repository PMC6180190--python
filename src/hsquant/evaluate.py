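"""Evaluation statistics: sensitivity/specificity, CL sweep, ROC/AUC, Fisher.

Definitions are lateralization-aware: a patient counts toward sensitivity
only when flagged abnormal *and* lateralized to the correct side (code
``p``); a detection on the wrong side (``w``) counts as a miss, as does an
undetected patient (``n``). Specificity is the fraction of controls inside
the ellipse. Sweeping the confidence level from 1 to 99% traces the ROC
curve; Youden's index (sensitivity + specificity - 1) picks the operating
point.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ellipse import classify_cohort, fit_control_ellipse

log = logging.getLogger(__name__)

METHOD_COLUMNS = ("cva_mri", "cva_pet", "q_volume", "q_flair", "q_pet")
SUBTYPES = (1, 2, 3)


def sensitivity_specificity(table: pd.DataFrame, method: str) -> tuple[float, float]:
    """(sensitivity %, specificity %) of one method column of an outcome table.

    Sensitivity = 100 * #p / #patients (correct lateralization required);
    specificity = 100 * #inside / #controls.
    """
    if method not in table.columns:
        raise ValueError(f"method column {method!r} not in table")
    patients = table[table["group"] == "patient"]
    controls = table[table["group"] == "control"]
    if len(patients) == 0:
        raise ValueError("no patient rows in table")
    if len(controls) == 0:
        raise ValueError("no control rows in table")
    sens = 100.0 * (patients[method] == "p").sum() / len(patients)
    spec = 100.0 * (controls[method] == "inside").sum() / len(controls)
    return float(sens), float(spec)


def make_control_rows(n: int, inside: dict | int | None = None,
                      methods=METHOD_COLUMNS) -> pd.DataFrame:
    """Synthesize control rows for an outcome table from summary counts.

    ``inside`` maps method -> number of controls inside the ellipse (or a
    single int / None meaning all inside). Used when a study reports control
    specificity only in aggregate.
    """
    rows = []
    for i in range(n):
        row = {"subject_id": f"C{i+1:03d}", "group": "control",
               "hs_type": None, "true_side": "none"}
        for m in methods:
            k = n if inside is None else (inside.get(m, n) if isinstance(inside, dict) else inside)
            row[m] = "inside" if i < k else "outside"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RocCurve:
    """ROC over the confidence-level sweep for one modality."""

    method: str
    points: pd.DataFrame  # columns: cl_percent, sensitivity, specificity, youden
    auc: float
    optimal_cl: float  # percent
    youden_at_optimal: float


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """Youden's J = sensitivity + specificity - 1, on the fraction scale."""
    return sensitivity_pct / 100.0 + specificity_pct / 100.0 - 1.0


def cl_sweep(
    measures: pd.DataFrame,
    modality: str,
    cl_grid=range(1, 100),
    directions: dict | None = None,
    use_f_correction: bool = False,
    require_lateralization: bool = True,
    model=None,
) -> RocCurve:
    """Trace sensitivity/specificity over the confidence-level grid.

    The control mean/covariance are fitted once; each grid value only moves
    the chi-square threshold. AUC integrates sensitivity against
    (1 - specificity) by the trapezoid rule with (0,0) and (1,1) endpoints
    appended. The optimal CL maximizes Youden's index, ties broken toward the
    smallest CL (the largest normal region among the optima).

    With ``require_lateralization`` (the default, matching the clinical
    definition) only correctly lateralized detections (code ``p``) count as
    true positives; with it off any outside patient counts, which restores
    the usual label-swap symmetry of the ROC. Passing a prefit ``model``
    skips refitting and sweeps that model's threshold instead (used to score
    a cohort against an external control model).
    """
    if model is not None:
        base = model
    else:
        controls = measures[measures["group"] == "control"]
        pts = controls[[f"{modality}_right", f"{modality}_left"]].to_numpy(dtype=float)
        base = fit_control_ellipse(pts, 0.5, modality, use_f_correction)
    rows = []
    for cl in cl_grid:
        model = base.with_cl(cl / 100.0, use_f_correction)
        table = classify_cohort(measures, {modality: model}, directions)
        if require_lateralization:
            sens, spec = sensitivity_specificity(table, modality)
        else:
            pat = table[table["group"] == "patient"]
            ctl = table[table["group"] == "control"]
            sens = 100.0 * pat[modality].isin(["p", "w"]).sum() / len(pat)
            spec = 100.0 * (ctl[modality] == "inside").sum() / len(ctl)
        rows.append(
            {"cl_percent": float(cl), "sensitivity": sens, "specificity": spec,
             "youden": youden_index(sens, spec)}
        )
    points = pd.DataFrame(rows)
    x = 1.0 - points["specificity"].to_numpy() / 100.0
    y = points["sensitivity"].to_numpy() / 100.0
    xy = np.array(sorted(zip(np.r_[x, 0.0, 1.0], np.r_[y, 0.0, 1.0])))
    auc = float(np.trapezoid(xy[:, 1], xy[:, 0]))
    best = points.loc[points["youden"].idxmax()]
    optima = points[points["youden"] == best["youden"]]
    opt = optima.sort_values("cl_percent").iloc[0]
    return RocCurve(modality, points, auc, float(opt["cl_percent"]), float(opt["youden"]))


#: The integer 1-99% sweep extended past the resubstitution ceiling: with n
#: controls scored against their own fitted ellipse, squared Mahalanobis
#: distance never exceeds (n-1)^2/n, so specificity provably reaches 100%
#: once the chi-square threshold passes that bound (CL ~ 99.996% at n=22).
EXTENDED_CL_GRID = list(range(1, 100)) + [99.9, 99.99, 99.999]


def detection_rates_by_subtype(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Detected counts and rates overall and per HS subtype (1/2/3).

    Detection = code ``p`` (correct lateralization). Raises if any subtype is
    absent from the table, naming the missing ones.
    """
    patients = table[table["group"] == "patient"]
    present = set(pd.to_numeric(patients["hs_type"], errors="coerce").dropna().astype(int))
    missing = [t for t in SUBTYPES if t not in present]
    if missing:
        raise ValueError(f"no patients with HS subtype(s): {missing}")
    rows = []
    for label, sub in [("all", patients)] + [
        (t, patients[patients["hs_type"].astype(int) == t]) for t in SUBTYPES
    ]:
        detected = int((sub[method] == "p").sum())
        rows.append(
            {"stratum": str(label), "n": len(sub), "detected": detected,
             "rate_percent": round(100.0 * detected / len(sub), 2)}
        )
    return pd.DataFrame(rows)


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's. Any zero margin
    gives p = 1 by convention.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("Fisher table entries must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        log.info("fisher_exact_two_tailed: zero margin, returning p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p by exhaustive enumeration over the
    hypergeometric support with fixed margins. Reference oracle; O(min margin)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    denom = math.comb(n, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def compare_methods(
    table: pd.DataFrame,
    reference_method: str,
    others=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Fisher comparisons of detection counts against a reference.

    Each comparison is a 2x2 detected/missed table, computed overall and for
    the single-subfield stratum (HS types 2 and 3 pooled). ``significant``
    flags p < alpha.
    """
    patients = table[table["group"] == "patient"]
    if others is None:
        others = [m for m in METHOD_COLUMNS if m in table.columns and m != reference_method]
    strata = {
        "all": patients,
        "types_2_3": patients[patients["hs_type"].astype(int).isin([2, 3])],
    }
    rows = []
    for stratum, sub in strata.items():
        n = len(sub)
        det_ref = int((sub[reference_method] == "p").sum())
        for other in others:
            det_o = int((sub[other] == "p").sum())
            p = fisher_exact_two_tailed(det_ref, n - det_ref, det_o, n - det_o)
            rows.append(
                {"stratum": stratum, "reference": reference_method, "method": other,
                 "detected_ref": det_ref, "detected_other": det_o, "n": n,
                 "p_value": p, "significant": p < alpha}
            )
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame) -> dict:
    """Descriptives: patient count, subtype counts, follow-up mean +/- SD and range."""
    patients = table[table["group"] == "patient"]
    fu = pd.to_numeric(patients["follow_up_months"], errors="coerce").dropna()
    if len(fu) == 0:
        raise ValueError("no follow-up values for patients")
    return {
        "n_patients": len(patients),
        "hs_type_counts": patients["hs_type"].astype(int).value_counts().sort_index().to_dict(),
        "follow_up_mean": round(float(fu.mean()), 2),
        "follow_up_sd": round(float(fu.std(ddof=1)), 2),
        "follow_up_min": float(fu.min()),
        "follow_up_max": float(fu.max()),
    }
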