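"""Control error-ellipse classifier with lateralization.

A healthy-control cohort's (right, left) measurement pairs for one modality
are summarized by their sample mean and covariance. Under a bivariate-normal
model, the squared Mahalanobis distance of a new point from the control mean
is approximately chi-square distributed with 2 degrees of freedom, so the
ellipse { v : (v-mu)' Sigma^-1 (v-mu) <= chi2_2(CL) } covers a fraction CL of
the control population. Subjects falling outside are flagged abnormal and
lateralized to the side whose deviation from the control mean points in the
pathological direction (volume down, FLAIR up, SUVR down) most strongly in
per-side SD units.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import BilateralMeasure
from .synthetic import PATHOLOGICAL_DIRECTION

MODALITIES = ("volume", "flair", "suvr")


@dataclass
class ControlEllipseModel:
    """Bivariate-normal control model at a confidence level.

    ``mean`` and ``covariance`` are over (right, left) pairs; ``threshold``
    is the chi-square(2 df) quantile at ``cl`` applied to squared Mahalanobis
    distance.
    """

    modality: str
    mean: np.ndarray
    covariance: np.ndarray
    cl: float
    threshold: float
    n_controls: int

    def with_cl(self, cl: float, use_f_correction: bool = False) -> "ControlEllipseModel":
        """Same fitted mean/covariance at a different confidence level."""
        return ControlEllipseModel(
            self.modality, self.mean, self.covariance, cl,
            _threshold(cl, self.n_controls, use_f_correction), self.n_controls,
        )

    def mahalanobis_sq(self, point) -> float:
        d = np.asarray(point, dtype=float) - self.mean
        return float(d @ np.linalg.solve(self.covariance, d))

    def to_json(self) -> str:
        return json.dumps(
            {
                "modality": self.modality,
                "mean": self.mean.tolist(),
                "covariance": self.covariance.tolist(),
                "cl": self.cl,
                "threshold": self.threshold,
                "n_controls": self.n_controls,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ControlEllipseModel":
        d = json.loads(text)
        return cls(
            d["modality"], np.asarray(d["mean"]), np.asarray(d["covariance"]),
            d["cl"], d["threshold"], d["n_controls"],
        )


def _threshold(cl: float, n: int, use_f_correction: bool) -> float:
    if not 0 < cl < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {cl}")
    if use_f_correction:
        # small-sample prediction ellipse for one new observation
        return 2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * stats.f.ppf(cl, 2, n - 2)
    return float(stats.chi2.ppf(cl, df=2))


def fit_control_ellipse(
    controls, cl: float, modality: str = "volume", use_f_correction: bool = False
) -> ControlEllipseModel:
    """Fit the control ellipse model from (right, left) pairs.

    Sample mean and sample covariance (n-1 denominator) are plugged into the
    chi-square(2 df) region. Requires at least 3 non-collinear controls.
    """
    pts = np.asarray(controls, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("controls must be an (n, 2) array of (right, left) pairs")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 control subjects")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 1e-12 * max(eig[1], 1e-300):
        raise ValueError("degenerate (collinear) control measurements")
    return ControlEllipseModel(
        modality, mean, cov, cl, _threshold(cl, pts.shape[0], use_f_correction),
        pts.shape[0],
    )


@dataclass
class ClassificationResult:
    subject_id: str
    modality: str
    mahalanobis_sq: float
    inside: bool
    predicted_side: str  # left | right | none

    def code(self, true_side: str) -> str:
        """p/n/w outcome code given the ground-truth side.

        ``n`` inside the ellipse; outside, ``p`` when the predicted side
        matches the truth and ``w`` otherwise (including an unlateralizable
        ``none`` prediction, scored conservatively as wrong).
        """
        if self.inside:
            return "n"
        return "p" if self.predicted_side == true_side else "w"


def classify_point(
    m, model: ControlEllipseModel, directions: dict | None = None,
    subject_id: str = "",
) -> ClassificationResult:
    """Test one (right, left) measurement against the control ellipse.

    Outside points are lateralized by the *pathological z-score*
    ``z_side = (mu_side - v_side)/sd_side`` for modalities where a decrease
    is pathological (volume, SUVR) and ``(v_side - mu_side)/sd_side`` where
    an increase is (FLAIR); the side with the larger positive z is blamed.
    If neither z is positive, or they tie exactly, the point is outside but
    unlateralizable (``predicted_side = "none"``).
    """
    directions = directions or PATHOLOGICAL_DIRECTION
    if isinstance(m, BilateralMeasure):
        if m.modality != model.modality:
            raise ValueError(f"modality mismatch: {m.modality} vs {model.modality}")
        point = m.as_point()
    else:
        point = np.asarray(m, dtype=float)
    d2 = model.mahalanobis_sq(point)
    inside = d2 <= model.threshold
    side = "none"
    if not inside:
        sd = np.sqrt(np.diag(model.covariance))
        dev = (point - model.mean) / sd  # (right, left)
        z = dev if directions[model.modality] == "high" else -dev
        if max(z) > 0 and z[0] != z[1]:
            side = "right" if z[0] > z[1] else "left"
    return ClassificationResult(subject_id, model.modality, d2, bool(inside), side)


def classify_cohort(
    measures: pd.DataFrame,
    models: dict,
    directions: dict | None = None,
) -> pd.DataFrame:
    """Classify every subject of a measurement table for each fitted modality.

    ``measures`` must carry ``subject_id, group, true_side`` and
    ``<modality>_right`` / ``<modality>_left`` columns for each modality in
    ``models``. Patients receive p/n/w codes; controls inside/outside.
    """
    for mod in models:
        missing = measures[
            measures[[f"{mod}_right", f"{mod}_left"]].isna().any(axis=1)
        ]["subject_id"].tolist()
        if missing:
            raise ValueError(f"missing {mod} measurements for subjects: {missing}")
    rows = []
    for _, rec in measures.iterrows():
        row = {
            "subject_id": rec["subject_id"],
            "group": rec["group"],
            "true_side": rec.get("true_side", "none"),
        }
        if "hs_type" in rec:
            row["hs_type"] = rec["hs_type"]
        for mod, model in models.items():
            res = classify_point(
                (rec[f"{mod}_right"], rec[f"{mod}_left"]),
                model, directions, subject_id=rec["subject_id"],
            )
            if rec["group"] == "patient":
                row[mod] = res.code(rec["true_side"])
            else:
                row[mod] = "inside" if res.inside else "outside"
        rows.append(row)
    return pd.DataFrame(rows)
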