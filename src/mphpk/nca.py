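"""Noncompartmental analysis (NCA) with the study's BLQ preprocessing rules.

Per-subject concentration-time series are first recoded:

* missing predose values, and BLQ values occurring before the first
  quantifiable concentration, become 0;
* missing postdose values, and BLQ values after the first quantifiable
  concentration, become MISSING and are excluded from every downstream
  computation.

From the cleaned series the standard parameters are derived: Cmax and tmax
(earliest time on ties), AUC0-t by the linear trapezoid rule (missing points
bridged), the terminal elimination rate λz by log-linear regression over the
best candidate terminal point set (maximum adjusted R² among all runs of ≥ 3
consecutive quantifiable points strictly after tmax and ending at the last
quantifiable point; ties prefer more points, then a later start),
t½ = ln 2/λz, and AUC0-∞ = AUC0-t + Clast/λz.

Cohort summaries follow the trial's reporting conventions: arithmetic mean
and CV% for Cmax and AUCs, median and range for tmax, mean and SD for t½.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_datasets import BLQ, MISSING, OBSERVED, ConcentrationDataset

__all__ = [
    "CleanSeries",
    "NcaResult",
    "preprocess_blq",
    "compute_cmax_tmax",
    "auc_linear_trapezoid",
    "estimate_lambda_z",
    "auc_extrapolate",
    "subject_nca",
    "run_dataset_nca",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class CleanSeries:
    """BLQ-preprocessed per-subject series; NaN marks excluded (MISSING) points."""

    times: np.ndarray
    conc: np.ndarray
    evaluable: bool


@dataclass
class NcaResult:
    """Per-subject noncompartmental parameters.

    ``lambda_z``/``t_half``/``auc_0_inf`` are None when the terminal phase is
    not estimable.  ``lambda_fit_quality`` is the adjusted R² of the selected
    log-linear terminal fit.
    """

    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: Optional[float]
    lambda_z: Optional[float]
    t_half: Optional[float]
    n_lambda_points: int
    lambda_fit_quality: Optional[float]
    evaluable: bool = True


def preprocess_blq(
    times: np.ndarray, conc: np.ndarray, status: np.ndarray
) -> CleanSeries:
    """Apply the positional BLQ/missing substitution rules to one series.

    ``conc`` is numeric with NaN at BLQ/MISSING positions; ``status`` holds
    the parse-time markers.  Quantifiable means an observed value > 0.
    Record count is preserved — values are only recoded.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    status = np.asarray(status, dtype=object)
    if not (times.shape == conc.shape == status.shape):
        raise ValueError("times, conc and status must share one shape")
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ValueError("records must be time-ordered")

    quant = (status == OBSERVED) & (conc > 0)
    out = conc.copy()
    if not quant.any():
        # no quantifiable value at all: zero the predose/BLQ positions and
        # flag the subject non-evaluable
        for i in range(times.size):
            if status[i] == BLQ or (status[i] == MISSING and times[i] <= 0):
                out[i] = 0.0
            elif status[i] == MISSING:
                out[i] = np.nan
        return CleanSeries(times=times, conc=out, evaluable=False)

    first_q = int(np.nonzero(quant)[0][0])
    for i in range(times.size):
        if status[i] == BLQ:
            out[i] = 0.0 if i < first_q else np.nan
        elif status[i] == MISSING:
            # only missing *predose* values become 0; missing postdose values
            # are excluded wherever they fall
            out[i] = 0.0 if times[i] <= 0 else np.nan
    return CleanSeries(times=times, conc=out, evaluable=True)


def compute_cmax_tmax(
    times: np.ndarray, conc: np.ndarray, subject: str = "?"
) -> tuple[float, float]:
    """Maximum observed concentration and the earliest time attaining it."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    ok = np.isfinite(conc)
    if not ok.any() or np.nanmax(conc[ok]) <= 0:
        raise ValueError(f"subject {subject}: no quantifiable concentration")
    cmax = float(np.max(conc[ok]))
    tmax = float(times[ok][np.argmax(conc[ok])])  # first index: earliest tie
    return cmax, tmax


def auc_linear_trapezoid(times: np.ndarray, conc: np.ndarray) -> float:
    """Linear-trapezoid AUC over non-missing points; NaN points are skipped by
    bridging their neighbours."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    ok = np.isfinite(conc)
    if ok.sum() < 2:
        raise ValueError("AUC needs at least 2 non-missing points")
    t, c = times[ok], conc[ok]
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(c, t))


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """OLS of ln(c) on t → (slope, adjusted R²)."""
    y = np.log(c)
    n = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(adj)


def estimate_lambda_z(
    times: np.ndarray, conc: np.ndarray, tmax: float
) -> Optional[tuple[float, int, float]]:
    """Terminal-slope estimation: ``(lambda_z, n_points, adjusted R²)``.

    Candidate sets are runs of ≥ 3 consecutive quantifiable points strictly
    after ``tmax`` ending at the last quantifiable point.  Among candidates
    with negative slope, the one with maximal adjusted R² wins; near-ties
    (within 1e-10) prefer more points, then a later starting time.  Returns
    None when no candidate yields a negative slope.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    usable = np.isfinite(conc) & (conc > 0) & (times > tmax)
    t, c = times[usable], conc[usable]
    if t.size < 3:
        return None

    candidates = []
    for start in range(t.size - 2):
        slope, adj = _loglinear(t[start:], c[start:])
        if slope < 0:
            candidates.append((adj, t.size - start, t[start], slope))
    if not candidates:
        return None
    best_adj = max(c[0] for c in candidates)
    near = [c for c in candidates if c[0] >= best_adj - 1e-10]
    adj, n_pts, _, slope = max(near, key=lambda c: (c[1], c[2]))
    return (-slope, int(n_pts), adj)


def auc_extrapolate(
    auc_0_t: float, c_last: float, lambda_z: Optional[float]
) -> Optional[float]:
    """AUC0-∞ = AUC0-t + Clast/λz; None when λz is not estimable."""
    if lambda_z is None:
        return None
    if c_last < 0:
        raise ValueError("c_last must be ≥ 0")
    return float(auc_0_t + c_last / lambda_z)


def subject_nca(
    times: np.ndarray,
    conc: np.ndarray,
    status: np.ndarray,
    subject: str = "?",
) -> NcaResult:
    """Full NCA chain for one subject's series (raw markers in, parameters out)."""
    clean = preprocess_blq(times, conc, status)
    if not clean.evaluable:
        return NcaResult(
            cmax=np.nan,
            tmax=np.nan,
            auc_0_t=np.nan,
            auc_0_inf=None,
            lambda_z=None,
            t_half=None,
            n_lambda_points=0,
            lambda_fit_quality=None,
            evaluable=False,
        )
    cmax, tmax = compute_cmax_tmax(clean.times, clean.conc, subject=subject)
    # AUC0-t runs to the last quantifiable concentration
    quant = np.isfinite(clean.conc) & (clean.conc > 0)
    last_q = int(np.nonzero(quant)[0][-1])
    t0 = clean.times[: last_q + 1].copy()
    c0 = clean.conc[: last_q + 1]
    # the predose sample (nominal t ≤ 0) anchors the curve at dose time t = 0
    t0 = np.maximum(t0, 0.0)
    keep = np.ones_like(t0, dtype=bool)
    keep[:-1] = np.diff(t0) > 0  # if several predose points collapse, keep last
    auc_0_t = auc_linear_trapezoid(t0[keep], c0[keep])

    lam = estimate_lambda_z(clean.times, clean.conc, tmax)
    if lam is None:
        lambda_z = t_half = None
        n_pts, quality = 0, None
        auc_0_inf = None
    else:
        lambda_z, n_pts, quality = lam
        t_half = float(np.log(2.0) / lambda_z)
        auc_0_inf = auc_extrapolate(auc_0_t, float(clean.conc[last_q]), lambda_z)
    return NcaResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_0_t,
        auc_0_inf=auc_0_inf,
        lambda_z=lambda_z,
        t_half=t_half,
        n_lambda_points=n_pts,
        lambda_fit_quality=quality,
    )


def run_dataset_nca(dataset: ConcentrationDataset) -> pd.DataFrame:
    """Per-subject NCA over every (subject, formulation) series in a dataset."""
    rows = []
    frame = dataset.frame
    for (subject, formulation), grp in frame.groupby(
        ["subject_id", "formulation"], sort=True
    ):
        res = subject_nca(
            grp["time_h"].to_numpy(),
            grp["conc_ng_ml"].to_numpy(),
            grp["status"].to_numpy(),
            subject=str(subject),
        )
        rows.append(
            {
                "subject_id": subject,
                "formulation": formulation,
                "cmax": res.cmax,
                "tmax": res.tmax,
                "auc_0_t": res.auc_0_t,
                "auc_0_inf": np.nan if res.auc_0_inf is None else res.auc_0_inf,
                "lambda_z": np.nan if res.lambda_z is None else res.lambda_z,
                "t_half": np.nan if res.t_half is None else res.t_half,
                "n_lambda_points": res.n_lambda_points,
                "lambda_fit_quality": (
                    np.nan if res.lambda_fit_quality is None else res.lambda_fit_quality
                ),
                "evaluable": res.evaluable,
            }
        )
    return pd.DataFrame(rows)


def _cv_pct(x: np.ndarray) -> float:
    m = np.mean(x)
    if m == 0:
        return 0.0 if np.std(x, ddof=1) == 0 else np.inf
    return float(100.0 * np.std(x, ddof=1) / m)


def summarize_cohort(results: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary per formulation in the trial's reporting conventions.

    Mean ± CV% for Cmax / AUC0-t / AUC0-∞ (arithmetic, CV% = 100·SD/mean),
    median (range) for tmax, mean (SD) for t½.  Groups with fewer than two
    evaluable subjects are excluded with a logged warning.
    """
    rows = []
    for formulation, grp in results.groupby("formulation", sort=True):
        ev = grp[grp["evaluable"]]
        if len(ev) < 2:
            logger.warning(
                "formulation %s: %d evaluable subject(s), excluded from summary",
                formulation,
                len(ev),
            )
            continue
        t_half = ev["t_half"].dropna()
        auc_inf = ev["auc_0_inf"].dropna()
        rows.append(
            {
                "formulation": formulation,
                "n_evaluable": len(ev),
                "n_total": len(grp),
                "cmax_mean": float(ev["cmax"].mean()),
                "cmax_cv_pct": _cv_pct(ev["cmax"].to_numpy()),
                "tmax_median": float(ev["tmax"].median()),
                "tmax_min": float(ev["tmax"].min()),
                "tmax_max": float(ev["tmax"].max()),
                "auc_0_t_mean": float(ev["auc_0_t"].mean()),
                "auc_0_t_cv_pct": _cv_pct(ev["auc_0_t"].to_numpy()),
                "auc_0_inf_mean": float(auc_inf.mean()) if len(auc_inf) else np.nan,
                "auc_0_inf_cv_pct": (
                    _cv_pct(auc_inf.to_numpy()) if len(auc_inf) > 1 else np.nan
                ),
                "t_half_mean": float(t_half.mean()) if len(t_half) else np.nan,
                "t_half_sd": float(t_half.std(ddof=1)) if len(t_half) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
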