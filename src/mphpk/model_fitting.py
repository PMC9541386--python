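"""Estimation of convolution-model parameters from concentration data.

Two fully specified procedures stand in for mixed-effects estimation:

* :func:`fit_pooled` — one ordinary-least-squares fit of (EC, ga, kel, vd_f)
  to all subjects' quantifiable records jointly (a "naive pooled" fit);
* :func:`fit_two_stage` — independent per-subject fits summarized by the
  geometric mean and geometric CV of the individual estimates.

Both optimize on log-parameters (positivity by construction, scale-free
steps) with ``scipy.optimize.least_squares``.  BLQ preprocessing follows the
study rules before fitting: leading zeros created by the BLQ substitution are
data; excluded (MISSING) values are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .convolution_pk import (
    MG_PER_L_TO_NG_PER_ML,
    DispositionParams,
    simulate_amount,
    simulate_concentration,
)
from .io_datasets import ConcentrationDataset
from .nca import preprocess_blq
from .release_models import SigmoidReleaseParams

__all__ = [
    "FitResult",
    "DEFAULT_BOUNDS",
    "fit_pooled",
    "fit_two_stage",
    "predict",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("ec", "ga", "kel", "vd_f")

#: generous positive parameter box (log-uniform plausible range)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "ec": (0.5, 60.0),
    "ga": (0.3, 40.0),
    "kel": (0.005, 5.0),
    "vd_f": (10.0, 1e5),
}


@dataclass
class FitResult:
    """Fitted convolution-model parameters and fit diagnostics."""

    estimates: dict[str, float]
    objective_value: float
    converged: bool
    n_observations: int
    objective_trace: list[float] = field(default_factory=list)
    per_subject_estimates: Optional[pd.DataFrame] = None
    summary: Optional[dict[str, dict[str, float]]] = None
    n_subjects_failed: int = 0

    @property
    def release(self) -> SigmoidReleaseParams:
        return SigmoidReleaseParams(ec=self.estimates["ec"], ga=self.estimates["ga"])

    @property
    def disposition(self) -> DispositionParams:
        return DispositionParams(
            kel=self.estimates["kel"], vd_f=self.estimates["vd_f"]
        )


def _fitting_records(
    dataset: ConcentrationDataset, formulation: str
) -> pd.DataFrame:
    """Quantifiable records (plus BLQ-substituted leading zeros) per subject."""
    rows = []
    frame = dataset.frame[dataset.frame["formulation"] == formulation]
    if frame.empty:
        raise ValueError(f"no records for formulation {formulation!r}")
    for subject, grp in frame.groupby("subject_id", sort=True):
        clean = preprocess_blq(
            grp["time_h"].to_numpy(),
            grp["conc_ng_ml"].to_numpy(),
            grp["status"].to_numpy(),
        )
        ok = np.isfinite(clean.conc) & (clean.times > 0)
        for t, c in zip(clean.times[ok], clean.conc[ok]):
            rows.append(
                {
                    "subject_id": subject,
                    "time_h": float(t),
                    "conc_ng_ml": float(c),
                    "dose_mg": float(grp["dose_mg"].iloc[0]),
                }
            )
    return pd.DataFrame(rows)


def _predict_conc(x: np.ndarray, times: np.ndarray, dose: float) -> np.ndarray:
    ec, ga, kel, vd_f = np.exp(x)
    release = SigmoidReleaseParams(ec=ec, ga=ga)
    disp = DispositionParams(kel=kel, vd_f=vd_f)
    profile = simulate_amount(release, disp, dose, times)
    return profile.amounts / vd_f * MG_PER_L_TO_NG_PER_ML


def _run_ls(
    obs: pd.DataFrame,
    init: dict[str, float],
    bounds: dict[str, tuple[float, float]],
    weight_proportional: bool,
) -> FitResult:
    for name in PARAM_NAMES:
        lo, hi = bounds[name]
        if not lo <= init[name] <= hi:
            raise ValueError(f"init for {name} ({init[name]}) outside bounds [{lo}, {hi}]")

    # predictions are shared across subjects observed at the same (time, dose)
    grid = obs[["time_h", "dose_mg"]].drop_duplicates().sort_values("time_h")
    doses = sorted(grid["dose_mg"].unique())
    y = obs["conc_ng_ml"].to_numpy()
    trace: list[float] = []

    def residuals(x: np.ndarray) -> np.ndarray:
        pred_map: dict[tuple[float, float], float] = {}
        for dose in doses:
            t_un = np.sort(grid.loc[grid["dose_mg"] == dose, "time_h"].unique())
            pred = _predict_conc(x, t_un, dose)
            for t, p in zip(t_un, pred):
                pred_map[(t, dose)] = p
        pred_all = np.array(
            [pred_map[(t, d)] for t, d in zip(obs["time_h"], obs["dose_mg"])]
        )
        res = pred_all - y
        if weight_proportional:
            res = res / np.maximum(pred_all, 1e-3)
        trace.append(float(np.sum(res**2)))
        return res

    x0 = np.log([init[n] for n in PARAM_NAMES])
    lb = np.log([bounds[n][0] for n in PARAM_NAMES])
    ub = np.log([bounds[n][1] for n in PARAM_NAMES])
    sol = least_squares(
        residuals, x0, bounds=(lb, ub), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    estimates = dict(zip(PARAM_NAMES, np.exp(sol.x)))
    converged = bool(sol.status > 0)
    if not converged:  # pragma: no cover - best iterate still returned
        logger.warning("optimizer did not converge: %s", sol.message)
    return FitResult(
        estimates=estimates,
        objective_value=float(2.0 * sol.cost),  # sum of squared residuals
        converged=converged,
        n_observations=len(obs),
        objective_trace=trace,
    )


def fit_pooled(
    dataset: ConcentrationDataset,
    formulation: str,
    init: dict[str, float],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    weight_proportional: bool = False,
) -> FitResult:
    """Naive pooled OLS fit of the convolution model to one formulation.

    Minimizes Σ(observed − predicted)² over all subjects' quantifiable
    records jointly.  ``weight_proportional=True`` switches to residuals
    scaled by the prediction (proportional-error weighting); the default is
    unweighted.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    obs = _fitting_records(dataset, formulation)
    n_quant = int((obs["conc_ng_ml"] > 0).sum())
    if n_quant < 8:
        raise ValueError(
            f"formulation {formulation!r}: only {n_quant} quantifiable observations"
        )
    return _run_ls(obs, init, bounds, weight_proportional)


def fit_two_stage(
    dataset: ConcentrationDataset,
    formulation: str,
    init: dict[str, float],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    weight_proportional: bool = False,
) -> FitResult:
    """Two-stage fit: independent per-subject fits, then a population summary.

    Subjects with fewer than 5 quantifiable observations or failed
    convergence are excluded and counted.  The population summary reports the
    geometric mean and geometric CV% of each parameter across subjects.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    obs = _fitting_records(dataset, formulation)
    per_subject_rows = []
    n_failed = 0
    for subject, grp in obs.groupby("subject_id", sort=True):
        if int((grp["conc_ng_ml"] > 0).sum()) < 5:
            n_failed += 1
            continue
        try:
            res = _run_ls(grp, init, bounds, weight_proportional)
        except Exception:  # pragma: no cover - defensive
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        per_subject_rows.append(
            {"subject_id": subject, **res.estimates, "objective": res.objective_value}
        )
    if len(per_subject_rows) < 2:
        raise ValueError("fewer than 2 convergent subjects; two-stage summary undefined")
    per_subject = pd.DataFrame(per_subject_rows)

    summary: dict[str, dict[str, float]] = {}
    for name in PARAM_NAMES:
        logs = np.log(per_subject[name].to_numpy())
        gm = float(np.exp(np.mean(logs)))
        gcv = float(100.0 * np.sqrt(np.expm1(np.var(logs, ddof=1))))
        summary[name] = {"geometric_mean": gm, "geometric_cv_pct": gcv}

    estimates = {n: summary[n]["geometric_mean"] for n in PARAM_NAMES}
    return FitResult(
        estimates=estimates,
        objective_value=float(per_subject["objective"].sum()),
        converged=True,
        n_observations=len(obs),
        per_subject_estimates=per_subject,
        summary=summary,
        n_subjects_failed=n_failed,
    )


def predict(
    estimates: dict[str, float], dose: float, times: np.ndarray
) -> np.ndarray:
    """Predicted concentrations (ng/mL) at ``times`` for a fitted parameter set.

    Arbitrary doses are supported exactly by the model's dose linearity.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.empty(0)
    release = SigmoidReleaseParams(ec=estimates["ec"], ga=estimates["ga"])
    disp = DispositionParams(kel=estimates["kel"], vd_f=estimates["vd_f"])
    profile = simulate_concentration(simulate_amount(release, disp, dose, times))
    return profile.concentrations
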