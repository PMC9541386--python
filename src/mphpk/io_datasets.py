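"""Tabular I/O for concentration-time and dissolution data, plus run configuration.

This module is the single source of truth for column semantics and units:

* concentration CSV — columns ``subject_id``, ``formulation`` (SI/PC/DC/OROS),
  ``period`` (integer ≥ 1), ``time_h`` (hours since dose, ≥ −1), ``conc_ng_ml``
  (ng/mL; the literal token ``BLQ`` marks a below-LLOQ observation and an empty
  field marks a missing one), ``dose_mg`` (mg, > 0);
* dissolution CSV — columns ``time_h``, ``mph_pct``, ``erythro_pct``,
  ``compound_a_pct`` (percent of label claim), optional ``formulation``.

BLQ and missing observations are carried as explicit status markers, never as
numbers: the study's BLQ substitution rules are position-dependent and are
applied downstream (``mphpk.nca.preprocess_blq``), not at parse time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dissolution_analysis import DissolutionProfile, default_media_schedule

__all__ = [
    "OBSERVED",
    "BLQ",
    "MISSING",
    "FORMULATION_CODES",
    "CONCENTRATION_COLUMNS",
    "ConcentrationDataset",
    "read_concentration_csv",
    "write_concentration_csv",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "load_run_config",
    "save_run_config",
]

OBSERVED = "observed"
BLQ = "BLQ"
MISSING = "missing"

FORMULATION_CODES = ("SI", "PC", "DC", "OROS")

CONCENTRATION_COLUMNS = (
    "subject_id",
    "formulation",
    "period",
    "time_h",
    "conc_ng_ml",
    "dose_mg",
)

#: internal frame columns (CSV columns plus the explicit status marker)
_FRAME_COLUMNS = CONCENTRATION_COLUMNS + ("status",)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": pd.Series(dtype=str),
            "formulation": pd.Series(dtype=str),
            "period": pd.Series(dtype=int),
            "time_h": pd.Series(dtype=float),
            "conc_ng_ml": pd.Series(dtype=float),
            "dose_mg": pd.Series(dtype=float),
            "status": pd.Series(dtype=str),
        }
    )


@dataclass
class ConcentrationDataset:
    """Long-format plasma concentration records for a crossover study.

    ``frame`` holds one row per (subject, formulation, sampling time); the
    ``conc_ng_ml`` column is numeric with NaN wherever ``status`` is ``BLQ``
    or ``missing``.  ``lloq`` is the lower limit of quantitation in ng/mL.
    """

    frame: pd.DataFrame = field(default_factory=_empty_frame)
    lloq: float = 0.02

    def __post_init__(self) -> None:
        if not self.lloq > 0:
            raise ValueError(f"lloq must be > 0 ng/mL, got {self.lloq}")
        self.frame = self._normalize(self.frame)

    @staticmethod
    def _normalize(frame: pd.DataFrame) -> pd.DataFrame:
        missing_cols = [c for c in _FRAME_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"dataset frame lacks required columns: {missing_cols}")
        frame = frame.loc[:, list(_FRAME_COLUMNS)].copy()
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["formulation"] = frame["formulation"].astype(str)
        frame["period"] = frame["period"].astype(int)
        for col in ("time_h", "conc_ng_ml", "dose_mg"):
            frame[col] = frame[col].astype(float)
        frame["status"] = frame["status"].astype(str)

        bad_form = set(frame["formulation"]) - set(FORMULATION_CODES)
        if bad_form:
            raise ValueError(f"unknown formulation code(s): {sorted(bad_form)}")
        bad_status = set(frame["status"]) - {OBSERVED, BLQ, MISSING}
        if bad_status:
            raise ValueError(f"unknown status marker(s): {sorted(bad_status)}")
        if (frame["period"] < 1).any():
            raise ValueError("period must be ≥ 1")
        if (frame["time_h"] < -1).any():
            raise ValueError("nominal time must be ≥ −1 h")
        if (frame["dose_mg"] <= 0).any():
            raise ValueError("dose must be > 0 mg")
        obs = frame["status"] == OBSERVED
        if frame.loc[obs, "conc_ng_ml"].lt(0).any():
            raise ValueError("observed concentrations must be ≥ 0 ng/mL")
        if frame.loc[obs, "conc_ng_ml"].isna().any():
            raise ValueError("observed records must carry a numeric concentration")
        if not frame.loc[~obs, "conc_ng_ml"].isna().all():
            raise ValueError("BLQ/missing records must not carry a number")

        frame = frame.sort_values(
            ["subject_id", "formulation", "time_h"], kind="mergesort"
        ).reset_index(drop=True)
        dup = frame.duplicated(["subject_id", "formulation", "time_h"])
        if dup.any():
            raise ValueError(
                "duplicate (subject, formulation, time) records at rows "
                f"{frame.index[dup].tolist()}"
            )
        return frame

    def __len__(self) -> int:
        return len(self.frame)

    def n_status(self, status: str) -> int:
        """Count of records carrying the given status marker."""
        return int((self.frame["status"] == status).sum())

    def subject_series(self, subject_id: str, formulation: str) -> pd.DataFrame:
        """Time-ordered records of one subject under one formulation."""
        mask = (self.frame["subject_id"] == str(subject_id)) & (
            self.frame["formulation"] == formulation
        )
        return self.frame.loc[mask].reset_index(drop=True)

    def equals(self, other: "ConcentrationDataset", rel_tol: float = 1e-12) -> bool:
        """Field-level equality; numeric fields compared to ``rel_tol`` (12
        significant digits by default)."""
        a, b = self.frame, other.frame
        if len(a) != len(b) or not math.isclose(
            self.lloq, other.lloq, rel_tol=rel_tol
        ):
            return False
        for col in ("subject_id", "formulation", "status"):
            if not (a[col].values == b[col].values).all():
                return False
        if not (a["period"].values == b["period"].values).all():
            return False
        for col in ("time_h", "conc_ng_ml", "dose_mg"):
            x, y = a[col].values, b[col].values
            both_nan = np.isnan(x) & np.isnan(y)
            close = np.isclose(x, y, rtol=rel_tol, atol=0.0, equal_nan=True)
            if not np.all(close | both_nan):
                return False
        return True


def _fmt(x: float) -> str:
    return f"{x:.17g}"  # shortest exact-roundtrip decimal is ≤ 17 digits


def read_concentration_csv(path: str | Path, lloq: float = 0.02) -> ConcentrationDataset:
    """Read a concentration CSV into a validated :class:`ConcentrationDataset`.

    The token ``BLQ`` in ``conc_ng_ml`` maps to a censored marker and an empty
    field to a missing marker; neither is ever coerced to a number.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CONCENTRATION_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(
            f"{path.name}: missing required column(s): {', '.join(missing_cols)}"
        )

    conc = np.full(len(raw), np.nan)
    status = np.empty(len(raw), dtype=object)
    for i, cell in enumerate(raw["conc_ng_ml"].str.strip()):
        if cell == BLQ:
            status[i] = BLQ
        elif cell == "":
            status[i] = MISSING
        else:
            value = float(cell)
            if value < 0:
                raise ValueError(
                    f"{path.name}: negative concentration {value} at data row {i + 1}"
                )
            conc[i] = value
            status[i] = OBSERVED

    frame = pd.DataFrame(
        {
            "subject_id": raw["subject_id"].str.strip(),
            "formulation": raw["formulation"].str.strip(),
            "period": raw["period"].astype(int),
            "time_h": raw["time_h"].astype(float),
            "conc_ng_ml": conc,
            "dose_mg": raw["dose_mg"].astype(float),
            "status": status,
        }
    )
    return ConcentrationDataset(frame=frame, lloq=lloq)


def write_concentration_csv(dataset: ConcentrationDataset, path: str | Path) -> Path:
    """Write a dataset to CSV, readable back by :func:`read_concentration_csv`."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "subject_id": dataset.frame["subject_id"],
            "formulation": dataset.frame["formulation"],
            "period": dataset.frame["period"],
            "time_h": dataset.frame["time_h"].map(_fmt),
            "conc_ng_ml": [
                _fmt(c) if s == OBSERVED else ("BLQ" if s == BLQ else "")
                for c, s in zip(dataset.frame["conc_ng_ml"], dataset.frame["status"])
            ],
            "dose_mg": dataset.frame["dose_mg"].map(_fmt),
        }
    )
    out.to_csv(path, index=False)
    return path


_DISSOLUTION_COLUMNS = ("time_h", "mph_pct", "erythro_pct", "compound_a_pct")


def read_dissolution_csv(path: str | Path) -> DissolutionProfile:
    """Read a per-species dissolution CSV into a :class:`DissolutionProfile`."""
    path = Path(path)
    raw = pd.read_csv(path)
    missing_cols = [c for c in _DISSOLUTION_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(
            f"{path.name}: missing required column(s): {', '.join(missing_cols)}"
        )
    times = raw["time_h"].astype(float).to_numpy()
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path.name}: time_h must be strictly increasing")
    code = None
    if "formulation" in raw.columns:
        codes = set(raw["formulation"].astype(str))
        if len(codes) != 1:
            raise ValueError(f"{path.name}: mixed formulation codes {sorted(codes)}")
        code = codes.pop()
    return DissolutionProfile(
        times=times,
        mph_pct=raw["mph_pct"].astype(float).to_numpy(),
        erythro_pct=raw["erythro_pct"].astype(float).to_numpy(),
        compound_a_pct=raw["compound_a_pct"].astype(float).to_numpy(),
        schedule=default_media_schedule(),
        formulation_code=code,
    )


def write_dissolution_csv(profile: DissolutionProfile, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {
            "time_h": [_fmt(t) for t in profile.times],
            "mph_pct": [_fmt(v) for v in profile.mph_pct],
            "erythro_pct": [_fmt(v) for v in profile.erythro_pct],
            "compound_a_pct": [_fmt(v) for v in profile.compound_a_pct],
        }
    )
    if profile.formulation_code is not None:
        out["formulation"] = profile.formulation_code
    out.to_csv(path, index=False)
    return path


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration (seed, cohort spec, formulation
    parameters, output directory) as a plain dictionary."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def save_run_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
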