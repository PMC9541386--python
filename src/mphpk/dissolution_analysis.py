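"""Three-stage in vitro dissolution profiles and their analysis.

The dissolution test runs in three sequential media stages emulating transit
through the gastrointestinal tract: 0.1 N HCl (0-2 h, stomach), pH 6.0
phosphate buffer (2-6 h, upper GI tract) and pH 7.2 (6-24 h, ileum), sampled
every 2 hours.  Methylphenidate is unstable at high pH, so true cumulative
release is obtained by summing the parent drug with its two main degradation
species (the erythro isomer and related compound A) — the "degradation
correction".

Release onset is read off the corrected cumulative curve as the earliest
sampling time strictly exceeding a threshold (default 1% of label claim).
The packaged fixtures emulate the observed onset pattern for the three
formulations: small intestine (SI) 6 h, proximal colon (PC) 8 h, distal colon
(DC) 10 h, with release rate ordered SI > PC > DC.

Note: the media pH is carried as metadata but never triggers release in the
fixtures — onset timing is a property of the formulation's delayed-release
layer, not of reaching a pH threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MediaStage",
    "MediaSchedule",
    "DissolutionProfile",
    "default_media_schedule",
    "corrected_cumulative_release",
    "detect_onset",
    "generate_dissolution_fixture",
    "FIXTURE_KINETICS",
]

#: upper bound (%) tolerated for corrected cumulative release (assay slack)
MAX_CORRECTED_PCT = 105.0


@dataclass(frozen=True)
class MediaStage:
    start_h: float
    end_h: float
    description: str
    ph: float


@dataclass(frozen=True)
class MediaSchedule:
    """Ordered, contiguous media stages covering the 0-24 h test."""

    stages: tuple[MediaStage, ...]

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("schedule needs at least one stage")
        prev_end = 0.0
        for st in self.stages:
            if st.start_h != prev_end:
                raise ValueError("media stages must be contiguous and start at 0 h")
            if st.end_h <= st.start_h:
                raise ValueError("media stage must have positive duration")
            prev_end = st.end_h
        if prev_end != 24.0:
            raise ValueError("media stages must cover 0-24 h")

    def stage_at(self, t: float) -> MediaStage:
        for st in self.stages:
            if st.start_h <= t < st.end_h:
                return st
        return self.stages[-1]


def default_media_schedule() -> MediaSchedule:
    return MediaSchedule(
        stages=(
            MediaStage(0.0, 2.0, "700 mL 0.1 N HCl", 1.0),
            MediaStage(2.0, 6.0, "+200 mL 0.2 M sodium phosphate tribasic", 6.0),
            MediaStage(6.0, 24.0, "+10 mL 2 N NaOH", 7.2),
        )
    )


@dataclass
class DissolutionProfile:
    """Timed per-species percent-released measurements.

    Species percentages are percent of label claim: parent methylphenidate
    (``mph_pct``), erythro isomer (``erythro_pct``) and related compound A
    (``compound_a_pct``).
    """

    times: np.ndarray
    mph_pct: np.ndarray
    erythro_pct: np.ndarray
    compound_a_pct: np.ndarray
    schedule: MediaSchedule = field(default_factory=default_media_schedule)
    formulation_code: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("mph_pct", "erythro_pct", "compound_a_pct"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match the sampling-time grid")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be ≥ 0 %")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.formulation_code is not None and self.formulation_code not in (
            "SI",
            "PC",
            "DC",
        ):
            raise ValueError(f"unknown formulation code {self.formulation_code!r}")
        corrected = self.mph_pct + self.erythro_pct + self.compound_a_pct
        if np.any(corrected > MAX_CORRECTED_PCT):
            raise ValueError(
                f"corrected cumulative release exceeds {MAX_CORRECTED_PCT}%"
            )


def corrected_cumulative_release(profile: DissolutionProfile) -> np.ndarray:
    """Degradation-corrected cumulative release (%): pointwise sum of parent
    drug and its two degradation species."""
    series = (profile.mph_pct, profile.erythro_pct, profile.compound_a_pct)
    if not all(s.shape == profile.times.shape for s in series):
        raise ValueError("per-species series must share one length")
    return series[0] + series[1] + series[2]


def detect_onset(
    profile: DissolutionProfile, threshold: float = 1.0
) -> Optional[float]:
    """Earliest sampling time (h) whose corrected cumulative release strictly
    exceeds ``threshold`` percent; ``None`` when release never exceeds it."""
    corrected = corrected_cumulative_release(profile)
    above = np.nonzero(corrected > threshold)[0]
    if above.size == 0:
        return None
    return float(profile.times[above[0]])


# Lag-plus-Weibull kinetics for the packaged fixtures:
#   release(t) = 0 for t < lag, else 100·(1 − exp(−((t−lag)/td)^ss)).
# Lags place the first supra-threshold sample at 6/8/10 h on the 2-h grid and
# the td scale ordering makes release fastest for SI, slowest for DC.
FIXTURE_KINETICS: dict[str, dict[str, float]] = {
    "SI": {"lag": 5.0, "td": 3.0, "ss": 1.2},
    "PC": {"lag": 7.0, "td": 5.0, "ss": 1.2},
    "DC": {"lag": 9.0, "td": 8.0, "ss": 1.2},
}

# split of released amount across measured species (parent / erythro / A);
# fixed values exercising the degradation-correction arithmetic
_SPECIES_SPLIT = (0.97, 0.02, 0.01)

_ONSET_THRESHOLD_DEFAULT = 1.0


def _lag_weibull(t: np.ndarray, lag: float, td: float, ss: float) -> np.ndarray:
    out = np.zeros_like(t)
    late = t > lag
    out[late] = 100.0 * -np.expm1(-(((t[late] - lag) / td) ** ss))
    return out


def generate_dissolution_fixture(
    code: str, seed: Optional[int] = None
) -> DissolutionProfile:
    """Synthetic dissolution profile for formulation ``code`` on the 2-h grid.

    Without a seed the profile is deterministic and monotone.  With a seed,
    small Gaussian measurement noise (SD 0.2% of label claim) is added per
    species and then clamped so the corrected release stays within [0, 105]%
    and the onset sample detected at the default 1% threshold never moves.
    """
    if code not in FIXTURE_KINETICS:
        raise ValueError(f"unknown formulation code {code!r}; expected SI, PC or DC")
    kin = FIXTURE_KINETICS[code]
    times = np.arange(0.0, 24.0 + 1e-9, 2.0)
    base = _lag_weibull(times, kin["lag"], kin["td"], kin["ss"])

    split = np.array(_SPECIES_SPLIT)
    species = base[:, None] * split[None, :]

    if seed is not None:
        rng = np.random.default_rng(seed)
        noisy = np.clip(species + rng.normal(0.0, 0.2, size=species.shape), 0.0, None)
        totals = noisy.sum(axis=1)
        base_below = base <= _ONSET_THRESHOLD_DEFAULT
        for i in range(len(times)):
            if totals[i] <= 0:
                continue
            if base_below[i] and totals[i] > _ONSET_THRESHOLD_DEFAULT:
                noisy[i] *= 0.9 * _ONSET_THRESHOLD_DEFAULT / totals[i]
            elif not base_below[i] and totals[i] <= _ONSET_THRESHOLD_DEFAULT:
                noisy[i] *= 1.1 * _ONSET_THRESHOLD_DEFAULT / totals[i]
            elif totals[i] > MAX_CORRECTED_PCT:
                noisy[i] *= MAX_CORRECTED_PCT / totals[i]
        species = noisy

    return DissolutionProfile(
        times=times,
        mph_pct=species[:, 0],
        erythro_pct=species[:, 1],
        compound_a_pct=species[:, 2],
        schedule=default_media_schedule(),
        formulation_code=code,
    )


def shift_profile(profile: DissolutionProfile, n_samples: int) -> DissolutionProfile:
    """Shift release later by ``n_samples`` grid steps (diagnostic helper)."""
    if n_samples < 0:
        raise ValueError("n_samples must be ≥ 0")
    def shift(arr: np.ndarray) -> np.ndarray:
        out = np.zeros_like(arr)
        if n_samples < arr.size:
            out[n_samples:] = arr[: arr.size - n_samples]
        return out
    return replace(
        profile,
        mph_pct=shift(profile.mph_pct),
        erythro_pct=shift(profile.erythro_pct),
        compound_a_pct=shift(profile.compound_a_pct),
    )
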