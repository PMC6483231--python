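"""Synthetic cohort generator with the statistical structure the analysis assumes.

Each subject receives band-limited Gaussian ROI timecourses whose per-ROI
variance is controlled exactly in expectation.  Diagnostic signal is planted
as multiplicative variance effects (ADHD/TD variance ratio per ROI,
optionally restricted to one gender), so downstream feature selection and
tree induction have a known ground truth to recover.

Demographic defaults emulate the NYU site of the ADHD-200 collection:
training 93 TD (50 F) / 117 ADHD (25 F), test 12 TD (4 F) / 29 ADHD (9 F),
with the published group means/SDs for age and IQ.  Timecourses default to
176 timepoints at TR = 2 s, band-limited to the open interval
(0.009, 0.08) Hz used by the standard resting-state preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .cohort_io import (
    Cohort,
    CohortError,
    N_AAL_ROIS,
    RoiTimeseries,
    Subject,
)


@dataclass(frozen=True)
class GroupSpec:
    """Size and demographics of one diagnosis-by-role group."""

    n: int
    age_mean: float
    age_sd: float
    iq_mean: float
    iq_sd: float
    n_female: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.n_female < 0:
            raise CohortError("group sizes must be non-negative")
        if self.n_female > self.n:
            raise CohortError(
                f"infeasible gender counts: {self.n_female} females in a group of {self.n}"
            )


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative ADHD/TD variance effect in one ROI.

    gender_scope restricts the effect to ADHD subjects of one gender
    ('F' or 'M'); 'both' applies it to all ADHD subjects.
    """

    roi_id: int
    gender_scope: str = "both"
    variance_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.roi_id <= N_AAL_ROIS:
            raise CohortError(f"planted roi_id must be in 1..{N_AAL_ROIS}, got {self.roi_id}")
        if self.gender_scope not in ("F", "M", "both"):
            raise CohortError(f"gender_scope must be F, M or both, got {self.gender_scope!r}")
        if not self.variance_ratio > 0:
            raise CohortError("variance_ratio must be positive")


def _default_groups() -> dict:
    return {
        ("TD", "training"): GroupSpec(93, 12.1, 3.1, 110.8, 13.8, 50),
        ("ADHD", "training"): GroupSpec(117, 11.3, 2.7, 107.0, 13.3, 25),
        ("TD", "test"): GroupSpec(12, 11.8, 3.0, 114.0, 13.4, 4),
        ("ADHD", "test"): GroupSpec(29, 10.3, 2.5, 103.3, 13.2, 9),
    }


def _default_effects() -> tuple:
    # Lower resting-state signal variance in ADHD within a small set of
    # regions that the blind pipeline should rediscover; one effect is
    # gender-scoped to induce a gender split at the tree root.
    return (
        PlantedEffect(15, "both", 0.25),
        PlantedEffect(40, "both", 0.25),
        PlantedEffect(88, "F", 0.25),
    )


@dataclass
class SimulationConfig:
    """Full specification of a synthetic two-arm (training/test) cohort."""

    groups: dict = field(default_factory=_default_groups)
    t_points: int = 176
    tr_seconds: float = 2.0
    band: tuple = (0.009, 0.08)
    base_sigma: np.ndarray = None
    planted_effects: tuple = field(default_factory=_default_effects)
    handedness_mean: float = 0.7
    handedness_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_sigma is None:
            self.base_sigma = np.ones(N_AAL_ROIS)
        self.base_sigma = np.asarray(self.base_sigma, dtype=float)
        if self.base_sigma.shape != (N_AAL_ROIS,) or np.any(self.base_sigma <= 0):
            raise CohortError("base_sigma must be 116 positive reals")
        if self.t_points < 2:
            raise CohortError("t_points must be >= 2")
        if not self.tr_seconds > 0:
            raise CohortError("tr_seconds must be positive")
        low, high = self.band
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < low < high < nyquist):
            raise CohortError(f"band must satisfy 0 < low < high < Nyquist ({nyquist} Hz)")
        self.planted_effects = tuple(self.planted_effects)
        ids = [e.roi_id for e in self.planted_effects]
        if len(set(ids)) != len(ids):
            raise CohortError("planted roi ids must be distinct")
        for key in (("TD", "training"), ("ADHD", "training"), ("TD", "test"), ("ADHD", "test")):
            if key not in self.groups:
                raise CohortError(f"missing group spec for {key}")

    def n_subjects(self, role: str) -> int:
        return self.groups[("TD", role)].n + self.groups[("ADHD", role)].n

    def describe(self) -> dict:
        """JSON-serializable echo of the configuration."""
        d = {
            "groups": {f"{dx}_{role}": asdict(g) for (dx, role), g in self.groups.items()},
            "t_points": self.t_points,
            "tr_seconds": self.tr_seconds,
            "band": list(self.band),
            "base_sigma": self.base_sigma.tolist(),
            "planted_effects": [asdict(e) for e in self.planted_effects],
            "handedness_mean": self.handedness_mean,
            "handedness_sd": self.handedness_sd,
            "seed": self.seed,
        }
        return d


def _band_mask(t_points: int, tr_seconds: float, band) -> np.ndarray:
    freqs = np.fft.rfftfreq(t_points, d=tr_seconds)
    low, high = band
    return (freqs > low) & (freqs < high)


def _band_weight(t_points: int, mask: np.ndarray) -> float:
    # Parseval weight of the retained bins for unit-variance white input:
    # E[sum y^2] = sum_k w_k with w = 1 for the DC/Nyquist bins, 2 otherwise.
    w = np.full(mask.size, 2.0)
    w[0] = 1.0
    if t_points % 2 == 0:
        w[-1] = 1.0
    return float(w[mask].sum())


def _band_limited_noise(rng: np.random.Generator, t_points: int, tr_seconds: float, band) -> np.ndarray:
    """T x 116 unit-variance band-limited Gaussian noise (zero mean exactly)."""
    mask = _band_mask(t_points, tr_seconds, band)
    if not mask.any():
        raise CohortError("band retains no frequency bins at this t_points/tr")
    white = rng.standard_normal((t_points, N_AAL_ROIS))
    spec = np.fft.rfft(white, axis=0)
    spec[~mask, :] = 0.0
    y = np.fft.irfft(spec, n=t_points, axis=0)
    # scale so the unbiased sample variance has expectation exactly 1
    scale = np.sqrt((t_points - 1) / _band_weight(t_points, mask))
    return y * scale


def _positive(values: np.ndarray, floor: float = 0.1) -> np.ndarray:
    return np.maximum(values, floor)


def generate_cohort(config: SimulationConfig, role: str = "training") -> Cohort:
    """Generate a cohort deterministically from ``config.seed`` and ``role``.

    Group sizes and per-group gender counts are exact; ages and IQs are
    normal draws (clipped positive, rounded to one decimal, the precision of
    the published demographic tables).  ADHD subjects' timecourses in each
    planted ROI are scaled by sqrt(variance_ratio) when their gender falls
    inside the effect's scope.
    """
    if role not in ("training", "test"):
        raise CohortError(f"role must be 'training' or 'test', got {role!r}")
    rng = np.random.default_rng([config.seed, 0 if role == "training" else 1])
    subjects = []
    timeseries = {}
    prefix = {"training": "train", "test": "test"}[role]
    for dx in ("TD", "ADHD"):
        spec = config.groups[(dx, role)]
        ages = np.round(_positive(rng.normal(spec.age_mean, spec.age_sd, spec.n)), 1)
        iqs = np.round(_positive(rng.normal(spec.iq_mean, spec.iq_sd, spec.n)), 1)
        hand = np.round(
            np.clip(rng.normal(config.handedness_mean, config.handedness_sd, spec.n), -1, 1), 2
        )
        genders = np.array(["F"] * spec.n_female + ["M"] * (spec.n - spec.n_female))
        rng.shuffle(genders)
        for i in range(spec.n):
            sid = f"sub-{prefix}-{dx}-{i + 1:04d}"
            subjects.append(
                Subject(
                    subject_id=sid,
                    age=float(ages[i]),
                    gender=str(genders[i]),
                    iq=float(iqs[i]),
                    handedness=float(hand[i]),
                    dx=dx,
                )
            )
            matrix = _band_limited_noise(rng, config.t_points, config.tr_seconds, config.band)
            matrix *= config.base_sigma[np.newaxis, :]
            if dx == "ADHD":
                for eff in config.planted_effects:
                    if eff.gender_scope in ("both", genders[i]):
                        matrix[:, eff.roi_id - 1] *= np.sqrt(eff.variance_ratio)
            timeseries[sid] = RoiTimeseries(
                matrix=matrix, tr_seconds=config.tr_seconds
            )
    return Cohort(subjects=subjects, timeseries=timeseries, role=role)


def effect_recovery_reference(config: SimulationConfig) -> dict:
    """Expected ADHD-TD gap of log per-ROI variance, per ROI id.

    For a planted effect the generative gap is log(variance_ratio) within
    the effect's gender scope; for every other ROI it is 0.  Used as ground
    truth in parameter-recovery tests.
    """
    gaps = {rid: 0.0 for rid in range(1, N_AAL_ROIS + 1)}
    for eff in config.planted_effects:
        gaps[eff.roi_id] = float(np.log(eff.variance_ratio))
    return gaps


def planted_truth(config: SimulationConfig) -> dict:
    """JSON-serializable ground-truth record of the planted effects."""
    return {
        "planted_effects": [asdict(e) for e in config.planted_effects],
        "expected_log_variance_gaps": {
            str(k): v for k, v in effect_recovery_reference(config).items() if v != 0.0
        },
    }
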