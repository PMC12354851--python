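"""Absolute activity quantification from event counts.

The camera detects a fixed fraction of decays, expressed by the sensitivity
factor ``f`` (detected events per primary decay of the parent; > 1 is possible
for decay chains emitting several alphas per parent decay). With N0 atoms at
reference time 0 and decay constant lambda, the counts recorded over an
acquisition window [t1, t2) are

    Counts(t1 -> t2) = f * N0 * (exp(-lambda t1) - exp(-lambda t2)),

and summing over all windows of a schedule gives the total counts. Inverting
for the activity at the reference time, A0 = lambda * N0:

    A0 = (lambda / f) * Counts_total / sum_i (exp(-lambda t_i1) - exp(-lambda t_i2)).

This is exact for arbitrarily long or spliced acquisitions; no constant-activity
approximation is needed. ``constant_activity_error`` quantifies how wrong that
approximation would be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .listmode import AcquisitionSchedule, CountsImage

__all__ = [
    "Isotope",
    "AC225",
    "SINGLE_ALPHA_TEST",
    "CalibrationSample",
    "CalibrationResult",
    "ActivityImage",
    "decay_weight",
    "activity_at_reference",
    "constant_activity_error",
    "fit_sensitivity",
    "detector_efficiency",
]

SECONDS_PER_DAY = 86400.0
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class Isotope:
    """An alpha emitter (or chain) characterized for quantification and dosimetry.

    ``alphas_per_primary`` counts all alpha emissions of the chain per decay of
    the parent, assuming secular equilibrium of the short-lived daughters.
    """

    name: str
    half_life_s: float
    alphas_per_primary: int
    alpha_energies_mev: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise ValueError("half_life must be positive")
        if self.alphas_per_primary < 1:
            raise ValueError("alphas_per_primary must be >= 1")
        if len(self.alpha_energies_mev) != self.alphas_per_primary:
            raise ValueError("need one alpha energy per chain alpha")

    @property
    def decay_constant(self) -> float:
        """lambda = ln 2 / half-life, in s^-1."""
        return math.log(2.0) / self.half_life_s


#: Ac-225 chain: 4 alphas per parent decay (Ac-225, Fr-221, At-217, Po-213
#: dominant lines; the 2.1% Bi-213 alpha branch is folded into the Po-213 line).
AC225 = Isotope(
    name="Ac-225",
    half_life_s=9.920 * SECONDS_PER_DAY,
    alphas_per_primary=4,
    alpha_energies_mev=(5.830, 6.341, 7.067, 8.375),
)

#: single-alpha generic isotope for tests and examples
SINGLE_ALPHA_TEST = Isotope(
    name="test-1alpha",
    half_life_s=10.0 * SECONDS_PER_DAY,
    alphas_per_primary=1,
    alpha_energies_mev=(6.0,),
)

ISOTOPES = {AC225.name: AC225, SINGLE_ALPHA_TEST.name: SINGLE_ALPHA_TEST}


@dataclass
class ActivityImage:
    """Calibrated activity map, Bq per pixel, at the schedule's reference time."""

    activity: np.ndarray
    pixel_spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    isotope: Isotope = AC225
    reference_time_label: str = "reference time 0"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if not np.isfinite(self.activity).all():
            raise ValueError("activity must be finite")
        if (self.activity < 0).any():
            raise ValueError("activity must be non-negative")

    @property
    def total_bq(self) -> float:
        return float(self.activity.sum())


def decay_weight(schedule: AcquisitionSchedule, isotope: Isotope) -> float:
    """Summed decay fractions W = sum_i (exp(-lambda t_i1) - exp(-lambda t_i2)).

    W is the fraction of atoms present at reference time 0 that decay inside the
    acquisition windows; 0 < W <= 1 for windows in [0, inf).
    """
    lam = isotope.decay_constant
    w = 0.0
    for win in schedule.windows:
        w += math.exp(-lam * win.t_start) - math.exp(-lam * win.t_end)
    return w


def activity_at_reference(
    counts: CountsImage | float | np.ndarray,
    f: float,
    isotope: Isotope,
    schedule: AcquisitionSchedule,
) -> ActivityImage | float:
    """Convert detected counts into activity (Bq) at reference time 0.

    A0 = (lambda / f) * counts / W with W from :func:`decay_weight`. Accepts a
    :class:`CountsImage` (returns :class:`ActivityImage`) or a bare scalar/array
    of counts (returns Bq of the same shape).
    """
    if f <= 0:
        raise ValueError("sensitivity factor f must be positive")
    w = decay_weight(schedule, isotope)
    if w <= 0 or not math.isfinite(w):
        raise ValueError(
            f"degenerate decay weight W={w}: schedule lies after total decay of the source"
        )
    scale = isotope.decay_constant / (f * w)
    if isinstance(counts, CountsImage):
        return ActivityImage(
            activity=counts.counts * scale,
            pixel_spacing=counts.pixel_spacing,
            origin=counts.origin,
            isotope=isotope,
            reference_time_label=schedule.reference_time_label,
        )
    return np.asarray(counts, dtype=float) * scale if np.ndim(counts) else float(counts) * scale


def constant_activity_error(duration_s: float, isotope: Isotope) -> float:
    """Relative error of the constant-activity approximation over one acquisition.

    Compares the arithmetic mean of the start- and end-of-acquisition activities
    (the "assume constant average activity" shortcut) against the exact
    exponential time-average over [0, T]. With x = lambda * T the ratio of the
    two is (x/2) coth(x/2), so the relative error is

        err(T) = (x/2) * coth(x/2) - 1,

    which vanishes as T -> 0 and grows without bound for acquisitions long
    compared to the half-life. Returned as a fraction (0.0025 = 0.25%).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    x = isotope.decay_constant * duration_s
    half = 0.5 * x
    return half / math.tanh(half) - 1.0


@dataclass
class CalibrationSample:
    """A dried calibration dot of known activity imaged over a schedule."""

    known_activity_bq: float
    measured_counts: float
    schedule: AcquisitionSchedule

    def __post_init__(self) -> None:
        if self.known_activity_bq <= 0:
            raise ValueError("known_activity must be positive")
        if self.measured_counts < 0:
            raise ValueError("measured_counts must be non-negative")

    def primary_decays(self, isotope: Isotope) -> float:
        """Number of parent decays during the imaging windows: (A0/lambda) * W."""
        n0 = self.known_activity_bq / isotope.decay_constant
        return n0 * decay_weight(self.schedule, isotope)


@dataclass
class CalibrationResult:
    """Fitted sensitivity factor f and the derived detector efficiency."""

    sensitivity_factor: float
    detector_efficiency: float
    r_squared: float
    residuals: np.ndarray
    recovered_activity_bq: np.ndarray
    low_confidence: bool = False


def fit_sensitivity(
    samples: list[CalibrationSample],
    isotope: Isotope = AC225,
    weighted: bool = True,
) -> CalibrationResult:
    """Fit the camera sensitivity factor f from a dilution series.

    Least-squares regression of measured counts onto primary decays, forced
    through the origin (zero activity cannot produce counts). Under the Poisson
    model Var(counts) = counts, so weights 1/counts are used when all counts are
    positive; otherwise the unweighted fit is used. A single-sample fit reduces
    to the plain ratio and is flagged low-confidence.
    """
    if not samples:
        raise ValueError("at least one calibration sample required")
    d = np.array([s.primary_decays(isotope) for s in samples])
    c = np.array([s.measured_counts for s in samples], dtype=float)
    if not c.any():
        raise ValueError("all calibration counts are zero; cannot fit sensitivity")

    if weighted and (c > 0).all():
        # w = 1/c  ->  f = sum(w c d)/sum(w d^2) = sum(d) / sum(d^2/c)
        f = d.sum() / (d * d / c).sum()
    else:
        f = (c * d).sum() / (d * d).sum()

    pred = f * d
    resid = c - pred
    ss_tot = ((c - c.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    weights = np.array([decay_weight(s.schedule, isotope) for s in samples])
    recovered = isotope.decay_constant * c / (f * weights)
    return CalibrationResult(
        sensitivity_factor=float(f),
        detector_efficiency=detector_efficiency(float(f), isotope.alphas_per_primary),
        r_squared=float(r2),
        residuals=resid,
        recovered_activity_bq=recovered,
        low_confidence=len(samples) < 2,
    )


def detector_efficiency(f: float, alphas_per_primary: int) -> float:
    """Fraction of incident alphas that are detected.

    The scintillator covers the sample from one side only, so only half the
    isotropically emitted alphas can ever reach it: efficiency =
    f / (0.5 * alphas_per_primary).
    """
    if f <= 0:
        raise ValueError("f must be positive")
    if alphas_per_primary < 1:
        raise ValueError("alphas_per_primary must be >= 1")
    return f / (0.5 * alphas_per_primary)


def read_calibration_table(path) -> list[CalibrationSample]:
    """Read the calibration CSV dialect.

    Columns: ``sample_id,known_activity_bq,counts,window_start_s,window_end_s``;
    samples imaged over several windows span several rows with the same id.
    """
    import pandas as pd

    df = pd.read_csv(path)
    samples = []
    for _, grp in df.groupby("sample_id", sort=False):
        schedule = AcquisitionSchedule.from_pairs(
            sorted(zip(grp["window_start_s"], grp["window_end_s"]))
        )
        samples.append(
            CalibrationSample(
                known_activity_bq=float(grp["known_activity_bq"].iloc[0]),
                measured_counts=float(grp["counts"].sum()),
                schedule=schedule,
            )
        )
    return samples
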