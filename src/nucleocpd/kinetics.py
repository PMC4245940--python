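"""First-order deamination kinetics from gel-band time courses.

The assay follows conversion of the 5-methylcytosine in a cyclobutane
pyrimidine dimer (CPD) to thymine.  Each timed aliquot yields two band
intensities after digestion to mononucleotides: one for remaining
:sup:`32`\\ P-labelled 5-methyl-dC and one for the deamination product
:sup:`32`\\ P-dT.  A terminal aliquot driven to complete deamination fixes
both the photoproduct yield and the normalisation of the deaminated
fraction.  The rate constant is the negative slope of an ordinary
least-squares line through ln(remaining CPD fraction) versus time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BandMeasurement",
    "TimeCourse",
    "DeaminationFit",
    "DegenerateMeasurementError",
    "InsufficientDataError",
    "deaminated_fraction",
    "cpd_remaining_fraction",
    "photoproduct_yield",
    "fit_deamination",
    "half_life_to_rate",
    "fold_change",
]

logger = logging.getLogger(__name__)

#: Expected remaining-CPD fraction below which a time point is considered
#: noise-dominated (plateau of the decay) and excluded from the log-linear
#: fit.  See docs/methods.md for the calibration rationale.
PLATEAU_FLOOR = 0.1


class DegenerateMeasurementError(ValueError):
    """Both band intensities are zero (or a terminal aliquot is unusable)."""


class InsufficientDataError(ValueError):
    """Fewer than three usable time points survive filtering."""


@dataclass(frozen=True)
class BandMeasurement:
    """One aliquot: time and the two mononucleotide band intensities.

    Parameters
    ----------
    time_h : float
        Hours since the start of the 37 degC incubation.
    intensity_mC : float
        Band signal for 5-methyl-dC (arbitrary phosphorimager units).
    intensity_T : float
        Band signal for dT (same units).
    """

    time_h: float
    intensity_mC: float
    intensity_T: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if self.intensity_mC < 0 or self.intensity_T < 0:
            raise ValueError("band intensities must be nonnegative")
        if self.intensity_mC + self.intensity_T <= 0:
            raise DegenerateMeasurementError(
                "both band intensities are zero; aliquot carries no signal"
            )

    @property
    def deaminated_fraction(self) -> float:
        return deaminated_fraction(self.intensity_mC, self.intensity_T)


@dataclass(frozen=True)
class TimeCourse:
    """All aliquots for one substrate site, plus the terminal aliquot."""

    site_id: str
    measurements: tuple[BandMeasurement, ...]
    terminal: BandMeasurement

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if len(self.measurements) < 3:
            raise InsufficientDataError(
                f"{self.site_id}: need >= 3 timed measurements, "
                f"got {len(self.measurements)}"
            )
        times = [m.time_h for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.site_id}: times must be strictly increasing")
        if self.terminal.deaminated_fraction <= 0:
            raise DegenerateMeasurementError(
                f"{self.site_id}: terminal aliquot shows no deamination"
            )

    @property
    def times_h(self) -> np.ndarray:
        return np.array([m.time_h for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class DeaminationFit:
    """Result of the log-linear first-order fit for one site.

    ``half_life_h`` always equals ``ln(2)/k``; ``half_life_se_h`` is the
    first-order error propagation ``ln(2)*k_se/k**2``.  ``yield_`` is the
    CPD photoproduct yield (fraction of sites dimerised), measured as the
    deaminated fraction of the terminal aliquot.
    """

    site_id: str
    k: float
    k_se: float
    half_life_h: float
    half_life_se_h: float
    yield_: float
    intercept: float
    r_squared: float
    n_points: int
    n_excluded: int = 0
    valid: bool = True

    @property
    def yield_percent(self) -> float:
        return 100.0 * self.yield_


def deaminated_fraction(mC: float, T: float) -> float:
    """Fraction of label found in the dT band: ``T / (T + mC)``.

    This is the raw deamination read-out of one aliquot, before
    normalisation by the terminal (fully deaminated) aliquot.
    """
    if mC < 0 or T < 0:
        raise ValueError("band intensities must be nonnegative")
    total = mC + T
    if total <= 0:
        raise DegenerateMeasurementError("both band intensities are zero")
    return T / total


def cpd_remaining_fraction(f_t: float, f_inf: float) -> float:
    """Fraction of CPDs not yet deaminated: ``1 - f_t / f_inf``.

    ``f_inf`` is the deaminated fraction of the fully deaminated terminal
    aliquot.  Under noise ``f_t`` may exceed ``f_inf``; the result is then
    nonpositive and the caller is expected to filter such points.
    """
    if f_inf <= 0:
        raise DegenerateMeasurementError("terminal deaminated fraction must be > 0")
    if f_t < 0:
        raise ValueError("deaminated fraction must be >= 0")
    return 1.0 - f_t / f_inf


def photoproduct_yield(terminal: BandMeasurement) -> float:
    """CPD photoproduct yield: deaminated fraction of the terminal aliquot."""
    return terminal.deaminated_fraction


def half_life_to_rate(half_life_h: float) -> float:
    """First-order rate constant ``ln(2) / t_1/2`` in h^-1."""
    if half_life_h <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_h}")
    return math.log(2.0) / half_life_h


def fold_change(test_value: float, reference_value: float) -> float:
    """Ratio test/reference (e.g. nucleosome vs free-DNA half-life)."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return test_value / reference_value


def _remaining_fractions(tc: TimeCourse) -> tuple[np.ndarray, np.ndarray]:
    f_inf = photoproduct_yield(tc.terminal)
    rem = np.array(
        [cpd_remaining_fraction(m.deaminated_fraction, f_inf) for m in tc.measurements]
    )
    return tc.times_h, rem


def _plateau_keep_mask(
    t: np.ndarray, rem: np.ndarray, floor: float
) -> np.ndarray:
    """Flag time points whose *expected* remaining fraction is above ``floor``.

    The expectation comes from an exponential fit on the linear scale,
    which is insensitive to the sign of individual noisy points and so can
    locate the plateau without the selection bias a threshold on observed
    values would introduce.  Falls back to keeping everything if the
    auxiliary fit fails or finds no decay.
    """
    positive = rem > 0
    try:
        (a, k_lin), _ = curve_fit(
            lambda x, a, k: a * np.exp(-k * x),
            t,
            rem,
            p0=(1.0, 0.05),
            maxfev=5000,
        )
    except RuntimeError:
        return positive
    if k_lin <= 0 or a <= 0:
        return positive
    keep = positive & (a * np.exp(-k_lin * t) >= floor)
    if keep.sum() < 3:
        # keep the three earliest usable points so short/fast courses
        # remain fittable
        idx = np.flatnonzero(positive)[:3]
        keep = np.zeros_like(positive)
        keep[idx] = True
    return keep


def fit_deamination(
    tc: TimeCourse, *, plateau_floor: float = PLATEAU_FLOOR
) -> DeaminationFit:
    """Fit the first-order deamination rate for one time course.

    Ordinary least squares of ``ln(remaining fraction)`` on time with a
    free intercept (the initial amount of dT is nonzero and varies between
    samples, so the line is not forced through the origin).  Points with
    nonpositive remaining fraction are excluded and counted, as are
    points in the noise-dominated plateau (expected remaining fraction
    below ``plateau_floor``; pass 0 to disable that guard).

    Raises
    ------
    InsufficientDataError
        If fewer than three points survive filtering.
    """
    t, rem = _remaining_fractions(tc)
    if plateau_floor > 0:
        keep = _plateau_keep_mask(t, rem, plateau_floor)
    else:
        keep = rem > 0
    n_excluded = int(len(t) - keep.sum())
    if n_excluded:
        logger.warning(
            "%s: excluded %d of %d points (nonpositive or plateau remaining fraction)",
            tc.site_id,
            n_excluded,
            len(t),
        )
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"{tc.site_id}: only {int(keep.sum())} usable points after filtering"
        )

    x = t[keep]
    y = np.log(rem[keep])
    n = len(x)
    design = np.column_stack([x, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = n - 2
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = math.sqrt(ss_res / dof / sxx) if dof > 0 and sxx > 0 else math.nan

    k = -slope
    if k <= 0:
        logger.warning("%s: nonpositive rate (slope >= 0); no detectable deamination", tc.site_id)
        return DeaminationFit(
            site_id=tc.site_id,
            k=k,
            k_se=slope_se,
            half_life_h=math.inf,
            half_life_se_h=math.inf,
            yield_=photoproduct_yield(tc.terminal),
            intercept=intercept,
            r_squared=r_squared,
            n_points=n,
            n_excluded=n_excluded,
            valid=False,
        )
    return DeaminationFit(
        site_id=tc.site_id,
        k=k,
        k_se=slope_se,
        half_life_h=math.log(2.0) / k,
        half_life_se_h=math.log(2.0) * slope_se / k**2 if not math.isnan(slope_se) else math.nan,
        yield_=photoproduct_yield(tc.terminal),
        intercept=intercept,
        r_squared=r_squared,
        n_points=n,
        n_excluded=n_excluded,
    )


def fit_many(courses: Iterable[TimeCourse], **kwargs) -> list[DeaminationFit]:
    """Fit every time course, in input order."""
    return [fit_deamination(tc, **kwargs) for tc in courses]
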