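"""Radiocarbon calibration with marine-reservoir mixing.

A conventional radiocarbon age ``age_bp ± sigma`` is calibrated against a
tabulated calibration curve μ(θ) ± σ(θ) over calendar age θ (cal BP,
present = AD 1950).  For consumers of mixed terrestrial/marine diets the
curve is a diet-weighted combination of an atmospheric curve (IntCal-style)
and a marine curve (Marine-style) shifted by a local reservoir offset ΔR:

    μ_mix(θ) = (1 − f)·μ_atm(θ) + f·(μ_mar(θ) + ΔR)
    σ_mix(θ)² = ((1 − f)·σ_atm(θ))² + (f·σ_mar(θ))² + (f·σ_ΔR)²

With a flat prior over the calendar grid the posterior at θ is proportional
to the Gaussian likelihood of the measured age given μ_mix(θ) with variance
σ² + σ_mix(θ)².  Calibrated results are reported as highest-posterior-density
(HPD) range sets, which are multi-modal whenever the curve recrosses the
measured age.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "RadiocarbonDate",
    "CalibrationCurve",
    "ReservoirCorrection",
    "MixedCurveSpec",
    "CalendarPosterior",
    "HPDRange",
    "HPDRangeSet",
    "read_curve",
    "curve_at",
    "mix_curves",
    "calibrate",
    "hpd_ranges",
    "cal_bp_to_ad",
]

#: likelihood support cutoff relative to the grid maximum
SUPPORT_EPS = 1e-12


@dataclass(frozen=True)
class RadiocarbonDate:
    """A conventional radiocarbon age (14C yr BP) with its 1σ lab error."""

    age_bp: float
    sigma: float
    lab_code: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_bp):
            raise ValueError("age_bp must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class CalibrationCurve:
    """Tabulated calendar age vs radiocarbon age with per-knot uncertainty.

    Rows are stored sorted by increasing ``cal_bp``; evaluation between
    knots is piecewise linear in both μ and σ.
    """

    name: str
    cal_bp: np.ndarray
    c14_age: np.ndarray
    c14_sigma: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_bp, dtype=float)
        mu = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.c14_sigma, dtype=float)
        if cal.size < 2:
            raise ValueError(f"curve {self.name!r} needs >= 2 rows")
        order = np.argsort(cal)
        cal, mu, sig = cal[order], mu[order], sig[order]
        if np.any(np.diff(cal) == 0):
            raise ValueError(f"curve {self.name!r} has duplicate cal_bp knots")
        if np.any(sig < 0):
            raise ValueError(f"curve {self.name!r} has negative sigma")
        self.cal_bp, self.c14_age, self.c14_sigma = cal, mu, sig

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])

    def __call__(self, cal_bp) -> tuple[np.ndarray, np.ndarray]:
        return curve_at(self, cal_bp)


@dataclass(frozen=True)
class ReservoirCorrection:
    """Local marine reservoir offset ΔR ± σ (14C yr) from the global marine curve."""

    delta_r: float = 0.0
    delta_r_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_r_sigma < 0:
            raise ValueError("delta_r_sigma must be >= 0")


@dataclass
class MixedCurveSpec:
    """Diet-weighted mix of an atmospheric and a reservoir-shifted marine curve."""

    atmospheric: CalibrationCurve
    marine: CalibrationCurve
    marine_fraction: float
    correction: ReservoirCorrection = ReservoirCorrection()

    def __post_init__(self) -> None:
        if not 0.0 <= self.marine_fraction <= 1.0:
            raise ValueError("marine_fraction must be in [0, 1]")
        lo = max(self.atmospheric.domain[0], self.marine.domain[0])
        hi = min(self.atmospheric.domain[1], self.marine.domain[1])
        if lo >= hi:
            raise ValueError("curve calendar domains do not overlap")

    @property
    def domain(self) -> tuple[float, float]:
        return (
            max(self.atmospheric.domain[0], self.marine.domain[0]),
            min(self.atmospheric.domain[1], self.marine.domain[1]),
        )

    def __call__(self, cal_bp) -> tuple[np.ndarray, np.ndarray]:
        return mix_curves(self, cal_bp)


@dataclass
class CalendarPosterior:
    """Normalized posterior mass over a uniform calendar-age grid (cal BP)."""

    grid: np.ndarray
    density: np.ndarray  # probability mass per grid point, sums to 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid/density shape mismatch")
        if np.any(self.density < 0):
            raise ValueError("negative posterior mass")
        total = self.density.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior mass {total} not normalized")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else 1.0

    def mean(self) -> float:
        return float(np.dot(self.grid, self.density))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.dot((self.grid - m) ** 2, self.density)))


@dataclass(frozen=True)
class HPDRange:
    """One calendar interval of an HPD set, in calAD years with its mass."""

    cal_ad_start: float
    cal_ad_end: float
    mass: float

    @property
    def percent(self) -> float:
        return round(100.0 * self.mass, 1)


@dataclass
class HPDRangeSet:
    level: float
    ranges: list[HPDRange]

    @property
    def total_mass(self) -> float:
        return sum(r.mass for r in self.ranges)

    def __str__(self) -> str:
        parts = [
            f"calAD {r.cal_ad_start:.0f}–{r.cal_ad_end:.0f} ({r.percent:.1f}%)"
            for r in self.ranges
        ]
        return f"{100 * self.level:.1f}% HPD: " + ", ".join(parts)


_FLOAT = r"[-+]?\d+(?:\.\d*)?(?:[eE][-+]?\d+)?"


def read_curve(path, name: str | None = None) -> CalibrationCurve:
    """Parse a calibration curve in the standard IntCal ``.14c`` layout.

    Comment lines start with ``#``; data rows are comma- or
    whitespace-separated with at least three numeric columns
    (cal BP, 14C age BP, 1σ).  Trailing Δ14C columns are ignored.
    """
    path = Path(path)
    cal, mu, sig = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in re.split(r"[,\s]+", line) if f]
            if len(fields) < 3 or not all(re.fullmatch(_FLOAT, f) for f in fields[:3]):
                raise ValueError(f"{path}:{lineno}: malformed curve row: {line!r}")
            cal.append(float(fields[0]))
            mu.append(float(fields[1]))
            sig.append(float(fields[2]))
    if len(cal) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return CalibrationCurve(name or path.stem, np.array(cal), np.array(mu), np.array(sig))


def curve_at(curve: CalibrationCurve, cal_bp) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate μ and σ at calendar age(s); no extrapolation."""
    theta = np.asarray(cal_bp, dtype=float)
    lo, hi = curve.domain
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError(f"calendar age outside curve domain [{lo}, {hi}]")
    mu = np.interp(theta, curve.cal_bp, curve.c14_age)
    sig = np.interp(theta, curve.cal_bp, curve.c14_sigma)
    return mu, sig


def mix_curves(spec: MixedCurveSpec, cal_bp) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the diet-weighted mixed curve at calendar age(s).

    With marine fraction f = 0 this returns the atmospheric curve values
    exactly (ΔR plays no role); with f = 1, the shifted marine curve.
    """
    f = spec.marine_fraction
    theta = np.asarray(cal_bp, dtype=float)
    lo, hi = spec.domain
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError(f"calendar age outside mixed-curve overlap [{lo}, {hi}]")
    mu_a, sig_a = curve_at(spec.atmospheric, theta)
    if f == 0.0:
        return mu_a, sig_a
    mu_m, sig_m = curve_at(spec.marine, theta)
    mu = (1 - f) * mu_a + f * (mu_m + spec.correction.delta_r)
    sig = np.sqrt(
        ((1 - f) * sig_a) ** 2
        + (f * sig_m) ** 2
        + (f * spec.correction.delta_r_sigma) ** 2
    )
    return mu, sig


def calibrate(
    date: RadiocarbonDate,
    curve: Union[CalibrationCurve, MixedCurveSpec],
    grid_step: float = 1.0,
) -> CalendarPosterior:
    """Calendar-age posterior of a radiocarbon date under a flat grid prior.

    The grid spans the curve domain at ``grid_step`` (years) and is trimmed
    to where the likelihood exceeds ``SUPPORT_EPS`` of its maximum.
    """
    if grid_step < 1.0:
        raise ValueError("grid_step must be >= 1 year")
    lo, hi = curve.domain
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mu, sig = curve(grid)
    var = date.sigma**2 + sig**2
    z = np.abs(date.age_bp - mu) / np.sqrt(var)
    if z.min() > 38:  # exp(-z^2/2) underflows: likelihood is zero everywhere
        raise ValueError("date has no support on the curve domain")
    # log-likelihood to stay stable far in the curve tails
    loglik = -((date.age_bp - mu) ** 2) / (2 * var) - 0.5 * np.log(var)
    loglik -= loglik.max()
    lik = np.exp(loglik)
    keep = np.nonzero(lik > SUPPORT_EPS)[0]
    grid, lik = grid[keep[0] : keep[-1] + 1], lik[keep[0] : keep[-1] + 1]
    return CalendarPosterior(grid, lik / lik.sum())


def hpd_ranges(post: CalendarPosterior, level: float = 0.954) -> HPDRangeSet:
    """Highest-posterior-density range set at the given probability level.

    Grid points are taken in decreasing density order until the cumulative
    mass reaches ``level``; adjacent selected points merge into ranges,
    reported in calAD (1950 − cal BP) with each range's own mass.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    order = np.argsort(post.density)[::-1]
    cum = np.cumsum(post.density[order])
    n_keep = int(np.searchsorted(cum, level) + 1)
    selected = np.sort(order[:n_keep])
    ranges: list[HPDRange] = []
    run_start = selected[0]
    prev = selected[0]
    for idx in selected[1:]:
        if idx != prev + 1:
            ranges.append(_make_range(post, run_start, prev))
            run_start = idx
        prev = idx
    ranges.append(_make_range(post, run_start, prev))
    # oldest (largest cal BP = smallest calAD) first
    ranges.sort(key=lambda r: r.cal_ad_start)
    return HPDRangeSet(level, ranges)


def _make_range(post: CalendarPosterior, i0: int, i1: int) -> HPDRange:
    mass = float(post.density[i0 : i1 + 1].sum())
    # grid ascends in cal BP, so calAD descends: i1 is the older bound
    return HPDRange(cal_bp_to_ad(post.grid[i1]), cal_bp_to_ad(post.grid[i0]), mass)


def cal_bp_to_ad(cal_bp: float) -> float:
    """Convert calendar years BP (present = AD 1950) to calAD."""
    return 1950 - cal_bp
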