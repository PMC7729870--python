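"""Collagen quality control and stable-isotope dietary inference.

Bone collagen preserves the stable carbon (δ13C, ‰ vs VPDB) and nitrogen
(δ15N, ‰ vs AIR) isotope composition of the diet consumed during life.
Three standard computations are provided:

* the atomic C/N ratio of extracted collagen, whose recommended range
  2.9–3.6 diagnoses well-preserved (uncontaminated) collagen;
* the marine dietary fraction, by linear two-endmember mixing of δ13C
  between a pure-terrestrial and a pure-marine reference value;
* comparison of a specimen's (δ13C, δ15N) pair against a reference
  population cluster via the Mahalanobis distance under the cluster's
  sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "MOLAR_MASS_C",
    "MOLAR_MASS_N",
    "IsotopeMeasurement",
    "CollagenQC",
    "DietEndmembers",
    "ReferenceCluster",
    "ClusterDistance",
    "atomic_cn_ratio",
    "collagen_qc",
    "marine_fraction",
    "d13c_from_fraction",
    "cluster_distance",
    "read_measurements",
    "read_reference_cluster",
]

MOLAR_MASS_C = 12.011  # g/mol
MOLAR_MASS_N = 14.007  # g/mol

#: C/N range diagnostic of well-preserved bone collagen (inclusive).
DEFAULT_CN_RANGE = (2.9, 3.6)

#: Default δ13C mixing endmembers (‰): terrestrial and marine diet.
DEFAULT_ENDMEMBERS = (-21.0, -12.5)


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One specimen's collagen elemental and isotopic measurements."""

    specimen_id: str
    d13C: float  # ‰ vs VPDB
    d15N: float  # ‰ vs AIR
    carbon_pct: float  # weight %
    nitrogen_pct: float  # weight %

    d13C_bounds = (-40.0, 0.0)
    d15N_bounds = (-5.0, 30.0)

    def __post_init__(self) -> None:
        if not (self.carbon_pct > 0 and self.nitrogen_pct > 0):
            raise ValueError("carbon_pct and nitrogen_pct must be positive")
        lo, hi = self.d13C_bounds
        if not lo <= self.d13C <= hi:
            raise ValueError(f"d13C {self.d13C} outside sanity bounds {self.d13C_bounds}")
        lo, hi = self.d15N_bounds
        if not lo <= self.d15N <= hi:
            raise ValueError(f"d15N {self.d15N} outside sanity bounds {self.d15N_bounds}")


@dataclass(frozen=True)
class CollagenQC:
    atomic_cn_ratio: float
    within_recommended: bool
    recommended_range: tuple[float, float] = DEFAULT_CN_RANGE

    def __str__(self) -> str:
        verdict = "within" if self.within_recommended else "outside"
        lo, hi = self.recommended_range
        return f"atomic C/N = {self.atomic_cn_ratio:.1f} ({verdict} recommended [{lo}, {hi}])"


@dataclass(frozen=True)
class DietEndmembers:
    """δ13C values (‰) of pure-terrestrial and pure-marine diets."""

    d13C_terrestrial: float = DEFAULT_ENDMEMBERS[0]
    d13C_marine: float = DEFAULT_ENDMEMBERS[1]

    def __post_init__(self) -> None:
        if self.d13C_terrestrial == self.d13C_marine:
            raise ValueError("endmembers must be distinct")


def atomic_cn_ratio(carbon_pct: float, nitrogen_pct: float) -> float:
    """Molar carbon-to-nitrogen ratio from collagen weight percentages.

    Returns ``(carbon_pct / 12.011) / (nitrogen_pct / 14.007)``.
    """
    if carbon_pct <= 0 or nitrogen_pct <= 0:
        raise ValueError("weight percentages must be positive")
    return (carbon_pct / MOLAR_MASS_C) / (nitrogen_pct / MOLAR_MASS_N)


def collagen_qc(
    m: IsotopeMeasurement,
    recommended_range: tuple[float, float] = DEFAULT_CN_RANGE,
) -> CollagenQC:
    """Flag a specimen against the recommended collagen C/N range (inclusive)."""
    lo, hi = recommended_range
    if lo >= hi:
        raise ValueError(f"invalid recommended range [{lo}, {hi}]")
    ratio = atomic_cn_ratio(m.carbon_pct, m.nitrogen_pct)
    return CollagenQC(ratio, lo <= ratio <= hi, (lo, hi))


def marine_fraction(d13C: float, em: DietEndmembers = DietEndmembers()) -> float:
    """Marine dietary fraction by linear endmember mixing, clamped to [0, 1].

    f = (δ13C − δ13C_terrestrial) / (δ13C_marine − δ13C_terrestrial).
    """
    f = (d13C - em.d13C_terrestrial) / (em.d13C_marine - em.d13C_terrestrial)
    return min(1.0, max(0.0, f))


def d13c_from_fraction(f: float, em: DietEndmembers = DietEndmembers()) -> float:
    """Inverse of :func:`marine_fraction` (unclamped)."""
    return em.d13C_terrestrial + f * (em.d13C_marine - em.d13C_terrestrial)


@dataclass
class ReferenceCluster:
    """A reference population's (δ13C, δ15N) scatter with sample moments."""

    label: str
    members: np.ndarray  # shape (n, 2)
    mean: np.ndarray = field(init=False)
    covariance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        if self.members.ndim != 2 or self.members.shape[1] != 2:
            raise ValueError("members must be an (n, 2) array of (d13C, d15N)")
        if len(self.members) < 3:
            raise ValueError("need >= 3 members to estimate a covariance")
        self.mean = self.members.mean(axis=0)
        self.covariance = np.cov(self.members, rowvar=False, ddof=1)

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterDistance:
    mahalanobis: float
    inside_ellipse: bool
    level: float


def cluster_distance(
    point: tuple[float, float],
    cluster: ReferenceCluster,
    level: float = 0.95,
) -> ClusterDistance:
    """Mahalanobis distance of a point to a reference cluster.

    ``inside_ellipse`` is true iff the squared distance does not exceed the
    chi-square(2 df) quantile at ``level``, i.e. the point falls inside the
    corresponding probability ellipse of the fitted bivariate normal.
    """
    cov = cluster.covariance
    # reject numerically singular covariances (degenerate clusters)
    if np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(f"cluster {cluster.label!r} covariance is singular")
    diff = np.asarray(point, dtype=float) - cluster.mean
    d2 = float(diff @ np.linalg.solve(cov, diff))
    return ClusterDistance(np.sqrt(d2), d2 <= chi2.ppf(level, df=2), level)


def read_measurements(path) -> list[IsotopeMeasurement]:
    """Read specimen measurements from CSV/TSV with columns
    specimen_id, d13C, d15N, carbon_pct, nitrogen_pct."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"specimen_id", "d13C", "d15N", "carbon_pct", "nitrogen_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        IsotopeMeasurement(
            str(r.specimen_id), float(r.d13C), float(r.d15N),
            float(r.carbon_pct), float(r.nitrogen_pct),
        )
        for r in df.itertuples()
    ]


def read_reference_cluster(path, label: str | None = None) -> ReferenceCluster:
    """Read a reference cluster from CSV with columns label, d13C, d15N."""
    df = pd.read_csv(path, sep=None, engine="python")
    if label is not None:
        df = df[df["label"] == label]
    elif df["label"].nunique() > 1:
        raise ValueError("multiple labels in file; pass label= to select one")
    if df.empty:
        raise ValueError(f"no rows for label {label!r}")
    return ReferenceCluster(
        label or str(df["label"].iloc[0]),
        df[["d13C", "d15N"]].to_numpy(dtype=float),
    )
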