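"""Aggregation-propensity metrics from per-frame cluster counts.

The central statistic is **fC_5**: the percentage of analysed frames
in which the solute molecules form fewer than five clusters
(``N_c < 5``, strict).  Persistent low cluster counts mean the
molecules spend the trajectory fused into a few large aggregates — the
signature of a small colloidally aggregating molecule (SCAM) — while a
dispersed compound keeps ``N_c`` near the number of molecules and its
fC_5 near zero.  Compounds whose fC_5 falls below ~20% behave as
experimental non-aggregators; known aggregators sit at 36% and above,
so the default decision threshold splits that band at 20%.

The population profile P(k) — the percentage of frames with
``N_c = k`` — characterises the regime qualitatively: mass piled
toward k = 1 (aggregated), toward k = N_mol (dispersed), or an
interior bell (intermediate, polydisperse clustering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import NcSeries

__all__ = [
    "PopulationProfile",
    "AggregationReport",
    "population_profile",
    "fraction_below",
    "classify",
    "profile_shape",
    "analyze_series",
    "replicate_summary",
    "DEFAULT_K",
    "DEFAULT_THRESHOLD",
    "AGGREGATOR",
    "NON_AGGREGATOR",
]

#: Cluster-count threshold defining fC_5 (frames with N_c < 5 count).
DEFAULT_K = 5
#: Classification threshold on fC_5, percent.
DEFAULT_THRESHOLD = 20.0

AGGREGATOR = "aggregator"
NON_AGGREGATOR = "non-aggregator"

_SHAPES = ("aggregated-exponential", "dispersed-exponential", "bell")


@dataclass(frozen=True)
class PopulationProfile:
    """P(k): percentage of frames with N_c = k, for k = 1..N_mol."""

    percent: np.ndarray  # index 0 <-> k = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.percent, dtype=float)
        if (p < -1e-12).any():
            raise ValueError("population percentages must be non-negative")
        if abs(p.sum() - 100.0) > 1e-9:
            raise ValueError(f"population must sum to 100, got {p.sum()!r}")
        object.__setattr__(self, "percent", p)

    @property
    def n_molecules(self) -> int:
        return self.percent.size

    def __getitem__(self, k: int) -> float:
        """P(k) in percent for cluster count ``k`` (1-based)."""
        if not 1 <= k <= self.n_molecules:
            raise IndexError(f"k = {k} outside [1, {self.n_molecules}]")
        return float(self.percent[k - 1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": np.arange(1, self.n_molecules + 1), "percent": self.percent}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class AggregationReport:
    """fC_5 result plus classification for one compound/trajectory."""

    fc5: float  # percent
    label: str
    shape: str | None = None
    compound_id: str | None = None
    n_molecules: int | None = None
    cutoff: float | None = None
    k_threshold: int = DEFAULT_K
    classify_threshold: float = DEFAULT_THRESHOLD
    n_frames: int | None = None
    replica_fc5: tuple[float, ...] = ()
    fc5_mean: float | None = None
    fc5_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fc5 <= 100.0:
            raise ValueError(f"fC_5 must lie in [0, 100], got {self.fc5}")
        if self.label not in (AGGREGATOR, NON_AGGREGATOR):
            raise ValueError(f"unknown class label {self.label!r}")
        if self.shape is not None and self.shape not in _SHAPES:
            raise ValueError(f"unknown profile shape {self.shape!r}")

    def parameters(self) -> tuple:
        """Analysis parameters that must match across replicas."""
        return (self.cutoff, self.k_threshold, self.classify_threshold)

    def to_dict(self) -> dict:
        out = {
            "compound_id": self.compound_id,
            "n_mol": self.n_molecules,
            "cutoff": self.cutoff,
            "n_frames": self.n_frames,
            "fc5_percent": self.fc5,
            "class": self.label,
            "shape": self.shape,
            "k_threshold": self.k_threshold,
            "classify_threshold": self.classify_threshold,
        }
        if self.replica_fc5:
            out["replicas"] = list(self.replica_fc5)
            out["fc5_mean"] = self.fc5_mean
            out["fc5_sd"] = self.fc5_sd
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def population_profile(series: NcSeries) -> PopulationProfile:
    """Population distribution P(k) over cluster counts, percent.

    ``P(k) = 100 * (#frames with N_c = k) / (#frames)`` for
    ``k = 1..N_mol``.
    """
    if len(series) == 0:
        raise ValueError("cannot profile an empty N_c series")
    counts = np.bincount(series.nc, minlength=series.n_molecules + 1)[1:]
    return PopulationProfile(100.0 * counts / len(series))


def fraction_below(series: NcSeries, k: int = DEFAULT_K) -> float:
    """Percentage of frames with ``N_c < k`` (strict inequality).

    ``fraction_below(series, 5)`` is fC_5.  Frames with ``N_c = k``
    exactly are excluded from the numerator.
    """
    if len(series) == 0:
        raise ValueError("cannot compute fC on an empty N_c series")
    if not 1 <= k <= series.n_molecules + 1:
        raise ValueError(
            f"k = {k} outside [1, {series.n_molecules + 1}] for "
            f"{series.n_molecules} molecules"
        )
    return float(100.0 * np.count_nonzero(series.nc < k) / len(series))


def classify(fc5: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Aggregator / non-aggregator call from fC_5.

    ``aggregator`` iff ``fc5 >= threshold`` (percent).  The default 20%
    threshold sits in the empirical gap between non-aggregators
    (fC_5 < 20%) and the weakest known aggregators (fC_5 >= 36%).
    """
    if not 0.0 <= fc5 <= 100.0:
        raise ValueError(f"fC_5 must lie in [0, 100], got {fc5}")
    return AGGREGATOR if fc5 >= threshold else NON_AGGREGATOR


def profile_shape(profile: PopulationProfile, band: float = 0.2) -> str:
    """Heuristic shape label for a population profile.

    The profile mode within the lowest ``band`` fraction of the k-range
    is ``aggregated-exponential`` (mass decaying from k = 1), within the
    top band ``dispersed-exponential`` (mass decaying from k = N_mol),
    otherwise ``bell`` (interior mode, polydisperse clustering).  Ties
    in P(k) break toward the extremes.
    """
    p = profile.percent
    n = profile.n_molecules
    peak = p.max()
    modes = np.nonzero(p == peak)[0] + 1  # 1-based k of all tied modes
    lo_edge = 1 + band * (n - 1)
    hi_edge = n - band * (n - 1)
    if modes.min() < lo_edge:
        return "aggregated-exponential"
    if modes.max() > hi_edge:
        return "dispersed-exponential"
    return "bell"


def analyze_series(
    series: NcSeries,
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    compound_id: str | None = None,
) -> AggregationReport:
    """Full report (fC_5, class, profile shape) for one N_c series."""
    fc5 = fraction_below(series, k)
    return AggregationReport(
        fc5=fc5,
        label=classify(fc5, threshold),
        shape=profile_shape(population_profile(series)),
        compound_id=compound_id,
        n_molecules=series.n_molecules,
        cutoff=series.cutoff,
        k_threshold=k,
        classify_threshold=threshold,
        n_frames=len(series),
    )


def replicate_summary(reports: Sequence[AggregationReport]) -> AggregationReport:
    """Combine replica reports: mean fC_5, sample SD, class from the mean.

    All replicas must share analysis parameters (cutoff, k, threshold).
    The standard deviation uses the sample (n-1) convention and is
    reported only with two or more replicas.
    """
    if not reports:
        raise ValueError("need at least one replica report")
    params = {r.parameters() for r in reports}
    if len(params) > 1:
        raise ValueError(f"replicas mix analysis parameters: {sorted(params)}")
    values = np.array([r.fc5 for r in reports], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) >= 2 else None
    first = reports[0]
    return AggregationReport(
        fc5=mean,
        label=classify(mean, first.classify_threshold),
        shape=first.shape if len(reports) == 1 else None,
        compound_id=first.compound_id,
        n_molecules=first.n_molecules,
        cutoff=first.cutoff,
        k_threshold=first.k_threshold,
        classify_threshold=first.classify_threshold,
        n_frames=first.n_frames,
        replica_fc5=tuple(float(v) for v in values),
        fc5_mean=mean,
        fc5_sd=sd,
    )
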