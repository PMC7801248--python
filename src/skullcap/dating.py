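"""Ks-distribution peaks, molecular-rate calibration, event dating,
duplication timing and LTR insertion ages.

The molecular clock used throughout is K = 2 * mu * T: a pair of sequences
that split T years ago accumulates K substitutions per (synonymous) site
when each lineage substitutes at rate mu per site per year. Distribution
peaks are located by Gaussian kernel density estimation on a fixed grid;
insertion ages of LTR retrotransposons follow from the Jukes-Cantor-corrected
divergence of their two terminal repeats, which were identical at insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kaks import SaturationError, jc_correct

__all__ = [
    "DuplicationTiming",
    "EventDate",
    "KsSample",
    "LTRAge",
    "PeakEstimate",
    "RateCalibration",
    "calibrate_rate",
    "classify_duplication_timing",
    "date_event",
    "find_ks_peaks",
    "ltr_insertion_age",
    "summarize_ltr_ages",
]

MY = 1e6


@dataclass
class KsSample:
    values: np.ndarray
    source: str = "ortholog"  # ortholog | paralog
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("Ks values must be finite and nonnegative")


@dataclass
class PeakEstimate:
    location: float
    height: float
    bandwidth: float
    n: int


@dataclass
class RateCalibration:
    mu: float
    ks_anchor: float
    t_anchor: float
    source: str = ""


@dataclass
class EventDate:
    label: str
    ks_peak: float
    mu: float
    time_years: float

    @property
    def time_mya(self) -> float:
        return self.time_years / MY


@dataclass
class DuplicationTiming:
    pair: tuple[str, str]
    ks: float
    speciation_peak: float
    margin: float
    call: str  # before_speciation | after_speciation | ambiguous


@dataclass
class LTRAge:
    element_id: str
    p: float
    K: float | None
    age_years: float | None

    @property
    def saturated(self) -> bool:
        return self.age_years is None


def find_ks_peaks(sample: KsSample, bandwidth: float = 0.05,
                  max_ks: float = 3.0, min_sample: int = 50,
                  grid_step: float = 0.001) -> list[PeakEstimate]:
    """Local maxima of a fixed-bandwidth Gaussian KDE over (0, max_ks].

    Zero values are excluded (identical pairs carry no dating signal);
    raises ValueError naming the count when fewer than min_sample values
    survive clipping. Peaks are returned sorted by density, highest first.
    """
    values = sample.values
    values = values[(values > 0) & (values <= max_ks)]
    if len(values) < min_sample:
        raise ValueError(
            f"only {len(values)} usable Ks values (need >= {min_sample})")
    grid = np.arange(0.0, max_ks + grid_step / 2, grid_step)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * bandwidth
                                                  * np.sqrt(2 * np.pi))
    interior = (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
    peaks = [PeakEstimate(location=float(grid[i + 1]),
                          height=float(density[i + 1]),
                          bandwidth=bandwidth, n=len(values))
             for i in np.nonzero(interior)[0]]
    peaks.sort(key=lambda p: -p.height)
    return peaks


def calibrate_rate(ks_peak: float, t_anchor: float,
                   source: str = "") -> RateCalibration:
    """mu = Ks / (2 T) from one (Ks peak, divergence time) anchor."""
    if ks_peak <= 0 or t_anchor <= 0:
        raise ValueError("ks_peak and t_anchor must be positive")
    return RateCalibration(mu=ks_peak / (2.0 * t_anchor), ks_anchor=ks_peak,
                           t_anchor=t_anchor, source=source)


def calibrate_rate_multi(anchors: list[tuple[float, float]],
                         source: str = "") -> RateCalibration:
    """Arithmetic mean of per-anchor rates over (Ks, time) anchors."""
    if not anchors:
        raise ValueError("need at least one anchor")
    mus = [calibrate_rate(k, t).mu for k, t in anchors]
    mu = float(np.mean(mus))
    k0, t0 = anchors[0]
    return RateCalibration(mu=mu, ks_anchor=k0, t_anchor=t0, source=source)


def date_event(ks_peak: float, mu: float, label: str = "event") -> EventDate:
    """T = Ks / (2 mu); exact inverse of calibrate_rate."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if ks_peak < 0:
        raise ValueError("ks_peak must be nonnegative")
    return EventDate(label=label, ks_peak=ks_peak, mu=mu,
                     time_years=ks_peak / (2.0 * mu))


def classify_duplication_timing(pair_ks: float, speciation_peak: float,
                                margin: float = 0.25,
                                pair: tuple[str, str] = ("", "")
                                ) -> DuplicationTiming:
    """Place a duplication before/after the speciation split by its Ks.

    after_speciation iff ks < peak*(1 - margin); before iff
    ks > peak*(1 + margin); ambiguous inside the margin band.
    """
    if speciation_peak <= 0:
        raise ValueError("speciation_peak must be positive")
    if pair_ks < speciation_peak * (1.0 - margin):
        call = "after_speciation"
    elif pair_ks > speciation_peak * (1.0 + margin):
        call = "before_speciation"
    else:
        call = "ambiguous"
    return DuplicationTiming(pair=pair, ks=pair_ks,
                             speciation_peak=speciation_peak, margin=margin,
                             call=call)


def ltr_insertion_age(ltr5: str, ltr3: str, mu: float,
                      element_id: str = "") -> LTRAge:
    """Insertion age of one LTR element from its terminal-repeat divergence.

    p = mismatching positions / compared positions (positions carrying an
    ambiguity code in either repeat are excluded from both counts);
    K = JC(p); age = K / (2 mu). Saturated elements (p >= 0.75) get age None.
    """
    if len(ltr5) != len(ltr3):
        raise ValueError(f"terminal repeats differ in length "
                         f"({len(ltr5)} vs {len(ltr3)})")
    if len(ltr5) < 100:
        raise ValueError("terminal repeats must be >= 100 bp")
    if mu <= 0:
        raise ValueError("mu must be positive")
    a = np.frombuffer(ltr5.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(ltr3.upper().encode(), dtype=np.uint8)
    acgt = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) & \
        np.isin(b, np.frombuffer(b"ACGT", dtype=np.uint8))
    if not acgt.any():
        raise ValueError("no unambiguous positions to compare")
    p = float((a[acgt] != b[acgt]).mean())
    try:
        k = jc_correct(p)
    except SaturationError:
        return LTRAge(element_id=element_id, p=p, K=None, age_years=None)
    return LTRAge(element_id=element_id, p=p, K=k, age_years=k / (2.0 * mu))


def summarize_ltr_ages(ages: list[LTRAge], bin_my: float = 0.25
                       ) -> tuple[float, float, pd.DataFrame, int]:
    """(mean, median, histogram by bin_my MY bins, n_saturated) over a cohort.

    Saturated elements are excluded from the statistics but counted.
    """
    defined = [a.age_years for a in ages if not a.saturated]
    n_sat = sum(1 for a in ages if a.saturated)
    if not defined:
        raise ValueError("all elements saturated; no defined ages")
    arr = np.array(defined) / MY
    edges = np.arange(0.0, arr.max() + bin_my, bin_my)
    if len(edges) < 2:
        edges = np.array([0.0, bin_my])
    hist, edges = np.histogram(arr, bins=edges)
    table = pd.DataFrame({"age_my_lo": edges[:-1], "age_my_hi": edges[1:],
                          "count": hist})
    return float(np.mean(arr) * MY), float(np.median(arr) * MY), table, n_sat
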