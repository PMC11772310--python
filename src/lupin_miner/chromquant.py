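"""Chromatogram construction and quantitative readouts for alkaloid profiling.

This module turns centroided LC-MS / GC-MS acquisitions into the numbers a
metabolic-engineering study reports:

* extracted ion chromatograms (XICs) at narrow m/z windows and total ion
  chromatograms (TICs);
* chromatographic peak detection and trapezoidal integration;
* internal-standard + dry-weight normalization of peak areas;
* knockout-vs-wild-type comparison (residual percent, fold change);
* %area purity with blank-run exclusion, alkaloid-content fractions, and
  enantiomeric excess from chirally resolved peak pairs.

Units throughout: retention time in minutes, m/z in Thomson, intensity in
arbitrary detector counts, areas in counts*min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import (
    BlankContradictionError,
    ConfigError,
    MissingInternalStandardError,
)

log = logging.getLogger(__name__)

#: Scale factor turning a median absolute deviation into a Gaussian sigma.
MAD_TO_SD = 1.4826


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MzWindow:
    """Closed m/z interval [center - tol, center + tol] (both ends included)."""

    center: float
    tol: float

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ConfigError(f"MzWindow tolerance must be > 0, got {self.tol}")

    @property
    def lo(self) -> float:
        return self.center - self.tol

    @property
    def hi(self) -> float:
        return self.center + self.tol

    def contains(self, mz: float) -> bool:
        return self.lo <= mz <= self.hi


@dataclass
class Scan:
    """One centroided mass spectrum: parallel m/z and intensity arrays."""

    time: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class MsRun:
    """A time-ordered sequence of centroided scans.

    Invariants (checked by :meth:`validate`): scan times strictly increasing,
    all intensities non-negative.
    """

    scans: list[Scan]
    label: str = ""

    def validate(self) -> "MsRun":
        times = np.array([s.time for s in self.scans], dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("scan times must be strictly increasing")
        for s in self.scans:
            if len(s.intensity) and np.min(s.intensity) < 0:
                raise ValueError("centroid intensities must be >= 0")
        return self

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans], dtype=float)

    # -- long-format CSV round trip (scan_time_min, mz, intensity) ----------

    def to_csv(self, path: str | Path) -> None:
        """Write the run as long-format CSV; empty scans become NaN rows so
        the time axis survives a round trip."""
        rows_t, rows_mz, rows_i = [], [], []
        for s in self.scans:
            if len(s.mz) == 0:
                rows_t.append(s.time)
                rows_mz.append(np.nan)
                rows_i.append(np.nan)
            else:
                rows_t.extend([s.time] * len(s.mz))
                rows_mz.extend(s.mz.tolist())
                rows_i.extend(s.intensity.tolist())
        pd.DataFrame(
            {"scan_time_min": rows_t, "mz": rows_mz, "intensity": rows_i}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "MsRun":
        df = pd.read_csv(path)
        scans: list[Scan] = []
        for t, grp in df.groupby("scan_time_min", sort=True):
            g = grp.dropna(subset=["mz"])
            scans.append(
                Scan(
                    time=float(t),
                    mz=g["mz"].to_numpy(dtype=float),
                    intensity=g["intensity"].to_numpy(dtype=float),
                )
            )
        return cls(scans=scans, label=label or str(path)).validate()


@dataclass
class Chromatogram:
    """Intensity-vs-time trace derived from a run (one point per scan)."""

    times: np.ndarray
    intensities: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")


@dataclass
class Peak:
    """A detected chromatographic feature.

    ``height`` is the raw apex intensity (no baseline subtraction by default)
    and ``area`` the trapezoidal integral between the boundaries.
    """

    apex_time: float
    left_time: float
    right_time: float
    height: float
    area: float
    apex_index: int = -1
    left_index: int = -1
    right_index: int = -1

    def __post_init__(self) -> None:
        if not (self.left_time < self.apex_time < self.right_time):
            raise ValueError("peak boundaries must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be >= 0")


@dataclass(frozen=True)
class AnalyteDef:
    """Quantification target: name, extraction window, expected retention time."""

    name: str
    window: MzWindow
    expected_rt: float | None = None


@dataclass
class QuantConfig:
    """All thresholds of the quantification suite.

    Defaults mirror the published analysis: six alkaloid [M+H]+ windows at
    +/-0.01 Th, caffeine as internal standard, and the m/z 137 +/- 0.5 chiral
    channel (base peak of sparteine) for enantiomer work.
    """

    analytes: dict[str, AnalyteDef] = field(default_factory=dict)
    internal_standard: str = "caffeine"
    noise_k: float = 3.0
    noise_sd: float | None = None  # None -> robust MAD estimate per trace
    rt_tolerance: float = 0.2

    def __post_init__(self) -> None:
        self._check_windows()

    def _check_windows(self) -> None:
        """Partially overlapping windows for distinct analytes would merge
        signals that must stay separate (e.g. sparteine vs angustifoline,
        0.04 Th apart). Identical windows are allowed: enantiomer pairs share
        one m/z channel and are resolved by retention time instead."""
        defs = list(self.analytes.values())
        for i in range(len(defs)):
            for j in range(i + 1, len(defs)):
                a, b = defs[i].window, defs[j].window
                if (a.lo, a.hi) == (b.lo, b.hi):
                    continue
                if a.lo <= b.hi and b.lo <= a.hi:
                    raise ConfigError(
                        f"m/z windows of {defs[i].name} and {defs[j].name} overlap"
                    )

    @classmethod
    def default(cls) -> "QuantConfig":
        mk = lambda n, c, rt, tol=0.01: AnalyteDef(n, MzWindow(c, tol), rt)
        analytes = {
            a.name: a
            for a in [
                mk("caffeine", 195.09, 3.1),
                mk("sparteine", 235.22, 4.2),
                mk("angustifoline", 235.18, 4.8),
                mk("multiflorine", 247.18, 5.4),
                mk("lupanine", 249.20, 6.0),
                mk("hydroxylupanine", 265.19, 6.8),
                mk("hydroxylupanine_ester", 429.24, 8.6),
                # chiral GC channel: both enantiomers, one window
                mk("sparteine_minus", 137.0, 6.0, 0.5),
                mk("sparteine_plus", 137.0, 6.8, 0.5),
            ]
        }
        return cls(analytes=analytes)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "internal_standard": self.internal_standard,
            "noise_k": self.noise_k,
            "noise_sd": self.noise_sd,
            "rt_tolerance": self.rt_tolerance,
            "analytes": [
                {
                    "name": a.name,
                    "mz": a.window.center,
                    "tol": a.window.tol,
                    "expected_rt": a.expected_rt,
                }
                for a in self.analytes.values()
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuantConfig":
        doc = yaml.safe_load(Path(path).read_text())
        analytes = {
            row["name"]: AnalyteDef(
                row["name"],
                MzWindow(float(row["mz"]), float(row["tol"])),
                row.get("expected_rt"),
            )
            for row in doc.get("analytes", [])
        }
        return cls(
            analytes=analytes,
            internal_standard=doc.get("internal_standard", "caffeine"),
            noise_k=float(doc.get("noise_k", 3.0)),
            noise_sd=doc.get("noise_sd"),
            rt_tolerance=float(doc.get("rt_tolerance", 0.2)),
        )


# ---------------------------------------------------------------------------
# Chromatogram construction
# ---------------------------------------------------------------------------


def extract_xic(run: MsRun, window: MzWindow) -> Chromatogram:
    """Extracted ion chromatogram: per scan, sum of centroid intensities whose
    m/z lies in the closed window. The scan time axis is preserved; scans with
    no in-window centroids contribute zero."""
    if not run.scans:
        raise ValueError("run has no scans")
    lo, hi = window.lo, window.hi
    times = np.empty(len(run.scans))
    inten = np.zeros(len(run.scans))
    for i, s in enumerate(run.scans):
        times[i] = s.time
        if len(s.mz):
            mask = (s.mz >= lo) & (s.mz <= hi)
            if mask.any():
                inten[i] = float(s.intensity[mask].sum())
    return Chromatogram(times, inten, provenance=f"XIC {window.center}+/-{window.tol}")


def total_ion_chromatogram(run: MsRun) -> Chromatogram:
    """Total ion chromatogram: per scan, sum over all centroid intensities."""
    if not run.scans:
        raise ValueError("run has no scans")
    times = np.array([s.time for s in run.scans])
    inten = np.array(
        [float(s.intensity.sum()) if len(s.intensity) else 0.0 for s in run.scans]
    )
    return Chromatogram(times, inten, provenance="TIC")


# ---------------------------------------------------------------------------
# Peak detection and integration
# ---------------------------------------------------------------------------


def estimate_noise_sd(intensities: np.ndarray) -> float:
    """Robust noise scale of a chromatographic baseline.

    Uses the larger of 1.4826 * median absolute deviation and the upper
    quartile spread (q75 - q50)/0.6745. The MAD alone collapses on centroided
    traces whose baseline is zero-inflated (detectors drop near-zero
    centroids, leaving half the points exactly zero); the one-sided quartile
    estimator recovers the correct scale there and agrees with the MAD on
    symmetric baselines.
    """
    y = np.asarray(intensities, dtype=float)
    med = np.median(y)
    mad_est = MAD_TO_SD * np.median(np.abs(y - med))
    q75 = np.quantile(y, 0.75)
    quartile_est = (q75 - med) / 0.6745
    return float(max(mad_est, quartile_est))


def _boundary(
    y: np.ndarray, apex: int, neighbour: int | None, thr: float, step: int
) -> int:
    """Boundary on one side of an apex: the first return-to-baseline point
    (below the noise floor) or the valley towards the neighbouring apex,
    whichever lies closer to the apex. ``step`` is -1 (left) or +1 (right)."""
    last = 0 if step < 0 else len(y) - 1
    limit = neighbour if neighbour is not None else last
    # nearest below-threshold point between apex and neighbour (or trace end)
    base = None
    j = apex
    while j != limit:
        j += step
        if y[j] < thr or y[j] == 0.0:
            base = j
            break
    # valley towards the neighbouring apex; only trusted when it dips well
    # below both apices (otherwise the neighbour is a shoulder/noise bump)
    valley = None
    if neighbour is not None:
        lo, hi = (neighbour, apex) if step < 0 else (apex, neighbour)
        v = lo + int(np.argmin(y[lo : hi + 1]))
        if y[v] < 0.5 * min(y[apex], y[neighbour]):
            valley = v
        elif base is None:
            valley = v  # no baseline return either: best available separator
    candidates = [c for c in (base, valley) if c is not None and c != apex]
    if not candidates:
        if neighbour is None:
            lo, hi = (last, apex) if step < 0 else (apex, last)
            c = lo + int(np.argmin(y[lo : hi + 1]))
            return c if c != apex else last
        return limit
    return min(candidates, key=lambda c: abs(c - apex))


def detect_peaks(
    chrom: Chromatogram, noise_sd: float | None = None, k: float = 3.0
) -> list[Peak]:
    """Detect chromatographic peaks as local maxima above ``k * noise_sd``.

    When ``noise_sd`` is not supplied it is estimated robustly from the trace
    (1.4826 * MAD). A prominence guard of the same magnitude keeps noise
    wiggles riding on peak flanks from counting as apices. Boundaries sit at
    the nearest of (a) return-to-baseline below the noise floor and (b) the
    valley towards the neighbouring apex, so peaks never overlap. Flat traces
    yield no peaks.
    """
    y = chrom.intensities
    t = chrom.times
    if len(y) < 5:
        raise ValueError("need at least 5 points to detect peaks")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(y)
    thr = k * noise_sd
    # strict ">" on the height criterion; fall back to >0 on noiseless traces
    height = np.nextafter(thr, np.inf) if thr > 0 else np.finfo(float).tiny
    prominence = thr if thr > 0 else None
    apices, _ = _scipy_find_peaks(y, height=height, prominence=prominence)
    if len(apices) == 0:
        return []
    peaks: list[Peak] = []
    for pos, apex in enumerate(apices):
        left_nb = int(apices[pos - 1]) if pos > 0 else None
        right_nb = int(apices[pos + 1]) if pos + 1 < len(apices) else None
        left = _boundary(y, int(apex), left_nb, thr, -1)
        right = _boundary(y, int(apex), right_nb, thr, +1)
        if not (left < apex < right):
            continue
        area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
        peaks.append(
            Peak(
                apex_time=float(t[apex]),
                left_time=float(t[left]),
                right_time=float(t[right]),
                height=float(y[apex]),
                area=area,
                apex_index=int(apex),
                left_index=int(left),
                right_index=int(right),
            )
        )
    return peaks


def integrate_peak(chrom: Chromatogram, peak: Peak) -> float:
    """Trapezoidal integral of the trace between the peak boundaries."""
    if peak.left_time >= peak.right_time:
        raise ValueError("inverted peak boundaries")
    t = chrom.times
    eps = 1e-12
    if peak.left_time < t[0] - eps or peak.right_time > t[-1] + eps:
        raise ValueError("peak boundaries outside the chromatogram time range")
    i0 = int(np.searchsorted(t, peak.left_time - eps, side="left"))
    i1 = int(np.searchsorted(t, peak.right_time + eps, side="right")) - 1
    return float(np.trapezoid(chrom.intensities[i0 : i1 + 1], t[i0 : i1 + 1]))


def match_peak(
    peaks: Sequence[Peak], expected_rt: float, tolerance: float
) -> Peak | None:
    """Nearest-apex peak within ``tolerance`` of the expected retention time.

    Equidistant candidates resolve to the larger area. Returns None (logged)
    when nothing matches.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    best: Peak | None = None
    for p in peaks:
        d = abs(p.apex_time - expected_rt)
        if d > tolerance:
            continue
        if best is None:
            best = p
            continue
        dbest = abs(best.apex_time - expected_rt)
        if d < dbest or (d == dbest and p.area > best.area):
            best = p
    if best is None:
        log.debug("no peak within %.3g min of rt %.3g", tolerance, expected_rt)
    return best


# ---------------------------------------------------------------------------
# Quantitative readouts
# ---------------------------------------------------------------------------


def normalized_abundance(
    analyte_area: float, is_area: float, dry_weight: float
) -> float:
    """Peak area normalized by the internal-standard area and dry weight (mg).

    The double ratio cancels instrument response drift (via the spiked
    standard) and sample-size variation (via the weight).
    """
    if is_area <= 0:
        raise MissingInternalStandardError(
            "internal-standard area is zero or missing; sample cannot be normalized"
        )
    if dry_weight <= 0:
        raise ValueError("dry weight must be > 0")
    return analyte_area / is_area / dry_weight


def residual_percent(wt: Sequence[float], ko: Sequence[float]) -> float:
    """Residual metabolite content of the knockout: 100 * mean(KO) / mean(WT)."""
    mwt = float(np.mean(wt))
    if mwt <= 0:
        raise ValueError(
            "mean wild-type abundance is zero; residual percent undefined "
            "(use fold_change with swapped roles instead)"
        )
    return 100.0 * float(np.mean(ko)) / mwt


def fold_change(wt: Sequence[float], ko: Sequence[float]) -> float:
    """Knockout-over-wild-type abundance ratio: mean(KO) / mean(WT)."""
    mwt = float(np.mean(wt))
    if mwt <= 0:
        raise ValueError("mean wild-type abundance is zero; fold change undefined")
    return float(np.mean(ko)) / mwt


def area_percent_purity(
    sample_peaks: Sequence[tuple[str | None, Peak]],
    blank_peaks: Sequence[Peak],
    analyte: str,
    rt_tolerance: float,
) -> float:
    """%Area purity with blank exclusion.

    The denominator is the summed area of all sample peaks that do NOT match a
    blank-run peak within ``rt_tolerance`` (column bleed and solvent artefacts
    appear in both runs and are removed). A blank match of the analyte peak
    itself is a contradiction and raises.
    """
    analyte_peak = None
    kept_area = 0.0
    for name, p in sample_peaks:
        blank_matched = any(
            abs(p.apex_time - b.apex_time) <= rt_tolerance for b in blank_peaks
        )
        if name == analyte:
            if blank_matched:
                raise BlankContradictionError(
                    f"analyte {analyte!r} peak matches a blank-run peak"
                )
            analyte_peak = p
        if not blank_matched:
            kept_area += p.area
    if analyte_peak is None:
        raise LookupError(f"analyte {analyte!r} not among the sample peaks")
    if kept_area <= 0:
        raise ValueError("no non-blank peak area to normalize against")
    return 100.0 * analyte_peak.area / kept_area


def alkaloid_fraction(
    peaks: Sequence[tuple[str, Peak]], analyte: str
) -> float:
    """Share of one alkaloid in the total alkaloid peak area, in percent.

    Assumes the peak list has already been blank-subtracted and restricted to
    alkaloids upstream.
    """
    if not peaks:
        raise ValueError("empty peak list")
    total = sum(p.area for _, p in peaks)
    for name, p in peaks:
        if name == analyte:
            if total <= 0:
                raise ValueError("total alkaloid area is zero")
            return 100.0 * p.area / total
    raise LookupError(f"analyte {analyte!r} not in peak list")


def enantiomeric_excess(area_target: float, area_antipode: float) -> float:
    """Signed enantiomeric excess in percent.

    ``100 * (A_target - A_antipode) / (A_target + A_antipode)``; positive when
    the designated enantiomer dominates, -100 for the pure antipode.
    """
    if area_target < 0 or area_antipode < 0:
        raise ValueError("peak areas must be >= 0")
    total = area_target + area_antipode
    if total <= 0:
        raise ValueError("both enantiomer areas are zero; ee undefined")
    return 100.0 * (area_target - area_antipode) / total


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------


def quantify_run(
    run: MsRun,
    config: QuantConfig,
    names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Extract, detect, match and integrate each configured analyte.

    Returns analyte -> peak area (0.0 when no matching peak is found, which is
    the honest readout for a metabolite absent from a sample).
    """
    areas: dict[str, float] = {}
    for name in names if names is not None else config.analytes:
        adef = config.analytes[name]
        xic = extract_xic(run, adef.window)
        peaks = detect_peaks(xic, noise_sd=config.noise_sd, k=config.noise_k)
        if adef.expected_rt is None:
            areas[name] = sum(p.area for p in peaks)
            continue
        match = match_peak(peaks, adef.expected_rt, config.rt_tolerance)
        areas[name] = match.area if match is not None else 0.0
    return areas
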