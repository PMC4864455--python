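"""Growth-rate estimation from OD600 plate-reader time courses.

A temperature-sensitive yeast strain carrying a human allele is grown in
liquid medium at the nonpermissive temperature and its absorbance at 600 nm
is read at a fixed cadence (every 15 min in the assays this models).  The
exponential growth rate of each culture is taken as the least-squares slope
of ln(OD) versus time during log phase, fitted over the first five doubling
times after detectable growth.  Dividing a test strain's rate by the rate of
the same ts strain expressing the wild-type human allele yields the relative
growth rate mu, the quantity the complementation scores are built from.

Times are stored in minutes throughout; rates are reported per hour, with
the unit conversion applied only at the fitting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssayInvalidError, InputError

PLATE_COLUMNS = ["well", "strain_id", "allele_class", "time_min", "od600"]

#: OD increase over baseline that counts as detectable growth.  The source
#: assays never operationalised "detectable", so this is an explicit knob.
DEFAULT_DETECT_THRESHOLD = 0.05

#: Reads per sliding window when locating the provisional (maximal) log-slope.
SLIDING_WINDOW_READS = 5


@dataclass
class GrowthCurve:
    """One well's OD600 time series.

    times : minutes, strictly increasing
    od    : absorbance at 600 nm (raw; values <= 0 are floored at fit time)
    """

    times: np.ndarray
    od: np.ndarray
    strain_id: str = ""
    allele_class: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise InputError(
                f"curve {self.strain_id!r}: times and od must be equal-length 1-D arrays"
            )
        if self.times.size < 2:
            raise InputError(f"curve {self.strain_id!r}: need at least 2 reads")
        if not np.all(np.diff(self.times) > 0):
            raise InputError(f"curve {self.strain_id!r}: times must be strictly increasing")


@dataclass
class RateEstimate:
    """Absolute exponential growth rate of one culture.

    rate        : per-hour slope of ln(OD) vs time over the fitted window
    detect_time : minutes at which growth became detectable
    window      : (start, end) minutes of the fitted region
    fit_r2      : squared Pearson correlation of the ln-linear fit
    detected    : False when the culture never exceeded baseline + threshold,
                  in which case rate is 0 by convention
    warning     : set when detection succeeded but the fit window held fewer
                  than ``min_points`` reads (treated as not detected)
    """

    rate: float
    detect_time: float | None = None
    window: tuple[float, float] | None = None
    fit_r2: float = 0.0
    detected: bool = False
    warning: str | None = None


@dataclass
class RelativeRate:
    """Relative growth rate mu = rate(test allele) / rate(wild-type allele)."""

    mu: float
    replicate_values: list[float] = field(default_factory=list)
    concordance: float | None = None

    def __post_init__(self) -> None:
        if not self.replicate_values:
            self.replicate_values = [self.mu]


def read_plate(path) -> list[GrowthCurve]:
    """Read a tidy plate CSV (well, strain_id, allele_class, time_min, od600).

    Rows within a well are sorted by time before curve construction; a
    negative OD value is rejected with the offending row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"plate file {path}: missing columns {missing}")
    for col in ("time_min", "od600"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise InputError(f"plate file {path}: non-numeric {col} at row {bad[0] + 2}")
        df[col] = vals
    if df[["time_min", "od600"]].isna().any().any():
        row = int(df.index[df[["time_min", "od600"]].isna().any(axis=1)][0])
        raise InputError(f"plate file {path}: missing value at row {row + 2}")
    neg = df.index[df["od600"] < 0]
    if len(neg):
        r = int(neg[0])
        raise InputError(
            f"plate file {path}: negative od600 at row {r + 2} (well {df.loc[r, 'well']})"
        )
    curves = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        if grp["time_min"].duplicated().any():
            raise InputError(f"plate file {path}: duplicate time in well {well}")
        curves.append(
            GrowthCurve(
                times=grp["time_min"].to_numpy(),
                od=grp["od600"].to_numpy(),
                strain_id=str(grp["strain_id"].iloc[0]),
                allele_class=str(grp["allele_class"].iloc[0]),
            )
        )
    return curves


def _floor_od(od: np.ndarray) -> np.ndarray:
    """Replace values <= 0 by half the smallest positive OD (log must be defined)."""
    positive = od[od > 0]
    if positive.size == 0:
        return np.full_like(od, np.nan)
    return np.where(od > 0, od, positive.min() / 2.0)


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on t."""
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def _window_slope(times_h: np.ndarray, ln_od: np.ndarray, width: int) -> float:
    """Maximum least-squares slope over all ``width``-read sliding windows."""
    n = times_h.size
    width = min(width, n)
    if width < 2:
        return -np.inf
    best = -np.inf
    for i in range(n - width + 1):
        best = max(best, _ls_slope(times_h[i : i + width], ln_od[i : i + width]))
    return best


def estimate_rate(
    curve: GrowthCurve,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    min_points: int = 5,
) -> RateEstimate:
    """Estimate the exponential growth rate (per hour) of one culture.

    Growth is detected at the first read where OD exceeds baseline (mean of
    the first three reads) by ``detect_threshold``.  A provisional rate is
    taken as the maximum sliding-window slope of ln(OD) vs time (5-read
    windows), and defines a hard cap of five doubling times after detection.
    Within that cap the log-phase fit window starts at detection and its end
    is chosen to maximise the R^2 of the ln-linear fit (near-ties resolved
    toward the longer window), so saturating reads do not drag the slope
    down.  The reported rate is the least-squares slope over that window.
    """
    if detect_threshold <= 0:
        raise InputError("detect_threshold must be > 0")
    od = _floor_od(curve.od)
    if np.isnan(od).any():
        return RateEstimate(rate=0.0, detected=False, warning="no positive OD values")
    baseline = float(np.mean(od[: min(3, od.size)]))
    above = np.nonzero(od >= baseline + detect_threshold)[0]
    if above.size == 0:
        return RateEstimate(rate=0.0, detected=False)
    i_detect = int(above[0])
    t_detect = float(curve.times[i_detect])

    ln_od = np.log(od)
    times_h = curve.times / 60.0
    provisional = _window_slope(
        times_h[i_detect:], ln_od[i_detect:], SLIDING_WINDOW_READS
    )
    if not np.isfinite(provisional) or provisional <= 0:
        return RateEstimate(rate=0.0, detected=False, warning="no positive log-slope")

    t_end = t_detect + 5.0 * (np.log(2.0) / provisional) * 60.0
    in_cap = np.nonzero((curve.times >= t_detect) & (curve.times <= t_end))[0]
    width = max(min_points, 2)
    if in_cap.size < width:
        return RateEstimate(
            rate=0.0,
            detect_time=t_detect,
            detected=False,
            warning=f"fit window holds {in_cap.size} < {min_points} reads",
        )
    best_r2, best_slope, best_j = -np.inf, 0.0, in_cap[-1]
    for j in range(i_detect + width - 1, in_cap[-1] + 1):
        t = times_h[i_detect : j + 1]
        y = ln_od[i_detect : j + 1]
        slope = _ls_slope(t, y)
        r = np.corrcoef(t, y)[0, 1] if np.std(y) > 0 else 0.0
        r2 = r * r
        if r2 >= best_r2 - 1e-9:  # prefer the longer window on near-ties
            if r2 > best_r2:
                best_r2 = r2
            best_slope, best_j = slope, j
    return RateEstimate(
        rate=float(best_slope),
        detect_time=t_detect,
        window=(t_detect, float(curve.times[best_j])),
        fit_r2=float(best_r2),
        detected=True,
    )


def relative_rate(test: RateEstimate, reference: RateEstimate) -> RelativeRate:
    """mu = test rate / wild-type-allele reference rate.

    The wild-type allele must rescue growth; an undetected or non-growing
    reference invalidates the assay.  An undetected test strain maps to
    mu = 0 (no rescue at all).
    """
    if not reference.detected or reference.rate <= 0:
        raise AssayInvalidError(
            "reference (wild-type allele) strain shows no detectable growth"
        )
    if not test.detected:
        return RelativeRate(mu=0.0)
    return RelativeRate(mu=float(test.rate / reference.rate))


def average_replicates(reps: list[RelativeRate]) -> RelativeRate:
    """Combine independent replicate mu values by their arithmetic mean."""
    if not reps:
        raise InputError("average_replicates: empty replicate list")
    values = [r.mu for r in reps]
    return RelativeRate(mu=float(np.mean(values)), replicate_values=values)


def replicate_concordance(rep1, rep2) -> float | None:
    """Pearson correlation between two replicate mu vectors across strains.

    Returns None (undefined) when fewer than 3 strains are supplied or either
    vector is constant.
    """
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    if x.shape != y.shape:
        raise InputError("replicate vectors must have equal length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
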