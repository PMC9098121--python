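"""Elongation-rate estimation from transcription wavefronts.

Two complementary read-outs, both in kb/min:

* DRB release: a wave of polymerases advances into genes; the wave peak is
  the maximum of a smoothing spline fitted to the meta-profile at each
  timepoint, constrained to advance with time, and the rate is the OLS
  slope of peak position on time.
* FP (flavopiridol) runoff: elongating polymerases clear the 5' end; the
  receding rear edge is read either as the first-derivative slope at the
  inflection of a smoothed profile, or per gene as the position where the
  density rises through half the maximum observed within a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .genome_model import CoverageTrack, GeneModel, GenomicInterval, query_coverage

logger = logging.getLogger(__name__)


@dataclass
class SmoothCurve:
    """Penalised cubic smoothing spline with analytic derivatives."""

    grid: np.ndarray       # evaluation positions (kb)
    values: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    lam: float | None      # penalty used (None = GCV-selected)


@dataclass
class WaveSeries:
    """(time, position) pairs from wavefront calling on one profile/gene."""

    times: np.ndarray          # minutes post release/addition
    positions_kb: np.ndarray   # kb from TSS, non-decreasing
    method: str
    constrained: np.ndarray = field(default=None)  # monotone constraint applied?
    peak_values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.positions_kb = np.asarray(self.positions_kb, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.positions_kb) < -1e-9):
            raise ValueError("positions must be non-decreasing")


@dataclass
class RateFit:
    """OLS fit of wave position (kb) on time (min): rate = slope."""

    rate: float            # kb/min
    intercept: float       # kb
    stderr: float
    n: int
    residuals: np.ndarray


def fit_smooth_curve(
    positions_kb: np.ndarray,
    values: np.ndarray,
    lam: float | None = None,
    grid: np.ndarray | None = None,
) -> SmoothCurve:
    """Fit a penalised cubic smoothing spline and evaluate it with its first
    two derivatives (analytically, from the spline coefficients).

    ``lam`` is the roughness penalty; None selects it by generalised
    cross-validation, which is the default used throughout.
    """
    positions_kb = np.asarray(positions_kb, float)
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    positions_kb, values = positions_kb[ok], values[ok]
    if len(values) < 10:
        raise ValueError(f"need >= 10 finite bins to fit a spline, got {len(values)}")
    spl = make_smoothing_spline(positions_kb, values, lam=lam)
    if grid is None:
        grid = positions_kb
    return SmoothCurve(
        grid=np.asarray(grid, float),
        values=spl(grid),
        d1=spl.derivative(1)(grid),
        d2=spl.derivative(2)(grid),
        lam=lam,
    )


def call_drb_wave_positions(
    curves: dict[float, SmoothCurve],
    promoter_region_kb: float = 2.0,
) -> WaveSeries:
    """Wave peaks as the spline maximum per timepoint, constrained so that
    peaks advance with time.

    At the earliest timepoint (release, t = 0) the peak is anchored at the
    promoter-region maximum; later peaks are the argmax restricted to
    positions at or beyond the previous peak.  If the restriction changes
    the unconstrained argmax, the point is flagged.
    """
    times = sorted(curves)
    positions, flags, peaks = [], [], []
    prev = -np.inf
    for k, t in enumerate(times):
        c = curves[t]
        if k == 0 and t == 0:
            window = c.grid <= promoter_region_kb
        else:
            window = c.grid >= prev
        if not window.any():
            window = c.grid >= c.grid[-1]
        masked = np.where(window, c.values, -np.inf)
        i = int(np.argmax(masked))  # leftmost max on ties
        unconstrained = int(np.argmax(c.values))
        positions.append(c.grid[i])
        peaks.append(c.values[i])
        flags.append(i != unconstrained)
        prev = c.grid[i]
    return WaveSeries(
        times=np.array(times, float),
        positions_kb=np.array(positions),
        method="drb_peak",
        constrained=np.array(flags),
        peak_values=np.array(peaks),
    )


def fit_elongation_rate(series: WaveSeries) -> RateFit:
    """Ordinary least squares of wave position (kb) on time (min)."""
    t, y = series.times, series.positions_kb
    if len(t) < 2:
        raise ValueError("need >= 2 (time, position) points to fit a rate")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate timepoints")
    fit = stats.linregress(t, y)
    resid = y - (fit.intercept + fit.slope * t)
    return RateFit(
        rate=float(fit.slope), intercept=float(fit.intercept),
        stderr=float(fit.stderr), n=len(t), residuals=resid,
    )


def fp_rear_slope(curve: SmoothCurve, min_kb: float = 0.0, max_kb: float | None = None) -> float:
    """First-derivative value where the second derivative first crosses zero
    downstream of the TSS: the slope of the receding wave's rear edge at its
    inflection.  Shallower magnitude across timepoints means faster
    clearance.  Raises if no sign change occurs in the window."""
    g = curve.grid
    mask = g >= min_kb
    if max_kb is not None:
        mask &= g <= max_kb
    idx = np.flatnonzero(mask)
    d2 = curve.d2[idx].copy()
    # numerical-zero guard: a straight segment has |d2| at rounding level
    span = np.ptp(curve.grid) or 1.0
    tol = 1e-6 * np.ptp(curve.values) / span**2
    d2[np.abs(d2) < tol] = 0.0
    sign = np.sign(d2)
    sign_change = np.flatnonzero((sign[:-1] * sign[1:]) < 0)
    if len(sign_change) == 0:
        lo = g[idx[0]] if len(idx) else min_kb
        hi = g[idx[-1]] if len(idx) else max_kb
        raise ValueError(f"no inflection of the smoothed profile in [{lo:g}, {hi:g}] kb")
    j = sign_change[0]
    a, b = idx[j], idx[j + 1]
    # linear interpolation of the zero crossing between grid points
    w = curve.d2[a] / (curve.d2[a] - curve.d2[b])
    return float((1 - w) * curve.d1[a] + w * curve.d1[b])


def fp_half_height_position(
    track: CoverageTrack,
    gene: GeneModel,
    window_kb: float = 150.0,
    extent_kb: float = 200.0,
    quartile_guard: float = 0.25,
) -> float | None:
    """Rear-edge position (kb from TSS) of the receding wave in one gene at
    one timepoint: the first coordinate where density rises through half the
    maximum observed within the first ``window_kb``.

    To skip residual promoter spikes, the crossing is searched after the
    last position where density is below ``quartile_guard`` x max.  Returns
    None (logged) if the density never reaches half the maximum.
    """
    extent = int(min(extent_kb * 1e3, gene.width))
    if gene.strand == "+":
        iv = GenomicInterval(gene.chrom, gene.tss, gene.tss + extent, "+")
    else:
        iv = GenomicInterval(gene.chrom, gene.tss - extent, gene.tss, "-")
    vec = query_coverage(track, iv, gene.strand)
    b_kb = track.bin_size / 1e3
    n_window = int(window_kb / b_kb)
    m = float(np.max(vec[:n_window])) if n_window else float(np.max(vec))
    if m <= 0:
        logger.info("fp_half_height: %s has no signal, excluded", gene.gene_id)
        return None
    half = m / 2.0
    below_quart = np.flatnonzero(vec < quartile_guard * m)
    start = int(below_quart[-1]) if len(below_quart) else 0
    if len(below_quart) == 0:
        return 0.0  # never cleared: wave still at the TSS
    above = np.flatnonzero(vec[start:] >= half)
    if len(above) == 0:
        logger.info("fp_half_height: %s never reaches half max, excluded", gene.gene_id)
        return None
    k = start + int(above[0])
    if k == 0:
        return 0.0
    y0, y1 = vec[k - 1], vec[k]
    frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(((k - 1) + frac + 0.5) * b_kb)


def fp_half_height_series(
    tracks: dict[float, CoverageTrack],
    gene: GeneModel,
    window_kb: float = 150.0,
    extent_kb: float = 200.0,
) -> WaveSeries:
    """Half-height rear-edge positions across timepoints for one gene,
    with the monotone (non-receding backwards) constraint applied."""
    times, positions = [], []
    prev = 0.0
    flags = []
    for t in sorted(tracks):
        pos = fp_half_height_position(tracks[t], gene, window_kb, extent_kb)
        if pos is None:
            continue
        flags.append(pos < prev)
        pos = max(pos, prev)
        times.append(t)
        positions.append(pos)
        prev = pos
    return WaveSeries(
        times=np.array(times, float),
        positions_kb=np.array(positions, float),
        method="fp_half_height",
        constrained=np.array(flags, bool),
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for rates).
    Values are first snapped to 9 decimals so float representation error
    (e.g. a mean that is 2.5499999999999998 instead of 2.55) does not flip
    a tie."""
    q = Decimal(1).scaleb(-ndigits)
    snapped = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


def mean_rate_one_decimal(rates) -> float:
    """Arithmetic mean of per-gene rates, reported to one decimal
    (half-up) — the convention for averaging a handful of single-gene
    elongation rates."""
    return round_half_up(float(np.mean(np.asarray(rates, float))), 1)
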