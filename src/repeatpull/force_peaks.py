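"""Force-peak identification from the force distribution's Gaussian body.

The force sampled along a constant-velocity pull is dominated by a
quasi-Gaussian body (many small contributions) plus a high-force tail
produced by rupture events.  The body is fitted to a normal
distribution; the deviation of the observed histogram from the fit,
normalised by the counting error of each bin, peaks where the tail
begins, and the location of that maximum is taken as the threshold above
which force peaks are unambiguous.  Peaks below it are discarded as
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .errors import FitError, ThresholdError
from .trajio import ForceTrace

__all__ = [
    "ForceDistributionFit", "Peak", "PeakSet",
    "fit_force_distribution", "select_threshold", "detect_peaks",
    "peak_density",
]

#: a normalized-deviation maximum below this is flagged unreliable
#: (indistinguishable from Gaussian sampling fluctuations)
MIN_RELIABLE_DEVIATION = 3.0


@dataclass
class ForceDistributionFit:
    bin_centers: np.ndarray       # pN
    counts: np.ndarray
    mean: float                   # fitted Gaussian body, pN
    sd: float
    amplitude: float
    normalized_deviation: np.ndarray   # (count - fit)/sqrt(max(count, 1))
    bin_width: float


@dataclass
class Peak:
    run_id: object
    time: float          # ps
    extension: float     # Å
    force: float         # pN
    prominence: float    # pN
    frame: int


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_force_distribution(forces, bin_width: float = 5.0,
                           n_body_iterations: int = 2) -> ForceDistributionFit:
    """Histogram the force sample and fit a Gaussian to its body.

    The fit window is the set of bins within ±2 fitted sd of the mode,
    re-selected over ``n_body_iterations`` passes so the high-force tail
    does not drag the fit.  Requires >= 1000 samples.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < 1000:
        raise ValueError(f"need >= 1000 force samples, got {forces.size}")
    if np.ptp(forces) == 0:
        raise FitError("degenerate force sample: all values identical")

    lo = np.floor(forces.min() / bin_width) * bin_width
    hi = np.ceil(forces.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mode = centers[np.argmax(counts)]
    sd = float(np.std(forces))
    mu, amp = mode, float(counts.max())
    for _ in range(n_body_iterations):
        sel = np.abs(centers - mode) <= 2.0 * sd
        if sel.sum() < 4:
            raise FitError("too few bins in the distribution body")
        try:
            popt, _ = curve_fit(_gauss, centers[sel], counts[sel],
                                p0=(amp, mu, sd), maxfev=10000)
        except RuntimeError as exc:
            raise FitError(f"Gaussian body fit failed: {exc}") from exc
        amp, mu, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        if sd <= 0:
            raise FitError("Gaussian body fit collapsed to zero width")

    fit_vals = _gauss(centers, amp, mu, sd)
    normdev = (counts - fit_vals) / np.sqrt(np.maximum(counts, 1))
    return ForceDistributionFit(bin_centers=centers, counts=counts,
                                mean=mu, sd=sd, amplitude=amp,
                                normalized_deviation=normdev,
                                bin_width=bin_width)


def select_threshold(fit: ForceDistributionFit) -> tuple[float, bool]:
    """Threshold = bin of maximal normalized deviation above mean + 1 sd.

    Returns ``(threshold_pN, reliable)``.  Ties break toward the lower
    force.  ``reliable`` is False when the maximal deviation is below
    3 (compatible with pure sampling noise, i.e. no real tail).
    Raises :class:`ThresholdError` when no bins lie above mean + 1 sd.
    """
    above = fit.bin_centers > fit.mean + fit.sd
    if not np.any(above):
        raise ThresholdError("no bins above mean + 1 sd: trace has no "
                             "high-force tail")
    dev = np.where(above, fit.normalized_deviation, -np.inf)
    idx = int(np.argmax(dev))        # argmax returns the first (lowest force)
    reliable = bool(dev[idx] >= MIN_RELIABLE_DEVIATION)
    return float(fit.bin_centers[idx]), reliable


def _hysteresis_maxima(f: np.ndarray, min_prominence: float) -> list[int]:
    """Indices of local maxima under a hysteresis rule: the series must
    rise by ``min_prominence`` from the preceding trough to open a peak
    and drop by the same amount below the running maximum to close it.
    The trailing open peak (a still-rising final segment) is discarded."""
    peaks = []
    cur_min = f[0]
    cur_max, cur_max_idx = -np.inf, -1
    peak_open = False
    for i, v in enumerate(f):
        if not peak_open:
            if v < cur_min:
                cur_min = v
            if v - cur_min >= min_prominence:
                peak_open = True
                cur_max, cur_max_idx = v, i
        else:
            if v > cur_max:
                cur_max, cur_max_idx = v, i
            elif cur_max - v >= min_prominence:
                peaks.append(cur_max_idx)
                peak_open = False
                cur_min = v
    return peaks


def detect_peaks(trace: ForceTrace, threshold: float,
                 min_prominence: float = 30.0,
                 smooth_window: int = 5,
                 run_id=None) -> PeakSet:
    """Hysteresis local maxima of the (smoothed) force series.

    The force must rise by at least ``min_prominence`` pN from the
    preceding trough and fall by the same amount before a new peak can
    open; this prevents noise from splitting one rupture into several
    detections, and a still-rising final segment is never a peak
    (boundary frames cannot be ruptures).  Maxima below ``threshold``
    are discarded — an empty PeakSet is a valid result.
    """
    f = trace.force_magnitude
    if smooth_window and smooth_window > 1:
        # edge-replicating moving average: zero padding would fabricate
        # force drops at the trace boundaries
        f = uniform_filter1d(f, int(smooth_window), mode="nearest")
    idx = [i for i in _hysteresis_maxima(f, min_prominence)
           if f[i] >= threshold and 0 < i < f.size - 1]
    # prominence relative to the deepest flanking troughs
    bounds = [0] + idx + [f.size - 1]
    ext = trace.extension
    peaks = []
    for k, i in enumerate(idx):
        left_min = f[bounds[k]:i].min() if i > bounds[k] else f[i]
        right_min = f[i + 1:bounds[k + 2] + 1].min()
        prom = float(f[i] - max(left_min, right_min))
        peaks.append(Peak(run_id=run_id, time=float(trace.time[i]),
                          extension=float(ext[i]), force=float(f[i]),
                          prominence=prom, frame=int(i)))
    return PeakSet(peaks=peaks, threshold=threshold)


def peak_density(peaks, bandwidths: tuple[float, float] = (20.0, 20.0),
                 grid_size: int = 128):
    """2-D kernel density of peaks on the extension-force plane.

    Every peak is replaced by an isotropic (per-axis) Gaussian of the
    given bandwidths (Å, pN); the summed density is renormalised to
    integrate to 1 on the returned grid, which spans the data ±4
    bandwidths.

    Returns ``(extension_grid, force_grid, density)`` with density shape
    ``(grid_size, grid_size)`` indexed [extension, force].
    """
    pts = np.array([[p.extension, p.force] for p in peaks], dtype=float)
    if pts.size == 0:
        raise ValueError("need at least one peak")
    bw_e, bw_f = bandwidths
    if bw_e <= 0 or bw_f <= 0:
        raise ValueError("bandwidths must be positive")
    eg = np.linspace(pts[:, 0].min() - 4 * bw_e, pts[:, 0].max() + 4 * bw_e,
                     grid_size)
    fg = np.linspace(pts[:, 1].min() - 4 * bw_f, pts[:, 1].max() + 4 * bw_f,
                     grid_size)
    de = (eg[:, None] - pts[None, :, 0]) / bw_e
    df = (fg[:, None] - pts[None, :, 1]) / bw_f
    dens = np.exp(-0.5 * de ** 2) @ np.exp(-0.5 * df ** 2).T / len(pts)
    norm = np.trapezoid(np.trapezoid(dens, fg, axis=1), eg)
    return eg, fg, dens / norm
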