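"""Worm-like chain fits and contour-length periodicity analysis.

The force-extension segments preceding each rupture peak are fitted to
the Marko–Siggia interpolation of the worm-like chain (WLC) at fixed
persistence length, yielding one contour length Lc per peak.  Pairwise
differences of the fitted contour lengths within a run report how much
chain each rupture released; repeat proteins produce combs of
differences at multiples of the half-repeat (L) or whole-repeat (2L)
unfolded length, and :func:`estimate_periodicity` scores candidate
periods against that comb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import kbt
from .errors import FitError, GeometryError

__all__ = [
    "WLCFit",
    "ContourHistogram",
    "wlc_force",
    "wlc_stretch_work",
    "fit_segment_contour_length",
    "fit_trace_peaks",
    "contour_length_differences",
    "estimate_periodicity",
]


@dataclass
class WLCFit:
    """One-parameter WLC fit of a pre-peak force-extension segment."""

    peak_id: int
    contour_length: float        # Lc, Å
    persistence_length: float    # p, Å (held fixed)
    residual_rms: float          # pN
    window: tuple[int, int]      # frame index range [start, stop)
    run_id: object = None


@dataclass
class ContourHistogram:
    """All-pairs contour-length differences pooled across runs."""

    differences: np.ndarray      # ΔLc values, Å (positive)
    bin_centers: np.ndarray
    counts: np.ndarray
    period: float | None = None  # filled by estimate_periodicity
    period_score: float | None = None
    bin_width: float = 5.0


def wlc_force(extension, contour_length: float, persistence_length: float,
              temperature: float = 300.0):
    """Marko–Siggia WLC restoring force in pN.

    F(x) = (kBT/p) · [ 1/(4(1−x/Lc)²) − 1/4 + x/Lc ]

    ``extension`` may be a scalar or array; every value must satisfy
    0 ≤ x < Lc (the force diverges at the contour length).
    """
    if contour_length <= 0 or persistence_length <= 0:
        raise ValueError("contour and persistence lengths must be positive")
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= contour_length):
        raise ValueError("extension must lie in [0, Lc)")
    s = x / contour_length
    f = (kbt(temperature) / persistence_length) * (
        0.25 / (1.0 - s) ** 2 - 0.25 + s)
    return float(f) if np.isscalar(extension) else f


def wlc_stretch_work(extension: float, contour_length: float,
                     persistence_length: float,
                     temperature: float = 300.0) -> float:
    """Closed-form ∫₀ˣ F dx' of the Marko–Siggia force, in pN·Å.

    Antiderivative (with s = x/Lc):
    W(x) = (kBT·Lc/p) · [ 1/(4(1−s)) − s/4 + s²/2 − 1/4 ].
    """
    if not 0 <= extension < contour_length:
        raise ValueError("extension must lie in [0, Lc)")
    s = extension / contour_length
    pref = kbt(temperature) * contour_length / persistence_length
    return pref * (0.25 / (1.0 - s) - 0.25 * s + 0.5 * s * s - 0.25)


def fit_segment_contour_length(extension, force,
                               persistence_length: float = 3.8,
                               temperature: float = 300.0,
                               peak_id: int = -1,
                               run_id=None,
                               window: tuple[int, int] = (0, 0)) -> WLCFit:
    """Least-squares fit of the contour length Lc to one segment.

    The persistence length is held fixed (default 3.8 Å); Lc is the only
    free parameter, bracketed in (1.001·max(x), 5·max(x)).

    Parameters
    ----------
    extension, force : arrays of equal length (Å, pN), extensions strictly
        increasing, at least 5 records.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.size < 5:
        raise GeometryError(
            f"segment for peak {peak_id} has {x.size} records; need >= 5")
    if x.shape != f.shape:
        raise GeometryError("extension and force must have equal length")
    if np.any(np.diff(x) <= 0):
        raise GeometryError("extensions must be strictly increasing")

    xmax = x[-1]
    lo, hi = xmax * 1.001, xmax * 5.0

    def sse(lc: float) -> float:
        model = wlc_force(x, lc, persistence_length, temperature)
        r = model - f
        return float(r @ r)

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6 * xmax})
    if not res.success:
        raise FitError(f"WLC fit did not converge for peak {peak_id}")
    lc = float(res.x)
    rms = float(np.sqrt(res.fun / x.size))
    return WLCFit(peak_id=peak_id, contour_length=lc,
                  persistence_length=persistence_length,
                  residual_rms=rms, window=window, run_id=run_id)


def contour_length_differences(fits_by_run: dict,
                               bin_width: float = 5.0) -> ContourHistogram:
    """Pool within-run all-pairs contour-length differences.

    ``fits_by_run`` maps a run id to its WLCFit list in peak (time)
    order.  Every ordered pair (earlier, later) within a run contributes
    ΔLc = Lc_later − Lc_earlier; cross-run pairs never appear.
    Non-positive differences (possible under fit noise) are dropped.
    """
    diffs = []
    for fits in fits_by_run.values():
        lcs = [f.contour_length if isinstance(f, WLCFit) else float(f)
               for f in fits]
        for i in range(len(lcs)):
            for j in range(i + 1, len(lcs)):
                d = lcs[j] - lcs[i]
                if d > 0:
                    diffs.append(d)
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        return ContourHistogram(differences=diffs,
                                bin_centers=np.array([]),
                                counts=np.array([], dtype=int),
                                bin_width=bin_width)
    nbins = max(1, int(np.ceil(diffs.max() / bin_width)))
    edges = np.arange(0.0, (nbins + 1) * bin_width, bin_width)
    counts, edges = np.histogram(diffs, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ContourHistogram(differences=diffs, bin_centers=centers,
                            counts=counts, bin_width=bin_width)


def fit_trace_peaks(trace, peaks, persistence_length: float = 3.8,
                    temperature: float = 300.0,
                    min_points: int = 5) -> list[WLCFit]:
    """WLC-fit the force-extension segment preceding each detected peak.

    The fit window runs from the force minimum after the previous peak
    (or the trace start) to the current peak frame.  Frames are filtered
    to strictly increasing extension before fitting; peaks whose window
    retains fewer than ``min_points`` frames are skipped.
    """
    f = trace.force_magnitude
    ext = trace.extension
    fits: list[WLCFit] = []
    prev_frame = 0
    for pid, peak in enumerate(peaks):
        stop = peak.frame
        if stop <= prev_frame + 1:
            prev_frame = stop
            continue
        start = prev_frame + int(np.argmin(f[prev_frame:stop]))
        x = ext[start:stop + 1]
        y = f[start:stop + 1]
        keep = np.concatenate([[True], np.diff(np.maximum.accumulate(x)) > 0])
        x, y = x[keep], y[keep]
        if x.size >= min_points:
            try:
                fits.append(fit_segment_contour_length(
                    x, y, persistence_length, temperature, peak_id=pid,
                    run_id=peak.run_id, window=(start, stop)))
            except (FitError, GeometryError):
                pass
        prev_frame = stop
    return fits


def estimate_periodicity(hist: ContourHistogram,
                         candidates=None,
                         tolerance: float = 10.0) -> tuple[float, float]:
    """Best period of the ΔLc comb and its score.

    For each candidate period T the score is the fraction of ΔLc values
    lying within ±``tolerance`` of a positive multiple of T.  The
    maximal score defines a plateau of near-equivalent candidates; the
    winner is the plateau member with the smallest mean comb residual
    |ΔLc − m·T|, and exact residual ties break toward the *largest*
    period, so a pure 2L comb (whose members are also multiples of L)
    reports 2L rather than L.
    """
    if candidates is None:
        candidates = np.arange(40.0, 130.0 + 1e-9, 0.2)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("empty candidate period range")
    d = hist.differences
    if d.size < 10:
        raise ValueError(f"need >= 10 pairwise differences, have {d.size}")

    scores = np.empty(candidates.size)
    residuals = np.empty(candidates.size)
    for k, period in enumerate(candidates):
        m = np.maximum(1, np.round(d / period))
        r = np.abs(d - m * period)
        scores[k] = np.mean(r <= tolerance)
        residuals[k] = r[r <= tolerance].mean() if scores[k] > 0 else np.inf
    best = scores.max()
    plateau = np.nonzero(scores >= best - 1e-12)[0]
    res_min = residuals[plateau].min()
    tied = plateau[residuals[plateau] <= res_min + 1e-9]
    idx = int(tied[-1])
    hist.period = float(candidates[idx])
    hist.period_score = float(best)
    return hist.period, hist.period_score
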