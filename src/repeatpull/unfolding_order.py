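"""Per-repeat unfolding midpoints, order statistics and exact Fisher test.

A repeat's unfolding midpoint is the first time its Cα/Cβ RMSD from the
native conformation reaches a threshold (10 Å by default; the ranking is
robust to thresholds in the 7–15 Å range because the RMSD rises abruptly
when a repeat lets go).  Midpoints define one order rank per repeat per
run; ranks are tabulated into contingency tables (repeat × position, or
condition × position of a fixed repeat) that an exact r×c Fisher test
compares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import DataError, GeometryError
from .trajio import PROTEIN, PullingTrajectory, RepeatMap

__all__ = [
    "UnfoldingEvent", "ContingencyTable",
    "repeat_rmsd", "unfolding_midpoints", "order_contingency",
    "fisher_exact_rxc", "kde_1d",
]


@dataclass
class UnfoldingEvent:
    run_id: object
    repeat_id: int
    time: float          # ps, interpolated first crossing
    rank: int            # 1 = first repeat to unfold in the run


@dataclass
class ContingencyTable:
    counts: np.ndarray           # (rows, positions), int
    row_labels: list
    col_labels: list


# ---------------------------------------------------------------------------
# RMSD and midpoints

def _batched_kabsch_rmsd(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superposition RMSD per frame.

    mobile: (n_frames, m, 3); ref: (m, 3).  Uses the SVD trace formula
    with the determinant sign correction, so rigid motions give RMSD 0.
    """
    m = ref.shape[0]
    mc = mobile - mobile.mean(axis=1, keepdims=True)
    rc = ref - ref.mean(axis=0)
    a = np.einsum("fij,fij->f", mc, mc)
    b = float(np.einsum("ij,ij->", rc, rc))
    h = np.einsum("fmi,mj->fij", mc, rc)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u) * np.linalg.det(vt)
    s_sum = s[:, 0] + s[:, 1] + np.where(det >= 0, s[:, 2], -s[:, 2])
    msd = np.maximum(a + b - 2.0 * s_sum, 0.0) / m
    return np.sqrt(msd)


def repeat_rmsd(traj: PullingTrajectory, repeat_map: RepeatMap,
                native_coords: np.ndarray,
                atom_names=("CA", "CB")) -> dict[int, np.ndarray]:
    """Per-repeat Cα/Cβ RMSD to the native conformation, per frame.

    Each repeat's atoms are optimally superposed (rotation +
    translation) onto the native structure before the RMSD is taken, so
    rigid displacement of an intact repeat does not register.
    """
    native = np.asarray(native_coords, dtype=float)
    if native.shape != (traj.topology.n_atoms, 3):
        raise GeometryError("native coordinates do not match topology")
    out = {}
    for rid, lo, hi in repeat_map.repeats:
        idx = traj.topology.atom_indices(atom_names=atom_names,
                                         repeat_id=rid, chain=PROTEIN)
        if idx.size < 3:
            raise GeometryError(
                f"repeat {rid} has {idx.size} superposition atoms; need >= 3")
        out[rid] = _batched_kabsch_rmsd(traj.coords[:, idx, :], native[idx])
    return out


def unfolding_midpoints(rmsd_series: dict[int, np.ndarray], times,
                        threshold: float = 10.0,
                        run_id=None) -> tuple[list[UnfoldingEvent], list[int]]:
    """First threshold crossings of the per-repeat RMSD series.

    The midpoint is linearly interpolated between the bracketing frames.
    Repeats that never reach the threshold produce no event and are
    returned in the second element.  Ranks are assigned by midpoint time
    (ties broken by repeat id).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise DataError("empty time base")
    crossings = []
    non_unfolded = []
    for rid, series in rmsd_series.items():
        series = np.asarray(series, dtype=float)
        if series.size != times.size:
            raise DataError(f"repeat {rid} series length mismatch")
        above = series >= threshold
        if not above.any():
            non_unfolded.append(rid)
            continue
        i = int(np.argmax(above))
        if i == 0:
            t_cross = float(times[0])
        else:
            frac = (threshold - series[i - 1]) / (series[i] - series[i - 1])
            t_cross = float(times[i - 1] + frac * (times[i] - times[i - 1]))
        crossings.append((t_cross, rid))
    crossings.sort()
    events = [UnfoldingEvent(run_id=run_id, repeat_id=rid, time=t,
                             rank=rank + 1)
              for rank, (t, rid) in enumerate(crossings)]
    return events, sorted(non_unfolded)


# ---------------------------------------------------------------------------
# contingency tables

def order_contingency(runs, by: str = "repeat", conditions=None,
                      repeat_id: int | None = None,
                      n_positions: int | None = None) -> ContingencyTable:
    """Tabulate unfolding-order ranks across runs.

    ``runs`` is a list of per-run event lists (:class:`UnfoldingEvent`).

    by="repeat": rows are repeats, columns order positions; entry (r, k)
    counts the runs in which repeat r unfolds k-th.

    by="condition": rows are the distinct values of ``conditions`` (one
    per run) and columns the order position of the single ``repeat_id``.
    """
    rank_maps = []
    for events in runs:
        ranks = {}
        for ev in events:
            if ev.repeat_id in ranks:
                raise DataError(f"duplicate event for repeat {ev.repeat_id} "
                                f"in run {ev.run_id}")
            ranks[ev.repeat_id] = ev.rank
        if sorted(ranks.values()) != list(range(1, len(ranks) + 1)):
            raise DataError(f"ranks are not a permutation in run "
                            f"{events[0].run_id if events else '?'}")
        rank_maps.append(ranks)

    if n_positions is None:
        n_positions = max((max(r.values()) for r in rank_maps if r),
                          default=0)

    if by == "repeat":
        repeats = sorted({rid for r in rank_maps for rid in r})
        counts = np.zeros((len(repeats), n_positions), dtype=int)
        for ranks in rank_maps:
            for rid, pos in ranks.items():
                counts[repeats.index(rid), pos - 1] += 1
        return ContingencyTable(counts=counts,
                                row_labels=[f"r{r}" for r in repeats],
                                col_labels=list(range(1, n_positions + 1)))

    if by == "condition":
        if conditions is None or repeat_id is None:
            raise DataError("condition mode needs conditions= and repeat_id=")
        if len(conditions) != len(rank_maps):
            raise DataError("one condition per run required")
        labels = sorted(set(conditions), key=str)
        counts = np.zeros((len(labels), n_positions), dtype=int)
        for cond, ranks in zip(conditions, rank_maps):
            if repeat_id in ranks:
                counts[labels.index(cond), ranks[repeat_id] - 1] += 1
        return ContingencyTable(counts=counts, row_labels=labels,
                                col_labels=list(range(1, n_positions + 1)))

    raise ValueError(f"unknown mode {by!r}")


# ---------------------------------------------------------------------------
# exact Fisher r x c

def _log_table_prob(cells, lgf, log_const):
    return log_const - sum(lgf[c] for c in cells)


def _enumerate_exact(rows, cols, lgf, log_const, log_p_obs):
    """DFS over all tables with the given margins; returns the summed
    probability of tables no more probable than the observed one."""
    r, c = len(rows), len(cols)
    p_le = 0.0
    cells = [0] * (r * c)
    col_rem = list(cols)

    def rec(i, row_rem, acc_lg):
        nonlocal p_le
        ri, ci = divmod(i, c)
        if ci == c - 1:
            v = row_rem
            if v < 0 or v > col_rem[ci]:
                return
            col_rem[ci] -= v
            new_acc = acc_lg + lgf[v]
            if ri == r - 1:
                if all(x == 0 for x in col_rem):
                    logp = log_const - new_acc
                    if logp <= log_p_obs + 1e-7:
                        p_le += np.exp(logp)
            else:
                rec(i + 1, rows[ri + 1], new_acc)
            col_rem[ci] += v
            return
        remaining_other_cols = sum(col_rem[ci + 1:])
        lo = max(0, row_rem - remaining_other_cols)
        hi = min(row_rem, col_rem[ci])
        for v in range(lo, hi + 1):
            col_rem[ci] -= v
            rec(i + 1, row_rem - v, acc_lg + lgf[v])
            col_rem[ci] += v

    rec(0, rows[0], 0.0)
    return p_le


def _estimated_leaves(rows, cols) -> float:
    est = 1.0
    for ri in rows[:-1]:
        for cj in cols[:-1]:
            est *= min(ri, cj) + 1
    return est


def fisher_exact_rxc(table, method: str = "auto", seed: int = 0,
                     n_mc: int = 100000, max_tables: float = 5e5) -> float:
    """Exact conditional Fisher p-value for an r×c contingency table.

    p is the total multivariate-hypergeometric probability (margins
    fixed) of all tables no more probable than the observed one.  When
    enumeration would be too large (estimated leaf count > ``max_tables``
    or total > 200) a seeded Monte-Carlo estimate over tables sampled by
    random permutation of case labels is returned, with the standard
    (1 + hits)/(B + 1) correction.
    """
    counts = np.asarray(getattr(table, "counts", table), dtype=int)
    if np.any(counts < 0):
        raise DataError("contingency counts must be non-negative")
    # drop all-zero rows/columns: they do not affect the conditional test
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0 or 1 in counts.shape:
        return 1.0
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())

    lgf = gammaln(np.arange(n + 2) + 1.0)
    log_const = float(lgf[list(rows)].sum() + lgf[list(cols)].sum() - lgf[n])
    log_p_obs = log_const - float(lgf[counts.ravel()].sum())

    if method == "auto":
        method = ("exact" if n <= 200 and
                  _estimated_leaves(rows, cols) <= max_tables else "mc")
    if method == "exact":
        p = _enumerate_exact(list(rows), list(cols), lgf, log_const,
                             log_p_obs)
        return float(min(p, 1.0))
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(rows)), rows)
    col_edges = np.concatenate([[0], np.cumsum(cols)])
    perm = np.tile(labels, (n_mc, 1))
    perm = rng.permuted(perm, axis=1)
    log_p_samples = np.full(n_mc, log_const)
    for j in range(len(cols)):
        block = perm[:, col_edges[j]:col_edges[j + 1]]
        for i in range(len(rows)):
            cell = (block == i).sum(axis=1)
            log_p_samples -= lgf[cell]
    hits = int(np.sum(log_p_samples <= log_p_obs + 1e-7))
    return (1.0 + hits) / (n_mc + 1.0)


# ---------------------------------------------------------------------------
# kernel density estimation

def kde_1d(values, bandwidth: float, grid=None, n_grid: int = 1024):
    """Fixed-bandwidth Gaussian kernel density estimate.

    Each data point is replaced by a Gaussian of width ``bandwidth``;
    the summed density is renormalised to integrate to exactly 1 on the
    returned grid, which spans the data ±4 bandwidths by default.

    Returns ``(grid, density)``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DataError("need at least one value")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(v.min() - 4 * bandwidth, v.max() + 4 * bandwidth,
                           n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    dens /= np.trapezoid(dens, grid)
    return grid, dens
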