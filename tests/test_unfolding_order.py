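import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import repeatpull as rp
from repeatpull.errors import DataError, GeometryError
from repeatpull.unfolding_order import (UnfoldingEvent, fisher_exact_rxc,
                                        kde_1d, order_contingency,
                                        repeat_rmsd, unfolding_midpoints)


# ---------------------------------------------------------------------------
# RMSD

def test_native_frame_has_zero_rmsd(template7_free):
    tmpl = template7_free
    traj = rp.PullingTrajectory(topology=tmpl.topology, times=[0.0],
                                coords=tmpl.coords[None])
    rmsd = repeat_rmsd(traj, tmpl.repeat_map, tmpl.coords)
    for series in rmsd.values():
        assert series[0] == pytest.approx(0.0, abs=1e-6)


def test_rigid_motion_has_zero_rmsd(template7_free):
    tmpl = template7_free
    rot = Rotation.from_euler("xyz", [90, 30, 10], degrees=True).as_matrix()
    moved = tmpl.coords @ rot.T + np.array([10.0, -5.0, 3.0])
    traj = rp.PullingTrajectory(topology=tmpl.topology, times=[0.0],
                                coords=moved[None])
    rmsd = repeat_rmsd(traj, tmpl.repeat_map, tmpl.coords)
    for series in rmsd.values():
        assert series[0] == pytest.approx(0.0, abs=1e-6)


def test_too_few_atoms_is_geometry_error(template7_free):
    tmpl = template7_free
    tiny_map = rp.RepeatMap(repeats=[(1, 1, 84)])
    traj = rp.PullingTrajectory(topology=tmpl.topology, times=[0.0],
                                coords=tmpl.coords[None])
    bad = rp.RepeatMap(repeats=[(99, 100, 101)])
    with pytest.raises(GeometryError):
        repeat_rmsd(traj, bad, tmpl.coords)
    # sanity: the full map works
    repeat_rmsd(traj, tiny_map, tmpl.coords)


# ---------------------------------------------------------------------------
# midpoints

def test_midpoint_interpolation_arithmetic():
    events, flagged = unfolding_midpoints(
        {1: np.array([2.0, 4.0, 12.0])}, [0.0, 4.0, 8.0])
    assert not flagged
    assert events[0].time == pytest.approx(7.0)


def test_non_crossing_repeat_flagged():
    events, flagged = unfolding_midpoints(
        {1: np.array([2.0, 4.0, 12.0]), 2: np.array([1.0, 2.0, 3.0])},
        [0.0, 4.0, 8.0])
    assert flagged == [2]
    assert [e.repeat_id for e in events] == [1]


def test_ranks_follow_crossing_times():
    series = {1: np.array([0.0, 12.0, 20.0]),
              2: np.array([0.0, 2.0, 15.0]),
              3: np.array([0.0, 1.0, 30.0])}
    events, _ = unfolding_midpoints(series, [0.0, 1.0, 2.0])
    ranks = {e.repeat_id: e.rank for e in events}
    assert ranks == {1: 1, 2: 3, 3: 2}


# ---------------------------------------------------------------------------
# contingency tables

def _run(ranks, run_id=0):
    return [UnfoldingEvent(run_id=run_id, repeat_id=r, time=float(k),
                           rank=k) for k, r in enumerate(ranks, start=1)]


def test_contingency_classic_marginal_row():
    runs = [_run([7, 6, 5, 4, 3, 2, 1], i) for i in range(28)]
    table = order_contingency(runs, by="repeat")
    assert table.row_labels[-1] == "r7"
    assert list(table.counts[-1]) == [28, 0, 0, 0, 0, 0, 0]
    assert table.counts.sum(axis=1).tolist() == [28] * 7


def test_single_run_rows_sum_to_one():
    table = order_contingency([_run([2, 1, 3])], by="repeat")
    assert table.counts.sum(axis=1).tolist() == [1, 1, 1]


def test_duplicate_rank_rejected():
    bad = _run([1, 2]) + [UnfoldingEvent(run_id=0, repeat_id=1, time=9.0,
                                         rank=2)]
    with pytest.raises(DataError):
        order_contingency([bad], by="repeat")


def test_condition_mode_positions_of_one_repeat():
    runs = [_run([7, 6, 1]), _run([1, 6, 7]), _run([7, 1, 6])]
    table = order_contingency(runs, by="condition",
                              conditions=["a", "a", "b"], repeat_id=1,
                              n_positions=3)
    assert table.counts.tolist() == [[1, 0, 1], [0, 1, 0]]


# ---------------------------------------------------------------------------
# exact Fisher r x c

def brute_force_fisher(counts):
    """Independent oracle: enumerate every table with the observed
    margins via products over free cells and sum exact Fraction
    probabilities of tables no more probable than the observed one."""
    counts = np.asarray(counts, dtype=int)
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    n = counts.sum()
    r, c = counts.shape

    def prob(cells):
        num = Fraction(1)
        for v in rows:
            num *= math.factorial(int(v))
        for v in cols:
            num *= math.factorial(int(v))
        den = Fraction(math.factorial(int(n)))
        for v in cells:
            den *= math.factorial(int(v))
        return num / den

    p_obs = prob(counts.ravel())
    total = Fraction(0)
    free_ranges = [range(min(rows[i], cols[j]) + 1)
                   for i in range(r - 1) for j in range(c - 1)]
    for combo in itertools.product(*free_ranges):
        table = np.zeros((r, c), dtype=int)
        for k, (i, j) in enumerate(
                (i, j) for i in range(r - 1) for j in range(c - 1)):
            table[i, j] = combo[k]
        table[:r - 1, c - 1] = rows[:r - 1] - table[:r - 1, :c - 1].sum(axis=1)
        table[r - 1, :] = cols - table[:r - 1, :].sum(axis=0)
        if (table < 0).any():
            continue
        p = prob(table.ravel())
        if p <= p_obs:
            total += p
    return float(total)


def test_two_by_two_closed_form():
    p = fisher_exact_rxc(np.array([[5, 0], [0, 5]]))
    assert p == pytest.approx(2 / 252, rel=1e-9)


def test_zero_column_is_dropped():
    t1 = np.array([[3, 0, 4], [2, 0, 6]])
    t2 = np.array([[3, 4], [2, 6]])
    assert fisher_exact_rxc(t1) == pytest.approx(fisher_exact_rxc(t2),
                                                 rel=1e-12)


@pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 3)])
def test_exact_matches_brute_force_enumeration(shape):
    rng = np.random.default_rng(17)
    for _ in range(40):
        total = int(rng.integers(4, 21))
        probs = rng.dirichlet(np.ones(shape[0] * shape[1]))
        counts = rng.multinomial(total, probs).reshape(shape)
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            continue
        p_pkg = fisher_exact_rxc(counts, method="exact")
        p_ref = brute_force_fisher(counts)
        assert p_pkg == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


def test_monte_carlo_agrees_with_exact():
    counts = np.array([[8, 2, 4], [3, 7, 5]])
    p_exact = fisher_exact_rxc(counts, method="exact")
    p_mc = fisher_exact_rxc(counts, method="mc", seed=0, n_mc=40000)
    assert abs(p_mc - p_exact) < 0.02


def test_negative_counts_rejected():
    with pytest.raises(DataError):
        fisher_exact_rxc(np.array([[1, -1], [2, 3]]))


# ---------------------------------------------------------------------------
# kernel density estimation

def test_kde_single_value():
    grid, dens = kde_1d([3.5], bandwidth=0.5)
    assert grid[np.argmax(dens)] == pytest.approx(3.5, abs=0.01)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


def test_kde_two_far_values_equal_modes():
    grid, dens = kde_1d([0.0, 100.0], bandwidth=1.0)
    lo = dens[grid < 50].max()
    hi = dens[grid >= 50].max()
    assert lo == pytest.approx(hi, rel=1e-6)


def test_kde_matches_true_density():
    rng = np.random.default_rng(1)
    sample = rng.normal(0, 1, 10000)
    grid, dens = kde_1d(sample, bandwidth=0.2)
    true = np.exp(-0.5 * grid ** 2) / np.sqrt(2 * np.pi)
    assert np.max(np.abs(dens - true)) < 0.05


def test_kde_rejects_bad_inputs():
    with pytest.raises(ValueError):
        kde_1d([1.0], bandwidth=0.0)
    with pytest.raises(DataError):
        kde_1d([], bandwidth=1.0)
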