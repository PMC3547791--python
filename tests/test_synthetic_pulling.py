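import numpy as np
import pytest

import repeatpull as rp
from repeatpull import contact_analysis as ca
from repeatpull import unfolding_order as uo
from repeatpull.errors import ConfigError
from repeatpull.wlc_fit import wlc_force


def test_no_event_limit_is_pure_wlc_loading():
    """With k0 = 0 and no noise the trace is the WLC loading curve of the
    initially unfolded linker and the stored force re-derives from the
    stored extension through the spring law."""
    params = rp.SimParams(k0=0.0, noise_sigma=0.0, t_max=2000.0, speed=0.01)
    trace, truth = rp.simulate_pull(params, 0)
    assert truth.events == []
    x = trace.extension
    X = params.speed * trace.time
    recomputed = params.spring_k * (X - x)
    assert np.allclose(recomputed, trace.force_magnitude, atol=1e-6)
    # and the force equals the Marko-Siggia force of the linker contour
    wlc = wlc_force(x[1:], params.linker_contour, params.persistence)
    assert np.allclose(wlc, trace.force_magnitude[1:], atol=1e-5)


def test_same_seed_bit_identical_different_seed_differs():
    p = rp.SimParams(speed=0.05)
    t1, g1 = rp.simulate_pull(p, 7)
    t2, g2 = rp.simulate_pull(p, 7)
    t3, g3 = rp.simulate_pull(p, 8)
    assert np.array_equal(t1.force, t2.force)
    assert np.array_equal(t1.anchors, t2.anchors)
    assert [e.time for e in g1.events] == [e.time for e in g2.events]
    assert [e.time for e in g1.events] != [e.time for e in g3.events]


def test_force_independent_rupture_is_exponential():
    """With Δx‡ = 0 the rupture rate is constant, so the first rupture
    time is Exp(k0): the sample mean over 2000 runs must sit within 3
    standard errors of 1/k0."""
    k0 = 0.1
    times = []
    for s in range(2000):
        params = rp.SimParams(n_repeats=1, k0=k0, bell_dx=0.0, q_whole=0.0,
                              noise_sigma=0.0, t_max=150.0, speed=0.05)
        _, truth = rp.simulate_pull(params, s)
        assert truth.events, "censoring should be negligible at t_max=150"
        times.append(truth.events[0].time)
    times = np.asarray(times)
    se = times.std(ddof=1) / np.sqrt(times.size)
    assert abs(times.mean() - 1.0 / k0) < 3.0 * se


def test_uniform_stabilization_raises_rupture_forces():
    """Uniform ΔΔG = 4 kBT on repeats 1..6 versus none: repeats 1-5 must
    rupture at strictly higher mean force (the bound force-peak shift)."""
    n = 40
    ddg_on = (4.0,) * 6 + (0.0,)
    forces = {True: {r: [] for r in range(1, 6)},
              False: {r: [] for r in range(1, 6)}}
    for s in range(n):
        for stabilized in (False, True):
            params = rp.SimParams(
                speed=0.05, ligand=stabilized,
                ddg_per_repeat=ddg_on if stabilized else (0.0,) * 7,
                q_whole=0.9)
            _, truth = rp.simulate_pull(params, 1000 + s)
            for r in range(1, 6):
                if r in truth.repeat_rupture_force:
                    forces[stabilized][r].append(
                        truth.repeat_rupture_force[r])
    for r in range(1, 6):
        assert np.mean(forces[True][r]) > np.mean(forces[False][r])


def test_contour_accounting():
    """Released contour totals n_halves x L and the final extension obeys
    the Marko-Siggia force balance at the final contour."""
    params = rp.SimParams(speed=0.05)
    trace, truth = rp.simulate_pull(params, 5)
    n_halves = len(truth.events)
    assert truth.events[-1].contour_released == pytest.approx(
        n_halves * params.half_contour)
    lc_total = params.linker_contour + n_halves * params.half_contour
    x_final = trace.extension[-1]
    f_balance = params.spring_k * (params.speed * trace.time[-1] - x_final)
    f_wlc = wlc_force(x_final, lc_total, params.persistence)
    assert f_wlc == pytest.approx(f_balance, abs=1e-4)


def test_restricted_order_under_strong_stabilization():
    """With the bound stabilisation profile the first two repeats to
    rupture are the C-terminal pair (7 then 6) in >= 95% of runs."""
    ok = 0
    n = 40
    for s in range(n):
        params = rp.SimParams(speed=0.05, ligand=True, ddg=4.0, q_whole=0.9)
        _, truth = rp.simulate_pull(params, 300 + s)
        seen = []
        for ev in truth.events:
            if ev.repeat_id not in seen:
                seen.append(ev.repeat_id)
        ok += seen[:2] == [7, 6]
    assert ok / n >= 0.95


# ---------------------------------------------------------------------------
# native template

def test_template_has_contiguous_repeats_and_local_contacts(template7_free):
    tmpl = template7_free
    assert [r[0] for r in tmpl.repeat_map.repeats] == list(range(1, 8))
    for (_, a0, a1), (_, b0, _) in zip(tmpl.repeat_map.repeats,
                                       tmpl.repeat_map.repeats[1:]):
        assert b0 == a1 + 1
    contacts = ca.native_contacts(tmpl.coords, tmpl.topology,
                                  tmpl.repeat_map)
    rmap = tmpl.repeat_map
    for c in contacts:
        ri, rj = rmap.repeat_of_residue(c.i), rmap.repeat_of_residue(c.j)
        assert abs(ri - rj) <= 1, "contacts only within/between adjacent"
    inter = [c for c in contacts
             if rmap.repeat_of_residue(c.i) != rmap.repeat_of_residue(c.j)]
    assert inter, "adjacent repeats must share contacts"


def test_ligand_beads_touch_only_bound_repeats(template7):
    tmpl = template7
    topo = tmpl.topology
    lig_idx = topo.atom_indices(chain="ligand")
    lig = tmpl.coords[lig_idx]
    for rep in range(1, 8):
        idx = topo.atom_indices(repeat_id=rep, chain="protein")
        d = np.linalg.norm(tmpl.coords[idx][:, None, :] - lig[None, :, :],
                           axis=-1).min()
        if rep <= 6:
            assert d < 5.0
        else:
            assert d >= 5.0


def test_template_is_deterministic():
    a = rp.make_native_template(3, 12, seed=5)
    b = rp.make_native_template(3, 12, seed=5)
    assert np.array_equal(a.coords, b.coords)


def test_template_rejects_bad_sizes():
    with pytest.raises(ConfigError):
        rp.make_native_template(0)
    with pytest.raises(ConfigError):
        rp.make_native_template(3, residues_per_repeat=7)


# ---------------------------------------------------------------------------
# synthesized trajectories

def test_rmsd_crosses_threshold_inside_unfolding_window(template7, bound_run):
    _, truth, traj = bound_run
    rmsd = uo.repeat_rmsd(traj, template7.repeat_map, template7.coords)
    for rid, series in rmsd.items():
        assert series.max() > 20.0
        mid = truth.repeat_midpoints[rid]
        window = (traj.times > mid - 800) & (traj.times < mid + 800)
        assert series[window].max() > 10.0
        assert series[~window & (traj.times < mid - 800)].max() < 10.0


def test_zero_jitter_frames_native_before_first_rupture(template7_free):
    params = rp.SimParams(speed=0.05)
    _, truth = rp.simulate_pull(params, 4)
    traj = rp.synthesize_trajectory(truth, template7_free, 1,
                                    frame_interval=20.0, window=200.0,
                                    jitter=0.0)
    first = min(truth.repeat_midpoints.values())
    before = traj.times < first - 100.0
    assert before.any()
    for fi in np.nonzero(before)[0]:
        assert np.array_equal(traj.coords[fi], template7_free.coords)


@pytest.mark.parametrize("seed", range(5))
def test_order_recovery_from_synthesized_trajectories(seed, template7_free):
    params = rp.SimParams(speed=0.01)
    _, truth = rp.simulate_pull(params, 40 + seed)
    traj = rp.synthesize_trajectory(truth, template7_free, seed)
    rmsd = uo.repeat_rmsd(traj, template7_free.repeat_map,
                          template7_free.coords)
    events, flagged = uo.unfolding_midpoints(rmsd, traj.times)
    assert not flagged
    assert {e.repeat_id: e.rank for e in events} == truth.repeat_order
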