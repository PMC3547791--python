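import numpy as np
import pytest

import repeatpull as rp
from repeatpull import contact_analysis as ca
from repeatpull.errors import ConfigError
from repeatpull.trajio import Atom, Residue, Topology


def chain_topology(n_res, with_ligand=False):
    residues = [Residue(index=i + 1, name="ALA", repeat_id=1)
                for i in range(n_res)]
    atoms = [Atom(residue_index=i, name="CA") for i in range(n_res)]
    if with_ligand:
        residues.append(Residue(index=1, name="LIG", repeat_id=None,
                                chain="ligand"))
        atoms.append(Atom(residue_index=n_res, name="C1"))
    return Topology(residues=residues, atoms=atoms)


# ---------------------------------------------------------------------------
# native contacts

def test_straight_chain_has_no_contacts():
    topo = chain_topology(20)
    coords = np.zeros((20, 3))
    coords[:, 2] = np.arange(20) * 3.8
    assert ca.native_contacts(coords, topo) == []


def test_cutoff_is_strict_and_sequence_separation_respected():
    topo = chain_topology(6)
    coords = np.zeros((6, 3))
    coords[:, 2] = np.arange(6) * 100.0        # far apart by default
    coords[5] = coords[0] + np.array([7.9, 0, 0])     # |i-j| = 5 > 3
    contacts = ca.native_contacts(coords, topo)
    assert [(c.i, c.j) for c in contacts] == [(1, 6)]
    coords[5] = coords[0] + np.array([8.1, 0, 0])
    assert ca.native_contacts(coords, topo) == []
    # 7.9 A but only 3 apart in sequence: excluded
    coords[5] = coords[0] + np.array([500.0, 0, 0])
    coords[3] = coords[0] + np.array([7.9, 0, 0])
    assert ca.native_contacts(coords, topo) == []


def test_contacts_invariant_under_rigid_motion(template7_free):
    from scipy.spatial.transform import Rotation
    tmpl = template7_free
    base = ca.native_contacts(tmpl.coords, tmpl.topology, tmpl.repeat_map)
    rot = Rotation.from_euler("zyx", [11, 42, 77], degrees=True).as_matrix()
    moved = tmpl.coords @ rot.T + np.array([3.0, -8.0, 12.0])
    same = ca.native_contacts(moved, tmpl.topology, tmpl.repeat_map)
    assert {(c.i, c.j) for c in base} == {(c.i, c.j) for c in same}


# ---------------------------------------------------------------------------
# presence and recurrence

def test_presence_native_first_frame_extended_last(template7_free):
    params = rp.SimParams(speed=0.05)
    _, truth = rp.simulate_pull(params, 4)
    traj = rp.synthesize_trajectory(truth, template7_free, 1,
                                    frame_interval=20.0, window=200.0,
                                    jitter=0.0)
    contacts = ca.native_contacts(template7_free.coords,
                                  template7_free.topology,
                                  template7_free.repeat_map)
    presence = ca.contact_presence(traj, contacts)
    assert presence[0].all()
    assert not presence[-1].any()


def test_recurrence_boundary_inclusive_and_alternating_excluded():
    times = np.arange(0.0, 2000.0, 4.0)
    n = times.size
    presence = np.zeros((n, 2), dtype=bool)
    # contact 0: present for exactly 0.4 ns once (101 frames at 4 ps)
    presence[50:151, 0] = True
    # contact 1: alternating frames
    presence[::2, 1] = True
    recurrent, last = ca.recurrent_contacts(presence, times, min_run=400.0)
    assert recurrent.tolist() == [True, False]
    assert last[0] == pytest.approx(times[150])
    assert last[1] == 0.0


def test_lifetime_full_run_and_mean_se():
    times = np.arange(0.0, 100.0, 4.0)
    n = times.size
    always = np.ones((n, 1), dtype=bool)
    contacts = [ca.Contact(i=1, j=6, native=True, contact_class="other")]
    cmap = ca.contact_lifetimes([always], times, contacts, min_run=40.0)
    assert cmap.mean[0] == pytest.approx(times[-1])

    run1 = np.zeros((n, 1), dtype=bool)
    run1[: np.searchsorted(times, 10.0) + 1] = True
    run2 = np.zeros((n, 1), dtype=bool)
    run2[: np.searchsorted(times, 20.0) + 1] = True
    cmap = ca.contact_lifetimes([run1, run2], times, contacts, min_run=8.0)
    assert cmap.mean[0] == pytest.approx(15.0, abs=2.0)
    assert cmap.sem[0] == pytest.approx(
        np.std(cmap.lifetimes[:, 0], ddof=1) / np.sqrt(2))


def test_scripted_transient_contact_detected_with_correct_end():
    times = np.arange(0.0, 4000.0, 4.0)
    n = times.size
    presence = np.zeros((n, 1), dtype=bool)
    start = np.searchsorted(times, 1000.0)
    stop = np.searchsorted(times, 1600.0)          # 0.6 ns stretch
    presence[start:stop + 1, 0] = True
    recurrent, last = ca.recurrent_contacts(presence, times, min_run=400.0)
    assert recurrent[0]
    assert abs(last[0] - 1600.0) <= 4.0


def test_intra_repeat_lifetimes_order_with_rupture_order(template7_free):
    """Mean lifetime of a repeat's intra-repeat contacts must rank like
    the ground-truth rupture order (later repeats live longer)."""
    from scipy.stats import spearmanr
    params = rp.SimParams(speed=0.01)
    rmap = template7_free.repeat_map
    contacts = ca.native_contacts(template7_free.coords,
                                  template7_free.topology, rmap)
    intra = {r: [k for k, c in enumerate(contacts)
                 if rmap.repeat_of_residue(c.i) == r
                 and rmap.repeat_of_residue(c.j) == r]
             for r in range(1, 8)}
    rhos = []
    for seed in range(3):
        _, truth = rp.simulate_pull(params, 60 + seed)
        traj = rp.synthesize_trajectory(truth, template7_free, seed)
        presence = ca.contact_presence(traj, contacts)
        _, last = ca.recurrent_contacts(presence, traj.times)
        life = [np.mean(last[intra[r]]) for r in range(1, 8)]
        mid = [truth.repeat_midpoints[r] for r in range(1, 8)]
        rhos.append(spearmanr(life, mid).statistic)
    assert min(rhos) > 0.9


# ---------------------------------------------------------------------------
# ligand binding

def test_fixed_bead_makes_native_binder():
    topo = chain_topology(12, with_ligand=True)
    n_frames = 50
    coords = np.zeros((n_frames, 13, 3))
    coords[:, :12, 2] = np.arange(12) * 3.8
    coords[:, 12] = coords[:, 9] + np.array([4.0, 0, 0])   # near residue 10
    traj = rp.PullingTrajectory(topology=topo,
                                times=np.arange(n_frames) * 4.0,
                                coords=coords)
    rec = ca.binding_analysis(traj, (0.0, 100.0))
    assert rec.native_binder[9]
    assert rec.native_binder.sum() == 1


def test_strict_eighty_percent_rule():
    topo = chain_topology(12, with_ligand=True)
    n_frames = 100
    coords = np.zeros((n_frames, 13, 3))
    coords[:, :12, 2] = np.arange(12) * 3.8
    coords[:, 12] = np.array([100.0, 0, 0])
    near = coords[0, 9] + np.array([4.0, 0, 0])
    coords[:79, 12] = near        # bound in 79 of 100 equilibration frames
    times = np.arange(n_frames, dtype=float)
    traj = rp.PullingTrajectory(topology=topo, times=times, coords=coords)
    rec = ca.binding_analysis(traj, (0.0, 99.0))
    assert not rec.native_binder[9]
    coords[:81, 12] = near        # 81%: strictly above the threshold
    traj = rp.PullingTrajectory(topology=topo, times=times, coords=coords)
    rec = ca.binding_analysis(traj, (0.0, 99.0))
    assert rec.native_binder[9]


def test_no_ligand_is_config_error(template7_free):
    traj = rp.PullingTrajectory(topology=template7_free.topology,
                                times=[0.0],
                                coords=template7_free.coords[None])
    with pytest.raises(ConfigError):
        ca.binding_analysis(traj, (0.0, 1.0))


def test_binding_loss_follows_detachment_schedule(template7, bound_run):
    """Per-residue last-binding frames must match the scripted ligand
    detachment times (each repeat's unfolding midpoint) within a frame."""
    _, truth, traj = bound_run
    rec = ca.binding_analysis(
        traj, (0.0, 0.5 * min(truth.repeat_midpoints.values())))
    dt = traj.times[1] - traj.times[0]
    rmap = template7.repeat_map
    for rep in range(1, 7):
        lo, hi = [r[1:] for r in rmap.repeats if r[0] == rep][0]
        mask = ((rec.residues >= lo) & (rec.residues <= hi)
                & rec.native_binder)
        assert mask.any()
        detach = truth.repeat_midpoints[rep] - 800.0   # window onset
        expected = traj.times[traj.times <= detach][-1]
        # the residue carrying the bead holds until the scripted
        # detachment; its neighbours may release earlier as the repeat
        # stretches
        assert abs(rec.lifetime[mask].max() - expected) <= dt + 1e-9
        assert rec.lifetime[mask].min() <= expected + dt
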