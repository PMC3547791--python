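"""Native-contact and ligand-binding lifetime analysis.

A native contact is a residue pair whose Cα atoms are closer than 8 Å in
the native structure, with the pair more than three residues apart in
sequence.  Along a pulling run a contact's lifetime is the last time it
was consistently observed, where "consistently" means inside a
continuous stretch of at least 0.4 ns of trajectory (the recurrence
filter, which removes transient flickers).  Ligand binding uses the same
machinery per protein residue: a residue is in contact with the ligand
when any of its atoms is within 5 Å of any ligand atom, native binders
are residues bound for more than 80% of the equilibration span, and the
binding lifetime is the last (recurrence-filtered) binding time,
averaged over runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, GeometryError
from .trajio import LIGAND, PROTEIN, PullingTrajectory, RepeatMap, Topology

__all__ = [
    "Contact", "ContactLifetimeMap", "BindingRecord",
    "native_contacts", "contact_presence", "recurrent_contacts",
    "contact_lifetimes", "binding_analysis", "binding_lifetime_map",
]

DEFAULT_CUTOFF = 8.0          # Å, Cα-Cα
DEFAULT_MIN_SEQ_SEP = 3       # pairs must be more than this apart
DEFAULT_MIN_RUN_PS = 400.0    # 0.4 ns recurrence window
BINDING_CUTOFF = 5.0          # Å, any atom to any ligand atom
NATIVE_BINDER_FRACTION = 0.8  # strict > 80% of equilibration


@dataclass(frozen=True)
class Contact:
    i: int                    # residue indices, i < j, j - i > min_seq_sep
    j: int
    native: bool
    contact_class: str        # intra_helix | inter_helix | intra_turn |
                              # inter_turn | other


@dataclass
class ContactLifetimeMap:
    contacts: list[Contact]
    lifetimes: np.ndarray      # (n_runs, n_contacts), ps
    mean: np.ndarray           # (n_contacts,)
    sem: np.ndarray            # standard error across runs
    never_recurrent: np.ndarray   # bool, lifetime 0 in every run


@dataclass
class BindingRecord:
    residues: np.ndarray            # residue indices (1-based)
    native_binder: np.ndarray       # bool per residue
    presence: np.ndarray            # (n_frames, n_residues) bool
    lifetime: np.ndarray            # per residue, ps (this run)


def _ca_positions(topology: Topology, coords: np.ndarray):
    idx = topology.atom_indices(atom_names=("CA",), chain=PROTEIN)
    res_index = np.array([topology.atoms[i].residue_index for i in idx])
    res_ids = np.array([topology.residues[r].index for r in res_index])
    order = np.argsort(res_ids)
    return idx[order], res_ids[order]


def _classify(i: int, j: int, repeat_map: RepeatMap | None) -> str:
    if repeat_map is None:
        return "other"
    ri = repeat_map.repeat_of_residue(i)
    rj = repeat_map.repeat_of_residue(j)
    if ri is None or rj is None:
        return "other"
    first_i = next(lo for rid, lo, hi in repeat_map.repeats if rid == ri)
    first_j = next(lo for rid, lo, hi in repeat_map.repeats if rid == rj)
    reg_i = repeat_map.region_of_offset(i - first_i)
    reg_j = repeat_map.region_of_offset(j - first_j)
    if reg_i != reg_j or reg_i not in ("helix", "turn"):
        return "other"
    scope = "intra" if ri == rj else "inter"
    return f"{scope}_{reg_i}"


def native_contacts(native_coords: np.ndarray, topology: Topology,
                    repeat_map: RepeatMap | None = None,
                    cutoff: float = DEFAULT_CUTOFF,
                    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> list[Contact]:
    """All residue pairs with native Cα distance strictly below cutoff.

    Only pairs more than ``min_seq_sep`` residues apart in sequence
    qualify.  Pairs are classified by repeat membership (intra/inter)
    and region (helix/turn) from the repeat map.
    """
    native_coords = np.asarray(native_coords, dtype=float)
    ca_idx, res_ids = _ca_positions(topology, native_coords)
    n_prot = sum(1 for r in topology.residues if r.chain == PROTEIN)
    if ca_idx.size != n_prot:
        missing = set(r.index for r in topology.residues
                      if r.chain == PROTEIN) - set(res_ids.tolist())
        raise GeometryError(f"missing CA for residues {sorted(missing)[:5]}")
    pos = native_coords[ca_idx]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    contacts = []
    for a in range(len(res_ids)):
        for b in range(a + 1, len(res_ids)):
            if res_ids[b] - res_ids[a] <= min_seq_sep:
                continue
            if dist[a, b] < cutoff:
                i, j = int(res_ids[a]), int(res_ids[b])
                contacts.append(Contact(i=i, j=j, native=True,
                                        contact_class=_classify(
                                            i, j, repeat_map)))
    return contacts


def contact_presence(traj: PullingTrajectory, contacts: list[Contact],
                     cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Boolean (n_frames, n_contacts): Cα distance < cutoff per frame."""
    ca_idx, res_ids = _ca_positions(traj.topology, traj.coords[0])
    id_to_pos = {int(r): k for k, r in enumerate(res_ids)}
    pos = traj.coords[:, ca_idx, :]
    ai = np.array([id_to_pos[c.i] for c in contacts])
    bi = np.array([id_to_pos[c.j] for c in contacts])
    d = np.linalg.norm(pos[:, ai, :] - pos[:, bi, :], axis=-1)
    return d < cutoff


def _last_consistent_time(present: np.ndarray, times: np.ndarray,
                          min_run: float) -> float:
    """End time of the last run of consecutive present frames spanning at
    least ``min_run`` ps (span inclusive: (k-1) x frame interval); 0.0 if
    no such run exists."""
    if not present.any():
        return 0.0
    padded = np.concatenate([[False], present, [False]])
    starts = np.nonzero(~padded[:-1] & padded[1:])[0]
    ends = np.nonzero(padded[:-1] & ~padded[1:])[0] - 1
    best = 0.0
    for s, e in zip(starts, ends):
        if times[e] - times[s] >= min_run:
            best = float(times[e])
    return best


def recurrent_contacts(presence: np.ndarray, times,
                       min_run: float = DEFAULT_MIN_RUN_PS
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Recurrence filter: a contact is recurrent iff it is present in a
    continuous stretch of trajectory spanning at least ``min_run`` ps.

    Returns ``(recurrent_mask, last_consistent_time)`` per contact; the
    time is the end of the last qualifying stretch (0 if none).
    """
    times = np.asarray(times, dtype=float)
    if times.size != presence.shape[0]:
        raise DataError("presence and time base differ in length")
    n_contacts = presence.shape[1]
    last = np.zeros(n_contacts)
    for c in range(n_contacts):
        last[c] = _last_consistent_time(presence[:, c], times, min_run)
    return last > 0, last


def contact_lifetimes(presence_per_run: list[np.ndarray], times,
                      contacts: list[Contact],
                      min_run: float = DEFAULT_MIN_RUN_PS
                      ) -> ContactLifetimeMap:
    """Per-run recurrence-filtered lifetimes, averaged across runs.

    The lifetime of a contact in a run is the last time it was
    consistently observed; contacts never recurrent in a run get 0 there
    and are flagged when that happens in every run.
    """
    if not presence_per_run:
        raise DataError("need at least one run")
    times = np.asarray(times, dtype=float)
    lifetimes = np.zeros((len(presence_per_run), len(contacts)))
    for k, presence in enumerate(presence_per_run):
        _, last = recurrent_contacts(presence, times, min_run)
        lifetimes[k] = last
    mean = lifetimes.mean(axis=0)
    n = lifetimes.shape[0]
    sem = (lifetimes.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
           else np.zeros(len(contacts)))
    return ContactLifetimeMap(contacts=contacts, lifetimes=lifetimes,
                              mean=mean, sem=sem,
                              never_recurrent=np.all(lifetimes == 0, axis=0))


# ---------------------------------------------------------------------------
# ligand binding

def _binding_presence(traj: PullingTrajectory,
                      cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    topo = traj.topology
    lig_idx = topo.atom_indices(chain=LIGAND)
    if lig_idx.size == 0:
        raise ConfigError("trajectory has no ligand atoms")
    prot_res = [r for r in topo.residues if r.chain == PROTEIN]
    res_ids = np.array([r.index for r in prot_res])
    presence = np.zeros((traj.n_frames, len(prot_res)), dtype=bool)
    lig = traj.coords[:, lig_idx, :]
    for k, res in enumerate(prot_res):
        atom_idx = [i for i, a in enumerate(topo.atoms)
                    if topo.residues[a.residue_index] is res]
        ra = traj.coords[:, atom_idx, :]
        d = np.linalg.norm(ra[:, :, None, :] - lig[:, None, :, :], axis=-1)
        presence[:, k] = d.min(axis=(1, 2)) < cutoff
    return presence, res_ids


def binding_analysis(traj: PullingTrajectory,
                     equilibration_span: tuple[float, float],
                     cutoff: float = BINDING_CUTOFF,
                     native_fraction: float = NATIVE_BINDER_FRACTION,
                     recurrence_filter: bool = True,
                     min_run: float = DEFAULT_MIN_RUN_PS) -> BindingRecord:
    """Per-residue ligand binding flags and lifetimes for one run.

    A residue binds at a frame when any of its atoms is within
    ``cutoff`` of any ligand atom; native binders are residues bound in
    strictly more than ``native_fraction`` of the equilibration frames.
    Lifetimes are the last binding time, by default recurrence-filtered
    with the same consistency window as protein contacts (set
    ``recurrence_filter=False`` for the raw last-observation time).
    """
    presence, res_ids = _binding_presence(traj, cutoff)
    t0, t1 = equilibration_span
    equil = (traj.times >= t0) & (traj.times <= t1)
    if not equil.any():
        raise ConfigError("equilibration span contains no frames")
    frac = presence[equil].mean(axis=0)
    native = frac > native_fraction

    lifetime = np.zeros(len(res_ids))
    for k in range(len(res_ids)):
        if recurrence_filter:
            lifetime[k] = _last_consistent_time(presence[:, k], traj.times,
                                                min_run)
        else:
            hits = np.nonzero(presence[:, k])[0]
            lifetime[k] = float(traj.times[hits[-1]]) if hits.size else 0.0
    return BindingRecord(residues=res_ids, native_binder=native,
                         presence=presence, lifetime=lifetime)


def binding_lifetime_map(records: list[BindingRecord]
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and standard error of per-residue binding lifetimes over runs.

    Returns ``(residues, mean, sem)``.
    """
    if not records:
        raise DataError("need at least one run")
    residues = records[0].residues
    lifetimes = np.stack([r.lifetime for r in records])
    mean = lifetimes.mean(axis=0)
    n = lifetimes.shape[0]
    sem = (lifetimes.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
           else np.zeros(len(residues)))
    return residues, mean, sem
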