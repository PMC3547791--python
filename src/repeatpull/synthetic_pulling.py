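"""Seeded synthetic stand-in for steered-MD constant-velocity pulling.

:func:`simulate_pull` couples a harmonic spring moved at constant
velocity to a worm-like chain whose contour grows by L = 56.8 Å each
time a half-repeat unfolds.  Unfolding is stochastic with Bell kinetics,
rate k0·exp(F·Δx‡/kBT − ΔΔG), evaluated on a fixed 0.1-ps step; ligand
binding adds a per-repeat stabilisation ΔΔG (restricted to all but the
C-terminal repeat) that raises rupture forces.  Only the two edge
repeats of the folded core are unfolding-competent, with the N-terminal
edge damped by a bias factor, which yields the dominantly C→N sequential
unfolding order seen for stacked repeat arrays.  Every event is recorded
as ground truth so the analysis modules can be scored against it.

:func:`make_native_template` and :func:`synthesize_trajectory` build a
toy coordinate trajectory (compact two-strand repeat blocks that extend
into straight segments around their rupture times, with optional ligand
beads) for the RMSD/contact/binding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kbt
from .errors import ConfigError, DataError, NumericalError
from .trajio import (LIGAND, PROTEIN, Atom, ForceTrace, PullingTrajectory,
                     RepeatMap, Residue, Topology)

__all__ = [
    "SimParams", "RuptureEvent", "GroundTruth", "NativeTemplate",
    "simulate_pull", "make_native_template", "synthesize_trajectory",
]

_BISECT_ITERS = 50          # brackets [0, 0.999 Lc] down to < 1e-8 A
_CHUNK = 20000              # substeps processed per vectorised block


@dataclass
class SimParams:
    """Parameters of the synthetic pulling run.

    Defaults reproduce the study conditions: 7 repeats, half-repeat
    unfolded contour L = 56.8 Å, persistence length 3.8 Å, spring
    20 pN/Å, pulling speed 0.01 Å/ps (frames every 4 ps) or 0.05 Å/ps
    (frames every 1 ps), 300 K.  Bell-rate defaults (k0 = 1e-5/ps,
    Δx‡ = 1 Å) are synthetic, calibrated so rupture forces land in the
    100–400 pN range at these speeds.
    """

    n_repeats: int = 7
    half_contour: float = 56.8        # L, Å released per half-repeat
    folded_rise: float = 0.0          # axial length of a folded repeat, Å
    persistence: float = 3.8          # p, Å
    spring_k: float = 20.0            # pN/Å
    speed: float = 0.01               # Å/ps
    temperature: float = 300.0        # K
    k0: float = 1e-5                  # intrinsic unfolding rate, 1/ps
    bell_dx: float = 1.0              # Δx‡, Å
    ligand: bool = False
    ddg: float = 4.0                  # kBT, applied to repeats 1..R-1 if bound
    ddg_per_repeat: tuple | None = None   # explicit override, length R
    q_whole: float = 0.3              # P(second half follows immediately)
    n_edge_bias: float = 0.05         # rate factor for the N-terminal edge
    noise_sigma: float = 8.0          # pN, reported-force noise
    frame_interval: float | None = None   # ps; default 4 (slow) / 1 (fast)
    dt: float = 0.1                   # kinetic integration step, ps
    linker_contour: float = 30.0      # initially unfolded contour, Å
    final_fraction: float = 0.93      # stop when X reaches this x total contour
    t_max: float | None = None        # explicit duration override, ps
    anchor_relax_ps: float = 200.0    # freed contour enters the anchors
                                      # over this span, not in one frame

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ConfigError("need at least one repeat")
        for name in ("half_contour", "persistence", "spring_k", "speed",
                     "temperature", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.k0 < 0 or self.bell_dx < 0 or self.noise_sigma < 0 \
                or self.folded_rise < 0 or self.linker_contour < 0:
            raise ConfigError("rates, lengths and noise must be >= 0")
        if not 0.0 <= self.q_whole <= 1.0:
            raise ConfigError("q_whole must be in [0, 1]")
        if self.frame_interval is None:
            self.frame_interval = 4.0 if self.speed <= 0.02 else 1.0

    def ddg_array(self) -> np.ndarray:
        """Effective per-repeat stabilisation in kBT (index 0 = repeat 1)."""
        if self.ddg_per_repeat is not None:
            arr = np.asarray(self.ddg_per_repeat, dtype=float)
            if arr.size != self.n_repeats:
                raise ConfigError("ddg_per_repeat length != n_repeats")
        elif self.ligand:
            # graded stabilisation profile: strongest at the N-terminal
            # repeat, weakest at the last ligand-contacting repeat, zero
            # on the C-terminal repeat (which the ligand does not touch)
            profile = np.ones(self.n_repeats)
            profile[-1] = 0.0
            profile[0] = 1.5
            if self.n_repeats >= 3:
                profile[1] = 1.25
            if self.n_repeats >= 2:
                profile[-2] = 0.75
            arr = float(self.ddg) * profile
        else:
            arr = np.zeros(self.n_repeats)
        if np.any(arr < 0):
            raise ConfigError("ddg must be >= 0")
        if self.ligand and arr[-1] > 0:
            raise ConfigError("stabilised repeats must exclude the "
                              "C-terminal repeat")
        return arr


@dataclass
class RuptureEvent:
    repeat_id: int
    half: int                  # 1 or 2
    time: float                # ps
    force: float               # pN, noiseless force just before rupture
    contour_released: float    # cumulative unfolded contour after event, Å


@dataclass
class GroundTruth:
    """Everything the analysis modules are supposed to recover."""

    events: list[RuptureEvent]
    repeat_midpoints: dict[int, float]       # fully unfolded repeats only
    repeat_order: dict[int, int]             # repeat -> rank (1 = first)
    repeat_rupture_force: dict[int, float]   # first-half rupture force
    total_work: float                        # pN·Å, noiseless
    repeat_work: dict[int, float]            # pN·Å, noiseless
    t_final: float
    params: SimParams = None


def _solve_extension(X, contour, rod, k, p, T):
    """Vectorised force balance k(X − rod − x) = F_wlc(x), x in [0, .999 Lc].

    Returns the chain (WLC) extension x for each spring position X.
    """
    X = np.atleast_1d(np.asarray(X, dtype=float))
    if contour <= 0:
        return np.zeros_like(X)
    lo = np.zeros_like(X)
    hi = np.full_like(X, 0.999 * contour)
    kb = kbt(T)

    def g(x):
        s = x / contour
        fw = (kb / p) * (0.25 / (1.0 - s) ** 2 - 0.25 + s)
        return k * (X - rod - x) - fw

    if np.any(g(hi) > 0):
        bad = int(np.nonzero(g(hi) > 0)[0][0])
        raise NumericalError(
            f"force balance not bracketed at step {bad}: spring position "
            f"exceeds 0.999 x contour capacity")
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


class _EdgeState:
    """Which half-repeats are currently unfolding-competent."""

    def __init__(self, n_repeats: int):
        self.halves = np.zeros(n_repeats + 1, dtype=int)  # 1-indexed
        self.c_ptr = n_repeats
        self.n_ptr = 1

    def eligible(self):
        """[(repeat, next_half, is_n_edge), ...] — C edge first."""
        out = []
        if self.c_ptr >= self.n_ptr and self.halves[self.c_ptr] < 2:
            out.append((self.c_ptr, self.halves[self.c_ptr] + 1, False))
        if self.n_ptr < self.c_ptr and self.halves[self.n_ptr] < 2:
            out.append((self.n_ptr, self.halves[self.n_ptr] + 1, True))
        return out

    def rupture(self, repeat: int) -> None:
        self.halves[repeat] += 1
        if self.halves[repeat] == 2:
            if repeat == self.c_ptr:
                self.c_ptr -= 1
            elif repeat == self.n_ptr:
                self.n_ptr += 1

    @property
    def done(self) -> bool:
        return self.c_ptr < self.n_ptr


def simulate_pull(params: SimParams, seed: int) -> tuple[ForceTrace, GroundTruth]:
    """Run one constant-velocity pull and return trace plus ground truth.

    The spring end moves as X(t) = X0 + v·t; at every 0.1-ps substep the
    chain extension solves the static force balance between the spring
    and the Marko–Siggia restoring force of the currently unfolded
    contour (folded repeats contribute a rigid rise, zero by default).
    Each competent half-repeat accumulates Bell hazard
    k0·exp(F·Δx‡/kBT − ΔΔG)·dt and ruptures when the accumulated hazard
    crosses an Exp(1) draw — the discrete fixed-step equivalent of
    per-step Bernoulli trials.  Gaussian noise is added to the reported
    force only; the dynamics are noise-free.
    """
    rng = np.random.default_rng(seed)
    R = params.n_repeats
    L = params.half_contour
    ddg = params.ddg_array()
    kb = kbt(params.temperature)
    dt, v, k = params.dt, params.speed, params.spring_k

    rod0 = R * params.folded_rise
    X0 = rod0
    total_contour = params.linker_contour + 2 * R * L
    if params.t_max is not None:
        n_steps = int(round(params.t_max / dt))
    else:
        X_end = params.final_fraction * total_contour + rod0
        n_steps = int(np.ceil((X_end - X0) / (v * dt)))
    m = max(1, int(round(params.frame_interval / dt)))
    frame_steps = np.arange(0, n_steps + 1, m)
    n_frames = frame_steps.size
    frame_is_needed = np.zeros(n_steps + 1, dtype=bool)
    frame_is_needed[frame_steps] = True
    frame_index_of_step = np.cumsum(frame_is_needed) - 1

    F_frame = np.zeros(n_frames)
    x_frame = np.zeros(n_frames)       # total extension (rod + WLC)

    state = _EdgeState(R)
    contour = params.linker_contour
    rod = rod0
    events: list[RuptureEvent] = []
    released = 0.0

    # frame 0 (t = 0): force balance at the initial spring position
    xw0 = float(_solve_extension(np.array([X0]), contour, rod, k,
                                 params.persistence, params.temperature)[0])
    F_frame[0] = k * (X0 - rod - xw0)
    x_frame[0] = rod + xw0

    j = 0          # substeps up to and including j are committed
    while j < n_steps:
        elig = state.eligible()
        thresholds = [rng.exponential() for _ in elig]
        hazards = [0.0] * len(elig)
        event_step = None
        event_elem = None
        seg_done = False
        while not seg_done:
            j1 = min(j + _CHUNK, n_steps)
            steps = np.arange(j + 1, j1 + 1)
            X = X0 + v * dt * steps
            xw = _solve_extension(X, contour, rod, k,
                                  params.persistence, params.temperature)
            F = k * (X - rod - xw)
            cross_at = len(steps)
            for idx, ((rep, half, n_edge), thr) in enumerate(
                    zip(elig, thresholds)):
                eff = ddg[rep - 1] if half == 1 else 0.0
                lam = params.k0 * np.exp(F * params.bell_dx / kb - eff)
                if n_edge:
                    lam = lam * params.n_edge_bias
                H = hazards[idx] + np.cumsum(lam) * dt
                hit = np.searchsorted(H, thr)
                if hit < cross_at:
                    cross_at = hit
                    event_elem = (rep, half)
                hazards[idx] = float(H[-1])
            commit = cross_at if cross_at < len(steps) else len(steps) - 1
            # store frames among committed substeps
            sel = frame_is_needed[steps[: commit + 1]]
            if np.any(sel):
                fidx = frame_index_of_step[steps[: commit + 1][sel]]
                F_frame[fidx] = F[: commit + 1][sel]
                x_frame[fidx] = rod + xw[: commit + 1][sel]
            if cross_at < len(steps):
                je = int(steps[cross_at])
                t_ev = je * dt
                f_ev = float(F[cross_at])
                rep, half = event_elem
                contour += L
                released += L
                rod -= params.folded_rise / 2.0
                state.rupture(rep)
                events.append(RuptureEvent(rep, half, t_ev, f_ev, released))
                if half == 1 and rng.random() < params.q_whole:
                    contour += L
                    released += L
                    rod -= params.folded_rise / 2.0
                    state.rupture(rep)
                    events.append(RuptureEvent(rep, 2, t_ev, f_ev, released))
                j = je
                seg_done = True
            else:
                j = j1
                if j >= n_steps:
                    seg_done = True
        if state.done and j < n_steps:
            # nothing left to unfold: fill remaining frames in one sweep
            steps = np.arange(j + 1, n_steps + 1)
            X = X0 + v * dt * steps
            xw = _solve_extension(X, contour, rod, k,
                                  params.persistence, params.temperature)
            sel = frame_is_needed[steps]
            fidx = frame_index_of_step[steps[sel]]
            F_frame[fidx] = (k * (X - rod - xw))[sel]
            x_frame[fidx] = rod + xw[sel]
            j = n_steps

    times = frame_steps * dt
    t_final = float(times[-1])

    # --- per-frame anchor positions --------------------------------------
    # Each repeat's weight on the pulling axis = its remaining rigid rise
    # plus its released contour (the linker is split between the terminal
    # repeats) times the instantaneous WLC fractional extension; the
    # weights then sum exactly to the total extension, so the per-repeat
    # end-to-end vectors telescope.
    rel = np.zeros((n_frames, R))
    rodf = np.full((n_frames, R), params.folded_rise)
    relax = max(params.anchor_relax_ps, 1e-9)
    for ev in events:
        # ramp the freed contour into the anchors over a short relaxation
        # window: the released chain straightens over the following
        # loading phase rather than teleporting in one frame
        frac = np.clip((times - ev.time) / relax, 0.0, 1.0)
        rel[:, ev.repeat_id - 1] += L * frac
        rodf[:, ev.repeat_id - 1] -= params.folded_rise / 2.0 * frac
    rel[:, 0] += params.linker_contour / 2.0
    rel[:, R - 1] += params.linker_contour / 2.0
    lc_tot = rel.sum(axis=1)
    xw_frames = x_frame - rodf.sum(axis=1)
    phi = np.where(lc_tot > 0, xw_frames / lc_tot, 0.0)
    weights = rodf + rel * phi[:, None]
    anchors = np.zeros((n_frames, R + 1, 3))
    anchors[:, 1:, 2] = np.cumsum(weights, axis=1)

    # --- ground-truth work (noiseless force) ------------------------------
    fbar = 0.5 * (F_frame[1:] + F_frame[:-1])
    d_tot = np.diff(x_frame)
    total_work = float(np.sum(fbar * d_tot))
    repeat_work = {}
    for r in range(R):
        d_r = np.diff(anchors[:, r + 1, 2] - anchors[:, r, 2])
        repeat_work[r + 1] = float(np.sum(fbar * d_r))

    # --- reported trace ----------------------------------------------------
    noise = (params.noise_sigma * rng.standard_normal(n_frames)
             if params.noise_sigma > 0 else np.zeros(n_frames))
    force = np.zeros((n_frames, 3))
    force[:, 2] = F_frame + noise
    e2e = np.zeros((n_frames, 3))
    e2e[:, 2] = x_frame

    metadata = {
        "spring_k_pN_A": params.spring_k, "speed_A_ps": params.speed,
        "seed": seed, "ligand": params.ligand,
        "n_repeats": R, "half_contour_A": L,
        "persistence_A": params.persistence,
        "temperature_K": params.temperature,
        "k0_per_ps": params.k0, "bell_dx_A": params.bell_dx,
        "q_whole": params.q_whole, "noise_sigma_pN": params.noise_sigma,
        "frame_interval_ps": params.frame_interval,
        "linker_contour_A": params.linker_contour,
    }
    trace = ForceTrace(time=times, force=force, end_to_end=e2e,
                       anchors=anchors, metadata=metadata)

    # --- per-repeat summary -----------------------------------------------
    halves_by_rep: dict[int, list[RuptureEvent]] = {}
    for ev in events:
        halves_by_rep.setdefault(ev.repeat_id, []).append(ev)
    midpoints = {r: float(np.mean([e.time for e in evs]))
                 for r, evs in halves_by_rep.items() if len(evs) == 2}
    order = {r: rank + 1 for rank, r in enumerate(
        sorted(midpoints, key=lambda r: (midpoints[r], r)))}
    rupture_force = {r: evs[0].force for r, evs in halves_by_rep.items()}

    truth = GroundTruth(events=events, repeat_midpoints=midpoints,
                        repeat_order=order,
                        repeat_rupture_force=rupture_force,
                        total_work=total_work, repeat_work=repeat_work,
                        t_final=t_final, params=params)
    return trace, truth


# ---------------------------------------------------------------------------
# toy coordinate template + trajectory synthesis

@dataclass
class NativeTemplate:
    topology: Topology
    coords: np.ndarray            # (n_atoms, 3), Å
    repeat_map: RepeatMap
    ligand_repeats: tuple = ()

    @property
    def n_repeats(self) -> int:
        return self.repeat_map.n_repeats


def make_native_template(n_repeats: int = 7, residues_per_repeat: int = 12,
                         seed: int = 0, ligand_repeats=None,
                         jitter: float = 0.0) -> NativeTemplate:
    """Deterministic toy repeat array of Cα/Cβ sites.

    Each repeat is a compact block of two antiparallel pseudo-helix
    strands; blocks stack along z with a fixed rise so inter-block Cα
    contacts (< 8 Å) exist only between adjacent repeats.  If
    ``ligand_repeats`` is given, one ligand bead is placed within 5 Å of
    each listed repeat's first strand (and > 5 Å from every other
    repeat).
    """
    if n_repeats < 1:
        raise ConfigError("n_repeats must be >= 1")
    if residues_per_repeat < 8 or residues_per_repeat % 2:
        raise ConfigError("residues_per_repeat must be even and >= 8")
    rng = np.random.default_rng(seed)
    h = residues_per_repeat // 2
    res_spacing, strand_sep, block_rise = 2.5, 5.0, 15.0

    residues, atoms, coords = [], [], []
    for rep in range(1, n_repeats + 1):
        z0 = (rep - 1) * block_rise
        for off in range(residues_per_repeat):
            gidx = (rep - 1) * residues_per_repeat + off + 1
            residues.append(Residue(index=gidx, name="ALA",
                                    repeat_id=rep, chain=PROTEIN))
            if off < h:                       # strand A, N->C along +z
                pos = np.array([0.0, 0.0, z0 + off * res_spacing])
            else:                             # strand B, antiparallel
                pos = np.array([strand_sep, 0.0,
                                z0 + (residues_per_repeat - 1 - off)
                                * res_spacing])
            ridx = len(residues) - 1
            atoms.append(Atom(residue_index=ridx, name="CA", element="C"))
            coords.append(pos)
            atoms.append(Atom(residue_index=ridx, name="CB", element="C"))
            coords.append(pos + np.array([0.0, 1.5, 0.0]))

    ligand_repeats = tuple(ligand_repeats or ())
    strand_mid = (h - 1) * res_spacing / 2.0
    for b, rep in enumerate(ligand_repeats, start=1):
        if not 1 <= rep <= n_repeats:
            raise ConfigError(f"ligand repeat {rep} outside 1..{n_repeats}")
        residues.append(Residue(index=b, name="LIG", repeat_id=None,
                                chain=LIGAND))
        atoms.append(Atom(residue_index=len(residues) - 1, name="C1",
                          element="C"))
        coords.append(np.array([-4.0, 0.0,
                                (rep - 1) * block_rise + strand_mid]))

    coords = np.asarray(coords)
    if jitter > 0:
        coords = coords + jitter * rng.standard_normal(coords.shape)
    coords = np.round(coords, 3)

    rmap = RepeatMap(
        repeats=[(r, (r - 1) * residues_per_repeat + 1,
                  r * residues_per_repeat) for r in range(1, n_repeats + 1)],
        regions={"turn": [0, 1], "helix": list(range(2, residues_per_repeat))})
    topology = Topology(residues=residues, atoms=atoms)
    return NativeTemplate(topology=topology, coords=coords, repeat_map=rmap,
                          ligand_repeats=ligand_repeats)


def synthesize_trajectory(truth: GroundTruth, template: NativeTemplate,
                          seed: int, frame_interval: float = 40.0,
                          window: float = 1600.0, jitter: float = 0.3,
                          detach_rate: float = 0.1,
                          extended_spacing: float | None = None
                          ) -> PullingTrajectory:
    """Build a coordinate trajectory consistent with a simulated pull.

    Each repeat interpolates linearly from its native block to a fully
    extended straight segment along z over a ``window`` (ps) centred on
    its ground-truth unfolding midpoint; untouched repeats keep their
    native geometry plus Gaussian ``jitter``.  Ligand beads track their
    repeat's first-strand anchor residue (staying < 5 Å away) until that
    repeat's unfolding window opens (midpoint − window/2) and then
    retreat at ``detach_rate`` Å/ps — releasing at the onset keeps a
    bead from riding its unfolding repeat across the extended chain,
    which would fabricate cross-repeat binding contacts.
    """
    rng = np.random.default_rng(seed)
    R = template.n_repeats
    if truth.params is not None and truth.params.n_repeats != R:
        raise ConfigError("template repeat count != ground-truth repeats")
    midpoints = truth.repeat_midpoints
    if midpoints and max(midpoints.values()) > truth.t_final:
        raise DataError("rupture times outside trace span")

    times = np.arange(0.0, truth.t_final + 0.5 * frame_interval,
                      frame_interval)
    n_frames = times.size
    topo = template.topology
    n_res_per = template.repeat_map.repeats[0][2] - \
        template.repeat_map.repeats[0][1] + 1
    if extended_spacing is None:
        L = truth.params.half_contour if truth.params else 56.8
        extended_spacing = 2.0 * L / n_res_per

    # extended target: all protein residues on a straight line along z,
    # offset in y so the extended chain does not thread through the
    # native blocks (and the beads still attached to them)
    y_ext = 12.0
    extended = np.empty_like(template.coords)
    for i, atom in enumerate(topo.atoms):
        res = topo.residues[atom.residue_index]
        if res.chain != PROTEIN:
            continue
        z = (res.index - 1) * extended_spacing
        extended[i] = ((0.0, y_ext, z) if atom.name == "CA"
                       else (0.0, y_ext + 1.0, z))

    prot_idx_by_rep = {r: topo.atom_indices(repeat_id=r, chain=PROTEIN)
                       for r in range(1, R + 1)}
    lig_atom_idx = topo.atom_indices(chain=LIGAND)
    # anchor residue per ligand bead: middle of its repeat's first strand
    anchor_atom = {}
    for b, rep in enumerate(template.ligand_repeats):
        a_idx = topo.atom_indices(atom_names=("CA",), repeat_id=rep,
                                  chain=PROTEIN)
        anchor_atom[lig_atom_idx[b]] = a_idx[(n_res_per // 2) // 2]

    coords = np.empty((n_frames, topo.n_atoms, 3))
    half_w = window / 2.0
    for fi, t in enumerate(times):
        frame = template.coords.copy()
        for r in range(1, R + 1):
            tm = midpoints.get(r)
            if tm is None:
                continue
            alpha = np.clip((t - (tm - half_w)) / window, 0.0, 1.0)
            if alpha > 0:
                idx = prot_idx_by_rep[r]
                frame[idx] = ((1 - alpha) * template.coords[idx]
                              + alpha * extended[idx])
        if jitter > 0:
            frame = frame + jitter * rng.standard_normal(frame.shape)
        # beads ride their (jittered) anchor residue so the bead-anchor
        # distance stays fixed until the scripted detachment
        for b, rep in enumerate(template.ligand_repeats):
            li = lig_atom_idx[b]
            ai = anchor_atom[li]
            offset = np.array([-4.0, 0.0, 0.0])
            tm = midpoints.get(rep)
            release = (truth.t_final + 1.0 if tm is None
                       else tm - half_w)
            if t > release:
                offset[0] -= detach_rate * (t - release)
            frame[li] = frame[ai] + offset
        coords[fi] = frame
    coords = np.round(coords, 3)     # PDB coordinate precision
    return PullingTrajectory(topology=topo, times=times, coords=coords)
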