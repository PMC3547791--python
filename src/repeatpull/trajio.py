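"""Data model and I/O for pulling trajectories, force traces and results.

Coordinates are in Å, times in ps, forces in pN.  Trajectories travel as
multi-model PDB files (one MODEL per saved frame); force traces as
TSV/CSV tables with ``# key=value`` metadata comment lines; repeat maps
as JSON.  Analysis outputs are written as TSV/JSON with fixed numeric
precision so identical inputs give byte-identical files.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, DataError, FormatError

__all__ = [
    "Residue", "Atom", "Topology", "RepeatMap", "PullingTrajectory",
    "ForceTrace", "read_trajectory", "write_trajectory",
    "read_force_trace", "write_force_trace",
    "read_repeat_map", "write_repeat_map",
    "write_table", "write_contingency_table", "write_json",
]

PROTEIN = "protein"
LIGAND = "ligand"


@dataclass
class Residue:
    index: int                 # 1-based, contiguous within a chain
    name: str
    repeat_id: int | None      # None for ligand residues
    chain: str = PROTEIN       # "protein" | "ligand"


@dataclass
class Atom:
    residue_index: int         # index into Topology.residues (0-based)
    name: str                  # e.g. "CA", "CB"
    element: str = "C"


@dataclass
class Topology:
    """Residue/atom naming for a pulling system.

    Residue indices are contiguous and unique within each chain; every
    repeat id maps to a non-empty contiguous residue range; ligand atoms
    carry no repeat id.
    """

    residues: list[Residue]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chain in (PROTEIN, LIGAND):
            idx = [r.index for r in self.residues if r.chain == chain]
            if idx and idx != list(range(idx[0], idx[0] + len(idx))):
                raise ConfigError(
                    f"{chain} residue indices not contiguous/unique: {idx[:8]}...")
        by_rep: dict[int, list[int]] = {}
        for i, r in enumerate(self.residues):
            if r.chain == LIGAND and r.repeat_id is not None:
                raise ConfigError("ligand residues must not carry a repeat_id")
            if r.repeat_id is not None:
                by_rep.setdefault(r.repeat_id, []).append(r.index)
        for rep, idx in by_rep.items():
            if idx != list(range(idx[0], idx[0] + len(idx))):
                raise ConfigError(f"repeat {rep} residue range not contiguous")
        n_res = len(self.residues)
        for a in self.atoms:
            if not 0 <= a.residue_index < n_res:
                raise ConfigError(f"atom {a.name} references residue "
                                  f"{a.residue_index} outside topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_indices(self, atom_names=None, repeat_id=None, chain=None):
        """Indices of atoms filtered by name / repeat / chain."""
        out = []
        for i, a in enumerate(self.atoms):
            res = self.residues[a.residue_index]
            if atom_names is not None and a.name not in atom_names:
                continue
            if repeat_id is not None and res.repeat_id != repeat_id:
                continue
            if chain is not None and res.chain != chain:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def repeat_ids(self) -> list[int]:
        seen = []
        for r in self.residues:
            if r.repeat_id is not None and r.repeat_id not in seen:
                seen.append(r.repeat_id)
        return seen


@dataclass
class RepeatMap:
    """Assignment of residue ranges to repeats plus pulling-anchor names.

    ``repeats`` is an ordered N→C list of (repeat_id, first_residue,
    last_residue) with non-overlapping ranges that jointly cover the
    protein chain (terminal overhangs belong to the first/last repeat).
    Boundary anchors are shared between adjacent repeats so the repeat
    end-to-end vectors telescope.  ``regions`` optionally labels residue
    offsets inside each repeat (e.g. {"turn": [0,1], "helix": [2,...,11]})
    for contact classification.
    """

    repeats: list[tuple[int, int, int]]
    n_terminal_anchor: str = "CA"
    c_terminal_anchor: str = "CA"
    boundary_anchor: str = "CA"
    regions: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        reps = [tuple(r) for r in self.repeats]
        for (ra, a0, a1), (rb, b0, b1) in zip(reps, reps[1:]):
            if a1 + 1 != b0:
                raise ConfigError(
                    f"repeats {ra} and {rb} are not contiguous N->C "
                    f"({a0}-{a1} then {b0}-{b1})")
        for rid, lo, hi in reps:
            if hi < lo:
                raise ConfigError(f"repeat {rid} has empty range {lo}-{hi}")
        self.repeats = reps

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def first_residue(self) -> int:
        return self.repeats[0][1]

    @property
    def last_residue(self) -> int:
        return self.repeats[-1][2]

    def repeat_of_residue(self, residue_index: int) -> int | None:
        for rid, lo, hi in self.repeats:
            if lo <= residue_index <= hi:
                return rid
        return None

    def region_of_offset(self, offset: int) -> str:
        if self.regions:
            for name, offsets in self.regions.items():
                if offset in offsets:
                    return name
        return "other"

    def check_span(self, n_protein_residues: int) -> None:
        if self.last_residue > n_protein_residues or self.first_residue < 1:
            raise ConfigError(
                f"repeat map spans residues {self.first_residue}-"
                f"{self.last_residue} but topology has {n_protein_residues}")


@dataclass
class PullingTrajectory:
    """Ordered frames of atom coordinates with a shared topology."""

    topology: Topology
    times: np.ndarray            # (n_frames,), ps, strictly increasing
    coords: np.ndarray           # (n_frames, n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DataError("frame times must be strictly increasing")
        if self.coords.ndim != 3 or self.coords.shape[0] != self.times.size \
                or self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate array {self.coords.shape} inconsistent with "
                f"{self.times.size} frames x {self.topology.n_atoms} atoms")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class ForceTrace:
    """Per-frame applied force, end-to-end vector and anchor positions.

    ``anchors`` has shape (n_frames, n_repeats+1, 3): anchor r is the
    N-side boundary of repeat r+1, anchor R is the C-terminal pull atom;
    adjacent repeats share boundary anchors so per-repeat end-to-end
    vectors telescope to the total.
    """

    time: np.ndarray             # (n,), ps
    force: np.ndarray            # (n, 3), pN
    end_to_end: np.ndarray       # (n, 3), Å
    anchors: np.ndarray | None = None   # (n, R+1, 3), Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.end_to_end = np.asarray(self.end_to_end, dtype=float)
        if self.anchors is not None:
            self.anchors = np.asarray(self.anchors, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise DataError("force-trace times must be strictly increasing")
        if self.force.shape != (self.time.size, 3):
            raise DataError("force must be (n, 3)")
        if self.end_to_end.shape != (self.time.size, 3):
            raise DataError("end_to_end must be (n, 3)")
        if self.anchors is not None:
            span = self.anchors[:, -1, :] - self.anchors[:, 0, :]
            if not np.allclose(span, self.end_to_end, atol=1e-6):
                raise DataError(
                    "end-to-end vector differs from terminal anchor span "
                    "by more than 1e-6 A")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def n_repeats(self) -> int | None:
        return None if self.anchors is None else self.anchors.shape[1] - 1

    @property
    def force_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.force, axis=1)

    @property
    def extension(self) -> np.ndarray:
        return np.linalg.norm(self.end_to_end, axis=1)


# ---------------------------------------------------------------------------
# trajectory I/O (multi-model PDB)

def _topology_template_atoms(topology: Topology) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    for i, a in enumerate(topology.atoms):
        res = topology.residues[a.residue_index]
        arr.chain_id[i] = "A" if res.chain == PROTEIN else "B"
        arr.res_id[i] = res.index
        arr.res_name[i] = res.name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = res.chain == LIGAND
    return arr


def write_trajectory(traj: PullingTrajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame).

    Frame times are stored in a leading ``REMARK 250 FRAME_TIMES_PS``
    block so the file round-trips without a sidecar table.
    """
    template = _topology_template_atoms(traj.topology)
    stack = struc.from_template(template, traj.coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    times_line = " ".join(f"{t:.6g}" for t in traj.times)
    with open(path, "w") as fh:
        fh.write(f"REMARK 250 FRAME_TIMES_PS {times_line}\n")
        fh.write("\n".join(pdb.lines) + "\n")


def _model_atom_counts(lines: list[str]) -> list[int]:
    counts, current, in_model = [], 0, False
    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model, current = True, 0
        elif rec.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            current += 1
    if not counts and current:
        counts = [current]          # single implicit model
    return counts


def read_trajectory(path, repeat_map: RepeatMap | None = None,
                    frame_spacing: float | None = None,
                    times=None) -> PullingTrajectory:
    """Read a multi-model PDB into a :class:`PullingTrajectory`.

    Frame times come from, in order of precedence: the explicit
    ``times`` argument, a ``REMARK 250 FRAME_TIMES_PS`` header, or
    uniform ``frame_spacing`` starting at 0.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    header_times = None
    for line in lines:
        if line.startswith("REMARK 250 FRAME_TIMES_PS"):
            header_times = np.array(
                [float(v) for v in line.split()[3:]], dtype=float)
            break

    counts = _model_atom_counts(lines)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise FormatError(
            f"model {bad + 1} has {counts[bad]} atoms but model 1 has "
            f"{counts[0]}")

    body = "\n".join(ln for ln in lines
                     if not ln.startswith("REMARK 250 FRAME_TIMES_PS"))
    pdb = PDBFile.read(io.StringIO(body))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):          # single model
        stack = struc.stack([stack])
    coords = stack.coord.astype(float)
    n_frames = coords.shape[0]

    # rebuild topology from the first model
    residues: list[Residue] = []
    atoms: list[Atom] = []
    res_key_to_idx: dict[tuple, int] = {}
    for i in range(stack.array_length()):
        chain = PROTEIN if stack.chain_id[i] == "A" else LIGAND
        key = (stack.chain_id[i], int(stack.res_id[i]))
        if key not in res_key_to_idx:
            rid = None
            if chain == PROTEIN and repeat_map is not None:
                rid = repeat_map.repeat_of_residue(int(stack.res_id[i]))
            res_key_to_idx[key] = len(residues)
            residues.append(Residue(index=int(stack.res_id[i]),
                                    name=str(stack.res_name[i]),
                                    repeat_id=rid, chain=chain))
        atoms.append(Atom(residue_index=res_key_to_idx[key],
                          name=str(stack.atom_name[i]),
                          element=str(stack.element[i])))
    topology = Topology(residues=residues, atoms=atoms)

    if repeat_map is not None:
        n_prot = sum(1 for r in residues if r.chain == PROTEIN)
        repeat_map.check_span(n_prot)

    if times is not None:
        times = np.asarray(times, dtype=float)
    elif header_times is not None:
        times = header_times
    elif frame_spacing is not None:
        times = np.arange(n_frames, dtype=float) * frame_spacing
    else:
        raise ConfigError("no frame times: pass times=, frame_spacing=, or "
                          "use a file with a FRAME_TIMES_PS header")
    if times.size != n_frames:
        raise DataError(f"{times.size} frame times for {n_frames} models")
    return PullingTrajectory(topology=topology, times=times, coords=coords)


# ---------------------------------------------------------------------------
# force-trace I/O (TSV with comment metadata)

_META_TYPES = {"True": True, "False": False}


def _parse_meta_value(text: str):
    if text in _META_TYPES:
        return _META_TYPES[text]
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def write_force_trace(trace: ForceTrace, path) -> None:
    """Write a force trace as TSV with ``# key=value`` metadata lines.

    Numbers are written with 12 significant digits, so a write→read
    round trip preserves values to ≲1e-9 relative error.
    """
    cols = {"time_ps": trace.time,
            "fx_pN": trace.force[:, 0], "fy_pN": trace.force[:, 1],
            "fz_pN": trace.force[:, 2],
            "ex_A": trace.end_to_end[:, 0], "ey_A": trace.end_to_end[:, 1],
            "ez_A": trace.end_to_end[:, 2]}
    if trace.anchors is not None:
        for r in range(trace.anchors.shape[1]):
            for k, ax in enumerate("xyz"):
                cols[f"anchor{r}_{ax}_A"] = trace.anchors[:, r, k]
    df = pd.DataFrame(cols)
    buf = io.StringIO()
    for key in sorted(trace.metadata):
        buf.write(f"# {key}={trace.metadata[key]}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_force_trace(path) -> ForceTrace:
    """Read a TSV/CSV force trace written by :func:`write_force_trace`."""
    metadata = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                metadata[key.strip()] = _parse_meta_value(val.strip())
        else:
            break
    sep = "\t" if "\t" in text.splitlines()[len(metadata)] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#")
    if "time_ps" not in df.columns:
        raise FormatError("force trace lacks a time_ps column")
    time = df["time_ps"].to_numpy()
    if np.any(np.diff(time) <= 0):
        raise DataError("time column is not strictly increasing")
    force = df[["fx_pN", "fy_pN", "fz_pN"]].to_numpy()
    e2e = df[["ex_A", "ey_A", "ez_A"]].to_numpy()
    anchor_cols = [c for c in df.columns if c.startswith("anchor")]
    anchors = None
    if anchor_cols:
        n_anchor = len(anchor_cols) // 3
        anchors = np.empty((len(df), n_anchor, 3))
        for r in range(n_anchor):
            for k, ax in enumerate("xyz"):
                anchors[:, r, k] = df[f"anchor{r}_{ax}_A"].to_numpy()
    return ForceTrace(time=time, force=force, end_to_end=e2e,
                      anchors=anchors, metadata=metadata)


# ---------------------------------------------------------------------------
# repeat-map I/O (JSON)

def write_repeat_map(rmap: RepeatMap, path) -> None:
    payload = {"repeats": [list(r) for r in rmap.repeats],
               "n_terminal_anchor": rmap.n_terminal_anchor,
               "c_terminal_anchor": rmap.c_terminal_anchor,
               "boundary_anchor": rmap.boundary_anchor,
               "regions": rmap.regions}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_repeat_map(path) -> RepeatMap:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return RepeatMap(
            repeats=[tuple(r) for r in payload["repeats"]],
            n_terminal_anchor=payload.get("n_terminal_anchor", "CA"),
            c_terminal_anchor=payload.get("c_terminal_anchor", "CA"),
            boundary_anchor=payload.get("boundary_anchor", "CA"),
            regions=payload.get("regions"))
    except KeyError as exc:
        raise ConfigError(f"repeat map missing key {exc}") from exc


# ---------------------------------------------------------------------------
# result writers

def write_table(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    """Deterministic TSV writer: fixed column order and precision."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


_ORDINALS = ["1st", "2nd", "3rd"] + [f"{i}th" for i in range(4, 21)]


def write_contingency_table(counts, row_labels, path) -> None:
    """Write an order-contingency table in the classic layout:

    a header of ordinal positions (1st, 2nd, ...) and one row per label,
    e.g. ``r7\\t28\\t0\\t0\\t0\\t0\\t0\\t0``.
    """
    counts = np.asarray(counts, dtype=int)
    n_pos = counts.shape[1]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(_ORDINALS[:n_pos]) + "\n")
        for label, row in zip(row_labels, counts):
            fh.write(str(label) + "\t" + "\t".join(str(int(v)) for v in row)
                     + "\n")


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, newline-terminated)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
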