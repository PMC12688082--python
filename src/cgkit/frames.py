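"""Trajectory frames: coordinates plus bead metadata.

A :class:`Frame` is one time point — per-bead coordinates in angstrom, an
orthorhombic box, and a pandas table of bead metadata (molecule id/name,
monomer resid/resname, bead name/type, size class, backbone/side-chain role,
charge, flags).  The metadata is what the analyses key on: peptide-level
clustering groups by molecule, M1-side-chain clustering by (molecule,
monomer).

Coordinate I/O: GRO files go through MDAnalysis (lossy for cgkit metadata —
GRO only stores residue/atom names); an internal JSON+TSV plain-text format
round-trips everything and is what the fixture generators emit.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .topology import CGTopology

__all__ = ["Frame", "frame_from_topologies", "read_frames", "write_frames",
           "write_gro", "read_gro"]

ATOM_COLUMNS = ["molid", "molname", "resid", "resname", "name", "type",
                "size_class", "role", "charge", "mass", "flags"]


@dataclass
class Frame:
    """One configuration of the system."""

    coords: np.ndarray                      # (N, 3) angstrom
    atoms: pd.DataFrame                     # columns ATOM_COLUMNS
    box: np.ndarray | None = None           # (3,) orthorhombic lengths, angstrom
    time_ps: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atoms) != len(self.coords):
            raise ValueError("atoms table and coordinates differ in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def total_charge(self) -> float:
        return float(self.atoms["charge"].sum())

    def select(self, mask) -> "Frame":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Frame(self.coords[idx],
                     self.atoms.iloc[idx].reset_index(drop=True),
                     None if self.box is None else self.box.copy(),
                     self.time_ps)

    def has_flag(self, flag: str) -> np.ndarray:
        return self.atoms["flags"].str.contains(flag, regex=False).to_numpy()

    def wrapped(self) -> np.ndarray:
        """Coordinates wrapped into [0, box) (copy); identity if no box."""
        if self.box is None:
            return self.coords.copy()
        return np.mod(self.coords, self.box)

    def concat(self, other: "Frame") -> "Frame":
        """Append another frame's beads, renumbering its molecule ids."""
        offset = (self.atoms["molid"].max() + 1) if len(self.atoms) else 0
        atoms = other.atoms.copy()
        atoms["molid"] = atoms["molid"] + offset
        return Frame(
            np.vstack([self.coords, other.coords]),
            pd.concat([self.atoms, atoms], ignore_index=True),
            self.box if self.box is not None else other.box,
            self.time_ps)


def _atoms_from_topology(top: CGTopology, molid: int) -> pd.DataFrame:
    rows = []
    for b in top.beads:
        rows.append({
            "molid": molid, "molname": top.name, "resid": b.resid,
            "resname": b.resname, "name": b.name, "type": b.type,
            "size_class": b.size_class, "role": b.role,
            "charge": b.charge, "mass": b.mass,
            "flags": ",".join(sorted(b.flags))})
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def frame_from_topologies(
    tops: list[CGTopology],
    coords: list[np.ndarray],
    box=None,
    time_ps: float = 0.0,
) -> Frame:
    """Assemble a frame from per-molecule topologies and coordinate blocks."""
    if len(tops) != len(coords):
        raise ValueError("one coordinate block per topology required")
    tables, blocks = [], []
    for molid, (top, xyz) in enumerate(zip(tops, coords)):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if len(xyz) != top.n_beads:
            raise ValueError(
                f"molecule {molid} ({top.name}): {len(xyz)} coordinates for "
                f"{top.n_beads} beads")
        tables.append(_atoms_from_topology(top, molid))
        blocks.append(xyz)
    if not tables:
        atoms = pd.DataFrame(columns=ATOM_COLUMNS)
        return Frame(np.zeros((0, 3)), atoms, box, time_ps)
    return Frame(np.vstack(blocks), pd.concat(tables, ignore_index=True),
                 box, time_ps)


# ---------------------------------------------------------------------------
# internal plain-text trajectory format
# ---------------------------------------------------------------------------

def write_frames(frames: list[Frame], path) -> None:
    """Write frames to the internal plain-text format (lossless)."""
    with open(path, "w") as fh:
        for fr in frames:
            header = {
                "n": fr.n_beads,
                "time_ps": fr.time_ps,
                "box": None if fr.box is None else fr.box.tolist(),
            }
            fh.write("#FRAME " + json.dumps(header) + "\n")
            buf = io.StringIO()
            table = fr.atoms.copy()
            table[["x", "y", "z"]] = fr.coords
            table.to_csv(buf, sep="\t", index=False)
            fh.write(buf.getvalue())
            fh.write("#END\n")


def read_frames(path) -> list[Frame]:
    frames = []
    with open(path) as fh:
        block, header = [], None
        for line in fh:
            if line.startswith("#FRAME"):
                header = json.loads(line[len("#FRAME"):])
                block = []
            elif line.startswith("#END"):
                table = pd.read_csv(io.StringIO("".join(block)), sep="\t",
                                    keep_default_na=False)
                coords = table[["x", "y", "z"]].to_numpy(dtype=float)
                atoms = table[ATOM_COLUMNS].copy()
                frames.append(Frame(
                    coords, atoms,
                    None if header["box"] is None else np.array(header["box"]),
                    float(header["time_ps"])))
            elif header is not None:
                block.append(line)
    return frames


# ---------------------------------------------------------------------------
# GRO via MDAnalysis
# ---------------------------------------------------------------------------

def _to_universe(frame: Frame):
    import MDAnalysis as mda

    n = frame.n_beads
    keys = list(zip(frame.atoms["molid"], frame.atoms["resid"]))
    res_keys = list(dict.fromkeys(keys))
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = [res_index[k] for k in keys]
    u = mda.Universe.empty(
        n_atoms=n, n_residues=max(len(res_keys), 1),
        atom_resindex=atom_resindex, trajectory=True)
    u.add_TopologyAttr("names", frame.atoms["name"].tolist())
    first = {}
    for k, rn in zip(keys, frame.atoms["resname"]):
        first.setdefault(k, rn)
    resnames = [first[k] for k in res_keys] or ["SYS"]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(range(1, max(len(res_keys), 1) + 1)))
    u.atoms.positions = frame.coords
    if frame.box is not None:
        u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    return u


def write_gro(frame: Frame, path) -> None:
    """Write one frame as a GRO coordinate file (via MDAnalysis)."""
    u = _to_universe(frame)
    u.atoms.write(str(path))


def read_gro(path) -> Frame:
    """Read a GRO file into a Frame.

    Only what GRO stores survives: names, residue ids/names, coordinates and
    box.  Molecule assignment, bead typing and flags default to placeholders;
    use the internal plain-text format for full-fidelity fixtures.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    n = len(u.atoms)
    atoms = pd.DataFrame({
        "molid": u.atoms.resids - 1,
        "molname": u.atoms.resnames,
        "resid": u.atoms.resids,
        "resname": u.atoms.resnames,
        "name": u.atoms.names,
        "type": [""] * n,
        "size_class": ["regular"] * n,
        "role": ["SC"] * n,
        "charge": np.zeros(n),
        "mass": np.full(n, 72.0),
        "flags": [""] * n,
    }, columns=ATOM_COLUMNS)
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float)
    return Frame(u.atoms.positions.astype(float), atoms, box)
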