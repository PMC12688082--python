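"""Simulation-system construction and run-parameter emission.

Builds initial configurations for the three simulation phases — unimer
self-assembly, cargo (DiI) loading, and protein-triggered disassembly — and
writes the run-parameter (MDP-dialect) files with the protocol settings:
10 fs timestep, neighbour list every 20 steps, 1.1 nm LJ and reaction-field
cutoffs with relative permittivity 15, 303 K Berendsen thermostat
(tau 0.5 ps), Parrinello-Rahman barostat at 1 bar (compressibility
4.5e-5 bar^-1, tau 4.0 ps), 5000-step steepest-descent minimisation, and
200 ps restrained equilibration (0.1 kcal/mol/A^2).

The module prepares MD inputs and never runs the MD engine; solvation is
bookkeeping (water bead count from free volume at CG water density, lattice
coordinates) since the engine equilibrates the solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.transform import Rotation

from . import analysis
from .frames import Frame, frame_from_topologies
from .topology import (CGTopology, assign_bonded_parameters,
                       build_polymer_topology, generate_chain_set)
from .units import CLASS_RADII, bond_k_to_kj_nm

__all__ = [
    "SystemSpec", "RunParameters", "emit_run_parameters", "write_mdp",
    "build_conformation", "place_unimers", "insert_cargo",
    "place_proteins_near_ligands", "solvation_counts", "water_lattice",
]

DEFAULT_MIN_SEP = 3.5          # angstrom, between beads of distinct molecules
DEFAULT_RETRIES = 10_000       # placement attempts per molecule
CG_WATER_DENSITY = 0.00835     # W beads per A^3 (4 waters per bead, bulk)
BEAD_VOLUME = 4.0 / 3.0 * math.pi * CLASS_RADII["regular"] ** 3


@dataclass
class SystemSpec:
    """Molecule inventory and placement constraints of one system."""

    box: np.ndarray                                  # (3,) angstrom
    molecule_counts: dict[str, int] = field(default_factory=dict)
    min_sep: float = DEFAULT_MIN_SEP
    ligand_window: tuple[float, float] = (5.0, 10.0)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box must be positive-definite")
        if any(c < 0 for c in self.molecule_counts.values()):
            raise ValueError("molecule counts must be >= 0")


# ---------------------------------------------------------------------------
# run parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunParameters:
    """Protocol settings for one simulation phase."""

    phase: str
    integrator: str
    nsteps: int
    timestep_fs: float | None = 10.0
    neighbor_update: int = 20
    lj_cutoff_nm: float = 1.1
    coulomb_cutoff_nm: float = 1.1
    electrostatics: str = "Reaction-Field"
    epsilon_r: float = 15.0
    temperature_K: float | None = 303.0
    thermostat: str = "berendsen"
    tau_t_ps: float = 0.5
    pressure_bar: float | None = 1.0
    barostat: str = "Parrinello-Rahman"
    compressibility_bar: float = 4.5e-5
    tau_p_ps: float = 4.0
    posres_fc_kcal_A2: float | None = None


def emit_run_parameters(phase: str,
                        nsteps: int | None = None
                        ) -> tuple[RunParameters, str]:
    """Run parameters plus MDP-dialect text for a protocol phase.

    Phases: ``minimize`` (5000 steepest-descent steps), ``equilibrate``
    (200 ps with 0.1 kcal/mol/A^2 positional restraints, no barostat) and
    ``production``.
    """
    if phase == "minimize":
        rp = RunParameters(
            phase=phase, integrator="steep", nsteps=nsteps or 5000,
            timestep_fs=None, temperature_K=None, pressure_bar=None)
    elif phase == "equilibrate":
        rp = RunParameters(
            phase=phase, integrator="md", nsteps=nsteps or 20_000,
            pressure_bar=None, posres_fc_kcal_A2=0.1)
    elif phase == "production":
        rp = RunParameters(
            phase=phase, integrator="md", nsteps=nsteps or 100_000_000)
    else:
        raise ValueError(f"unknown phase {phase!r}; expected minimize, "
                         "equilibrate or production")
    return rp, write_mdp(rp)


def write_mdp(rp: RunParameters) -> str:
    """Render run parameters as GROMACS MDP text (ps/nm/kJ units)."""
    lines = [f"; cgkit {rp.phase} parameters",
             f"integrator               = {rp.integrator}",
             f"nsteps                   = {rp.nsteps}"]
    if rp.integrator == "steep":
        lines += ["emtol                    = 100.0",
                  "emstep                   = 0.01"]
    if rp.timestep_fs is not None:
        lines.append(f"dt                       = {rp.timestep_fs / 1000:g}")
    lines += [
        "cutoff-scheme            = Verlet",
        f"nstlist                  = {rp.neighbor_update}",
        "vdw-type                 = Cut-off",
        "vdw-modifier             = Potential-shift-verlet",
        f"rvdw                     = {rp.lj_cutoff_nm:g}",
        f"coulombtype              = {rp.electrostatics}",
        f"rcoulomb                 = {rp.coulomb_cutoff_nm:g}",
        f"epsilon_r                = {rp.epsilon_r:g}",
    ]
    if rp.temperature_K is not None:
        lines += [
            f"tcoupl                   = {rp.thermostat}",
            "tc-grps                  = System",
            f"tau_t                    = {rp.tau_t_ps:g}",
            f"ref_t                    = {rp.temperature_K:g}",
        ]
    if rp.pressure_bar is not None:
        lines += [
            f"pcoupl                   = {rp.barostat}",
            "pcoupltype               = isotropic",
            f"tau_p                    = {rp.tau_p_ps:g}",
            f"ref_p                    = {rp.pressure_bar:g}",
            f"compressibility          = {rp.compressibility_bar:g}",
        ]
    else:
        lines.append("pcoupl                   = no")
    if rp.posres_fc_kcal_A2 is not None:
        k_kj_nm2 = bond_k_to_kj_nm(rp.posres_fc_kcal_A2)
        lines += ["define                   = -DPOSRES",
                  f"; position restraint fc  = {k_kj_nm2:g} kJ/mol/nm^2 "
                  f"({rp.posres_fc_kcal_A2:g} kcal/mol/A^2)"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# conformations and placement
# ---------------------------------------------------------------------------

def build_conformation(top: CGTopology, seed: int = 0,
                       fallback_bond: float = 3.5) -> np.ndarray:
    """Self-avoiding-ish random-walk coordinates for one molecule (angstrom).

    Beads are grown breadth-first over the bond graph at their bond lengths;
    directions are re-drawn a few times to avoid placing a bead within 2 A
    of an earlier one.  Good enough as an MD starting point — the engine
    relaxes it.
    """
    rng = np.random.default_rng(seed)
    n = top.n_beads
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    for b in top.bonds:
        length = b.length if b.length is not None else fallback_bond
        adj[b.i].append((b.j, length))
        adj[b.j].append((b.i, length))
    coords = np.full((n, 3), np.nan)
    coords[0] = 0.0
    queue, seen = [0], {0}
    while queue:
        cur = queue.pop(0)
        for nxt, length in adj[cur]:
            if nxt in seen:
                continue
            best, best_d = None, -1.0
            for _ in range(12):
                v = rng.normal(size=3)
                cand = coords[cur] + v / np.linalg.norm(v) * length
                placed = coords[list(seen)]
                dmin = float(np.min(np.linalg.norm(placed - cand, axis=1)))
                if dmin > 2.0:
                    best = cand
                    break
                if dmin > best_d:
                    best, best_d = cand, dmin
            coords[nxt] = best
            seen.add(nxt)
            queue.append(nxt)
    if np.isnan(coords).any():   # disconnected topology: drop remaining at org
        coords[np.isnan(coords[:, 0])] = rng.normal(
            scale=3.0, size=(int(np.isnan(coords[:, 0]).sum()), 3))
    return coords - coords.mean(axis=0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _min_image_dmin(pts: np.ndarray, tree: cKDTree | None,
                    box: np.ndarray) -> float:
    if tree is None:
        return np.inf
    wrapped = np.mod(pts, box)
    wrapped = np.where(wrapped >= box, 0.0, wrapped)
    d, _ = tree.query(wrapped)
    return float(np.min(d))


def _default_chain_tops(seed: int) -> list[CGTopology]:
    tops = []
    for i, chain in enumerate(generate_chain_set(4, seed=seed)):
        tops.append(assign_bonded_parameters(
            build_polymer_topology(chain)))
    return tops


def _ratio_counts(n: int, weights: tuple[int, ...]) -> list[int]:
    total = sum(weights)
    exact = [n * w / total for w in weights]
    counts = [int(math.floor(x)) for x in exact]
    rem = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: exact[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def place_unimers(
    n: int,
    box,
    topologies: list[CGTopology] | None = None,
    ratio: tuple[int, ...] = (2, 1, 1, 1),
    min_sep: float = DEFAULT_MIN_SEP,
    seed: int = 0,
    max_retries: int = DEFAULT_RETRIES,
) -> Frame:
    """Scatter ``n`` P1 unimers at random positions/orientations in the box.

    Chain identities are drawn from ``topologies`` (default: the balanced
    4-chain set) in the given ratio (2:1:1:1 by default); every
    inter-molecular bead distance is >= ``min_sep`` under periodic minimum
    image.  Raises if the packing cannot be realised within the retry budget.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    if np.any(box <= 0):
        raise ValueError("box must be positive-definite")
    if n < 0:
        raise ValueError("n must be >= 0")
    if topologies is None:
        topologies = _default_chain_tops(seed)
    counts = _ratio_counts(n, ratio[:len(topologies)])
    order = [i for i, c in enumerate(counts) for _ in range(c)]
    rng = np.random.default_rng(seed)

    n_beads_total = sum(topologies[i].n_beads for i in order)
    if n_beads_total * BEAD_VOLUME > 0.7 * float(np.prod(box)):
        raise ValueError(
            "packing infeasible: solute volume exceeds box capacity; "
            "use a larger box")

    placed_tops, placed_coords = [], []
    occupied = None
    tree = None
    for mol_i in order:
        top = topologies[mol_i]
        conf = build_conformation(top, seed=int(rng.integers(2**31)))
        ok = False
        for _ in range(max_retries):
            rot = _random_rotation(rng)
            com = rng.random(3) * box
            pts = conf @ rot.T + com
            if _min_image_dmin(pts, tree, box) >= min_sep:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place molecule {len(placed_tops) + 1}/{n} at "
                f"min_sep={min_sep} A after {max_retries} attempts; "
                "use a larger box")
        placed_tops.append(top)
        placed_coords.append(pts)
        block = np.mod(pts, box)
        block = np.where(block >= box, 0.0, block)
        occupied = block if occupied is None else np.vstack([occupied, block])
        tree = cKDTree(occupied, boxsize=box)
    return frame_from_topologies(placed_tops, placed_coords, box=box)


def _solute_mask(frame: Frame) -> np.ndarray:
    return ~frame.atoms["molname"].isin(["W", "ION", "NA", "CL"]).to_numpy()


def insert_cargo(
    frame: Frame,
    dii_top: CGTopology,
    n: int,
    seed: int = 0,
    min_sep: float = DEFAULT_MIN_SEP,
    max_retries: int = DEFAULT_RETRIES,
) -> Frame:
    """Insert ``n`` DiI molecules at random positions outside the aggregate.

    Placements keep every DiI bead at >= ``min_sep`` from existing beads and
    outside the convex region of the current aggregate (the stated initial
    condition: cargo starts in the bulk, not pre-embedded).
    """
    if n == 0:
        return frame
    if frame.box is None:
        raise ValueError("cargo insertion requires a periodic box")
    from .topology import dii_reference_coords

    rng = np.random.default_rng(seed)
    box = frame.box
    agg_mask = _solute_mask(frame)
    agg = frame.coords[agg_mask]
    hull = None
    if len(agg) >= 4:
        try:
            hull = Delaunay(agg)
        except Exception:
            hull = None
    conf = dii_reference_coords(dii_top)
    conf = conf - conf.mean(axis=0)
    out = frame
    wrapped = np.mod(frame.coords, box)
    wrapped = np.where(wrapped >= box, 0.0, wrapped)
    occupied = wrapped
    tree = cKDTree(occupied, boxsize=box) if len(occupied) else None
    for k in range(n):
        ok = False
        for _ in range(max_retries):
            rot = _random_rotation(rng)
            com = rng.random(3) * box
            pts = conf @ rot.T + com
            if tree is not None and _min_image_dmin(pts, tree, box) < min_sep:
                continue
            if hull is not None and np.any(hull.find_simplex(pts) >= 0):
                continue
            ok = True
            break
        if not ok:
            raise ValueError(
                f"could not insert cargo molecule {k + 1}/{n}; "
                "use a larger box")
        out = out.concat(frame_from_topologies([dii_top], [pts]))
        block = np.mod(pts, box)
        block = np.where(block >= box, 0.0, block)
        occupied = np.vstack([occupied, block]) if len(occupied) else block
        tree = cKDTree(occupied, boxsize=box)
    return out


def place_proteins_near_ligands(
    frame: Frame,
    protein_top: CGTopology,
    protein_coords: np.ndarray,
    n: int,
    window: tuple[float, float] = (5.0, 10.0),
    min_sep: float = DEFAULT_MIN_SEP,
    sasa_threshold: float = 10.0,
    seed: int = 0,
    max_retries: int = 2000,
) -> Frame:
    """Dock ``n`` protein copies with their Zn bead near exposed M3 ligands.

    An M3 terminal ligand bead counts as exposed when its SASA exceeds
    ``sasa_threshold`` (A^2).  Each placed protein's Zn bead ends within
    ``window`` (5-10 A) of a distinct exposed ligand bead, body oriented
    away from the aggregate, with no bead closer than ``min_sep`` to the
    assembly.  Raises if fewer exposed ligands than ``n`` exist or a
    placement cannot be realised.
    """
    if n == 0:
        return frame
    protein_coords = np.asarray(protein_coords, dtype=float)
    zn_candidates = protein_top.indices_with_flag("zn") or [
        i for i, b in enumerate(protein_top.beads) if b.name == "ZN"]
    if not zn_candidates:
        raise ValueError("protein topology has no Zn bead")
    zn = zn_candidates[0]
    ligand_idx = np.flatnonzero(frame.has_flag("ligand_site"))
    if len(ligand_idx) == 0:
        raise ValueError("frame exposes no ligand-site beads")
    areas = analysis.sasa_per_bead(frame, ligand_idx)
    exposed = ligand_idx[areas > sasa_threshold]
    if len(exposed) < n:
        raise ValueError(
            f"only {len(exposed)} exposed ligand beads (SASA > "
            f"{sasa_threshold} A^2) for {n} proteins")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(exposed, size=n, replace=False)

    agg_com = frame.coords[_solute_mask(frame)].mean(axis=0)
    body = protein_coords - protein_coords[zn]
    body_axis = -body.mean(axis=0)
    body_axis = body_axis / (np.linalg.norm(body_axis) + 1e-12)

    out = frame
    box = frame.box
    occupied = frame.coords if box is None else np.where(
        np.mod(frame.coords, box) >= box, 0.0, np.mod(frame.coords, box))
    tree = cKDTree(occupied, boxsize=box)
    for lig in chosen:
        lig_pos = frame.coords[lig]
        outward = lig_pos - agg_com
        outward = outward / (np.linalg.norm(outward) + 1e-12)
        ok = False
        for _ in range(max_retries):
            d = rng.uniform(*window)
            # point the protein body away from the aggregate, random spin
            align, _ = Rotation.align_vectors(
                outward[None, :], -body_axis[None, :])
            spin = Rotation.from_rotvec(
                outward * rng.uniform(0, 2 * np.pi))
            pts = body @ (spin * align).as_matrix().T + lig_pos + outward * d
            dmin = _min_image_dmin(pts, tree, box) if box is not None \
                else float(tree.query(pts)[0].min())
            if dmin >= min_sep:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place protein near ligand bead {int(lig)} "
                f"after {max_retries} attempts")
        out = out.concat(frame_from_topologies([protein_top], [pts]))
        block = pts if box is None else np.where(
            np.mod(pts, box) >= box, 0.0, np.mod(pts, box))
        occupied = np.vstack([occupied, block])
        tree = cKDTree(occupied, boxsize=box)
    return out


# ---------------------------------------------------------------------------
# solvation / ion bookkeeping
# ---------------------------------------------------------------------------

def solvation_counts(frame: Frame) -> dict[str, int]:
    """Water-bead and counter-ion counts for a frame (bookkeeping only).

    Water fills the free volume at bulk CG density (one W bead per four
    waters); counter ions neutralise the total solute charge so the emitted
    system is net neutral.
    """
    if frame.box is None:
        raise ValueError("solvation requires a periodic box")
    free = float(np.prod(frame.box)) - frame.n_beads * BEAD_VOLUME
    n_w = max(int(free * CG_WATER_DENSITY), 0)
    q = frame.total_charge
    n_na = int(round(max(-q, 0.0)))
    n_cl = int(round(max(q, 0.0)))
    return {"W": n_w, "NA": n_na, "CL": n_cl}


def water_lattice(frame: Frame, n: int,
                  min_sep: float = DEFAULT_MIN_SEP) -> np.ndarray:
    """Up to ``n`` lattice positions for water beads avoiding the solute."""
    box = frame.box
    spacing = (float(np.prod(box)) / max(n, 1)) ** (1.0 / 3.0)
    grids = [np.arange(spacing / 2, b, spacing) for b in box]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    if frame.n_beads:
        wrapped = np.mod(frame.coords, box)
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
        d, _ = tree.query(pts)
        pts = pts[d >= min_sep]
    return pts[:n]
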