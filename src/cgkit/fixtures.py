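"""Synthetic bead configurations and pseudo-trajectories.

Geometric stand-ins for the structural motifs the assembly model produces —
layered micelles, hierarchical multicore aggregates, dispersed unimers,
buried/exposed cargo, stepwise-disassembly series — so every analysis
operation can be exercised without running microsecond MD.  Fixtures use the
real bead typing from :mod:`cgkit.topology`, so SASA radii and clustering
entity definitions resolve without special-casing, but they are geometric
constructions, not thermodynamically realistic configurations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import fibonacci_sphere
from .frames import ATOM_COLUMNS, Frame, frame_from_topologies
from .topology import (build_dii_topology, build_polymer_topology,
                       dii_reference_coords, generate_chain_set, ChainSpec)

__all__ = [
    "make_dispersed", "make_micelle", "make_multicore_aggregate",
    "make_disassembly_series", "make_shape_cloud", "make_cargo_states",
]

DEFAULT_RADII = (15.0, 22.0, 27.0)   # core / backbone-shell / M3 surface, A


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _in_ball(rng, n, r_lo, r_hi):
    """n points uniform in the spherical shell [r_lo, r_hi]."""
    u = rng.random(n)
    r = (r_lo ** 3 + u * (r_hi ** 3 - r_lo ** 3)) ** (1.0 / 3.0)
    return _unit(rng, n) * r[:, None]


def _fit_core_radius(n_groups: int, spacing: float = 4.0) -> float:
    """Smallest core radius whose grid holds n_groups M1 side-chain sites."""
    r = 10.0
    while True:
        try:
            _grid_in_ball(r, spacing, n_groups)
            return r
        except ValueError:
            r += 1.0


def _grid_in_ball(radius: float, spacing: float, n: int) -> np.ndarray:
    """First n cubic-grid points inside a ball, nearest-to-centre first."""
    k = int(np.ceil(radius / spacing))
    axes = np.arange(-k, k + 1) * spacing
    pts = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    pts = pts[r <= radius - 0.5 * spacing]
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order]
    if len(pts) < n:
        raise ValueError(
            f"core radius {radius} A holds only {len(pts)} grid sites at "
            f"{spacing} A spacing; {n} requested")
    return pts[:n]


def _cloud_frame(coords, molname, resname, name, btype, size_class,
                 role="SC", start_molid=0, group_size=None) -> Frame:
    """Frame from a raw bead cloud with uniform tagging.

    ``group_size`` beads share one (molid, resid) so they form one entity;
    by default every bead is its own residue of one molecule.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if group_size:
        resid = np.repeat(np.arange(n // group_size) + 1, group_size)
    else:
        resid = np.arange(n) + 1
    atoms = pd.DataFrame({
        "molid": np.full(n, start_molid), "molname": molname,
        "resid": resid, "resname": resname, "name": name, "type": btype,
        "size_class": size_class, "role": role,
        "charge": np.zeros(n), "mass": np.full(n, 72.0),
        "flags": [""] * n}, columns=ATOM_COLUMNS)
    return Frame(coords, atoms)


def _shift_to_box(frame: Frame, pad: float = 30.0) -> Frame:
    """Translate all beads positive and set a box with a periodic margin."""
    lo = frame.coords.min(axis=0)
    hi = frame.coords.max(axis=0)
    coords = frame.coords - lo + pad
    box = hi - lo + 2 * pad
    return Frame(coords, frame.atoms, box, frame.time_ps)


# ---------------------------------------------------------------------------
# dispersed unimers
# ---------------------------------------------------------------------------

def make_dispersed(n_polymers: int = 20, spacing: float = 40.0,
                   seed: int = 0) -> Frame:
    """Fully dispersed unimer state: all inter-chain distances > eps.

    Chains are collapsed to compact blobs on a cubic lattice with centres
    ``spacing`` apart (default 40 A), so no two chains approach within the
    8 A clustering threshold: the zero-cluster reference state.
    """
    rng = np.random.default_rng(seed)
    chains = generate_chain_set(n_polymers, seed=seed)
    k = int(np.ceil(n_polymers ** (1.0 / 3.0)))
    tops, blocks = [], []
    sites = [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]
    for c, chain in enumerate(chains):
        top = build_polymer_topology(chain)
        blob = _in_ball(rng, top.n_beads, 0.0, 6.0)
        centre = np.array(sites[c], dtype=float) * spacing + spacing / 2
        tops.append(top)
        blocks.append(blob + centre)
    fr = frame_from_topologies(tops, blocks, box=np.full(3, k * spacing))
    return fr


# ---------------------------------------------------------------------------
# layered micelle
# ---------------------------------------------------------------------------

def make_micelle(
    n_polymers: int = 10,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    seed: int = 0,
    center: np.ndarray | None = None,
    compositions: list[ChainSpec] | None = None,
    m1_grid: bool = False,
    with_box: bool = True,
    time_ps: float = 0.0,
) -> Frame:
    """Three-layer micelle: M1 core, backbone/M2 shell, M3 surface.

    By construction, all M1 side-chain beads lie within the core radius, the
    backbone beads in the middle shell, M2 side chains through core+shell,
    and M3 side chains on the outer surface with the benzene-sulfonamide and
    terminal ligand beads outermost.  ``m1_grid`` places M1 side-chain
    groups on a 4 A grid (guaranteed mutual proximity) instead of uniformly.
    """
    r_core, r_shell, r_surf = radii
    if not (0 < r_core < r_shell < r_surf):
        raise ValueError("layer radii must be strictly increasing")
    rng = np.random.default_rng(seed)
    chains = compositions or generate_chain_set(n_polymers, seed=seed)
    if len(chains) < n_polymers:
        chains = [chains[i % len(chains)] for i in range(n_polymers)]
    tops = [build_polymer_topology(c) for c in chains[:n_polymers]]

    n_m1_groups = sum(
        1 for t in tops for b in t.beads
        if b.resname == "M1" and b.role == "SC" and b.name == "EST")
    grid = iter(_grid_in_ball(r_core, 4.0, n_m1_groups)) if m1_grid else None

    blocks = []
    for top in tops:
        xyz = np.zeros((top.n_beads, 3))
        m3_dirs = {}
        i = 0
        while i < top.n_beads:
            b = top.beads[i]
            if b.resname == "M1" and b.role == "SC":
                if m1_grid and b.name == "EST":
                    g = next(grid)
                    xyz[i] = g + (0.0, 0.0, -0.8)
                    xyz[i + 1] = g + (0.0, 0.0, 0.8)
                    i += 2
                    continue
                xyz[i] = _in_ball(rng, 1, 0.0, r_core)[0]
            elif b.role == "BB":
                xyz[i] = _in_ball(rng, 1, r_core, r_shell)[0]
            elif b.resname == "M2":
                xyz[i] = _in_ball(rng, 1, 0.0, r_shell)[0]
            elif b.resname == "M3":
                if "benzene_sulfonamide" in b.flags or "ligand_site" in b.flags:
                    u = m3_dirs.setdefault(b.resid, _unit(rng)[0])
                    r = r_surf if "benzene_sulfonamide" in b.flags \
                        else r_surf + 3.0
                    xyz[i] = u * r
                else:
                    xyz[i] = _in_ball(rng, 1, r_shell, r_surf)[0]
            else:
                xyz[i] = _in_ball(rng, 1, 0.0, r_surf)[0]
            i += 1
        blocks.append(xyz)
    if center is not None:
        blocks = [b + np.asarray(center, dtype=float) for b in blocks]
    fr = frame_from_topologies(tops, blocks, time_ps=time_ps)
    return _shift_to_box(fr) if with_box else fr


# ---------------------------------------------------------------------------
# multicore aggregate
# ---------------------------------------------------------------------------

def _bridge_pair(frame: Frame, ca: np.ndarray, cb: np.ndarray,
                 mol_a: int, mol_b: int) -> None:
    """Move one M2 bead of a molecule from each micelle to the interface,
    guaranteeing peptide-level contact between the two micelles."""
    at = frame.atoms
    mid = 0.5 * (ca + cb)
    for mol, off in ((mol_a, -1.5), (mol_b, 1.5)):
        cand = np.flatnonzero(
            (at["molid"] == mol) & (at["resname"] == "M2")
            & (at["role"] == "SC"))
        frame.coords[cand[0]] = mid + np.array([off, 0.0, 0.0])


def make_multicore_aggregate(
    n_micelles: int = 6,
    n_polymers_per: int = 10,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    spacing: float = 44.0,
    core_sizes: list[int] | None = None,
    bridged: bool = False,
    seed: int = 0,
    with_box: bool = True,
    time_ps: float = 0.0,
) -> Frame:
    """Hierarchical aggregate: several micelles with touching shells.

    Micelle centres sit ``spacing`` apart on a line, chosen so hydrophilic
    shells interpenetrate (one peptide-level cluster, enforced by explicit
    interface bridges) while hydrophobic cores stay separated by more than
    the 8 A clustering threshold.  ``core_sizes`` requests exact numbers of
    M1 side-chain groups per core (grid-packed); ``bridged`` additionally
    lays M1 groups across the interfaces so neighbouring cores merge.
    """
    r_core = radii[0]
    if core_sizes is not None:
        n_micelles = len(core_sizes)
        # grow the layers so the largest grid-packed core fits
        need = max(_fit_core_radius(max(core_sizes)), r_core)
        if need > r_core:
            radii = (need, need + (radii[1] - radii[0]),
                     need + (radii[2] - radii[0]))
            r_core = need
        spacing = max(spacing, 2 * r_core + 14.0)
    if spacing <= 2 * r_core + 8.0:
        raise ValueError(
            "spacing too small: cores would merge (needs > 2*r_core + 8 A)")
    rng = np.random.default_rng(seed)
    centres = [np.array([i * spacing, 0.0, 0.0]) for i in range(n_micelles)]
    frame = None
    first_mol = []
    for m, centre in enumerate(centres):
        if core_sizes is not None:
            b = core_sizes[m] % 5
            a = (core_sizes[m] - 6 * b) // 5
            if a < 0 or a * 5 + b * 6 != core_sizes[m]:
                raise ValueError(
                    f"core size {core_sizes[m]} not representable with "
                    "chains of 5 or 6 M1 monomers")
            comps = [ChainSpec(("M1",) * 5 + ("M2",) * 4 + ("M3",))] * a \
                + [ChainSpec(("M1",) * 6 + ("M2",) * 4 + ("M3",))] * b
            sub = make_micelle(
                len(comps), radii, seed=int(rng.integers(2**31)),
                center=centre, compositions=comps, m1_grid=True,
                with_box=False)
        else:
            sub = make_micelle(
                n_polymers_per, radii, seed=int(rng.integers(2**31)),
                center=centre, with_box=False)
        first_mol.append(0 if frame is None else frame.atoms["molid"].max() + 1)
        frame = sub if frame is None else frame.concat(sub)
    for m in range(n_micelles - 1):
        _bridge_pair(frame, centres[m], centres[m + 1],
                     first_mol[m], first_mol[m + 1])
    if bridged:
        extra = []
        for m in range(n_micelles - 1):
            lo = centres[m] + np.array([r_core - 2.0, 0, 0])
            hi = centres[m + 1] - np.array([r_core - 2.0, 0, 0])
            n_steps = int(np.ceil(np.linalg.norm(hi - lo) / 4.0)) + 1
            for t in np.linspace(0.0, 1.0, n_steps):
                g = lo + t * (hi - lo)
                extra.append(g + (0, 0, -0.8))
                extra.append(g + (0, 0, 0.8))
        bridge = _cloud_frame(np.array(extra), "P1", "M1", "ALK", "C2",
                              "small", group_size=2)
        frame = frame.concat(bridge)
    frame.time_ps = time_ps
    return _shift_to_box(frame) if with_box else frame


# ---------------------------------------------------------------------------
# stepwise disassembly pseudo-trajectory
# ---------------------------------------------------------------------------

def make_disassembly_series(
    steps: list[int] = (80, 60, 40, 20),
    micelle_size: int = 20,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    seed: int = 0,
    with_proteins: bool = False,
    frame_interval_ps: float = 1000.0,
) -> list[Frame]:
    """Pseudo-trajectory in which whole micelles detach stepwise.

    Frame ``t`` holds one aggregate of ``steps[t]`` polymers (as
    ``steps[t]/micelle_size`` bridged micelles) plus the previously detached
    micelles far away, so the largest peptide cluster per frame is exactly
    ``steps``.  With ``with_proteins`` a Zn bead is attached outside each of
    a mutually well-separated subset of surface ligand beads at a random
    distance in the 5-10 A binding window.
    """
    steps = list(steps)
    if any(s % micelle_size for s in steps):
        raise ValueError("every step must be a multiple of micelle_size")
    if any(b > a for a, b in zip(steps, steps[1:])):
        raise ValueError("steps must be non-increasing")
    rng = np.random.default_rng(seed)
    n_total = steps[0] // micelle_size
    frames = []
    for t, s in enumerate(steps):
        n_agg = s // micelle_size
        fr = make_multicore_aggregate(
            n_micelles=n_agg, n_polymers_per=micelle_size, radii=radii,
            seed=seed + t, with_box=False)
        for k in range(n_total - n_agg):
            det = make_micelle(
                micelle_size, radii, seed=int(rng.integers(2**31)),
                center=np.array([0.0, 150.0 * (k + 1), 0.0]),
                with_box=False)
            fr = fr.concat(det)
        if with_proteins:
            fr = _attach_zn(fr, rng)
        fr.time_ps = t * frame_interval_ps
        frames.append(_shift_to_box(fr, pad=60.0))
    return frames


def _attach_zn(frame: Frame, rng) -> Frame:
    """One Zn bead 5-10 A outside each of a >=12 A-separated ligand subset."""
    lig = np.flatnonzero(frame.has_flag("ligand_site"))
    chosen = []
    for i in lig:
        if all(np.linalg.norm(frame.coords[i] - frame.coords[j]) >= 12.0
               for j in chosen):
            chosen.append(i)
    p1 = frame.atoms["molname"].to_numpy() == "P1"
    pts = []
    for i in chosen:
        # outward from the local micelle, not the whole (multi-aggregate) frame
        near = p1 & (np.linalg.norm(
            frame.coords - frame.coords[i], axis=1) < 40.0)
        local_com = frame.coords[near].mean(axis=0)
        u = frame.coords[i] - local_com
        u = u / (np.linalg.norm(u) + 1e-12)
        pts.append(frame.coords[i] + u * rng.uniform(5.0, 10.0))
    zn = _cloud_frame(np.array(pts), "PROT", "ZN", "ZN", "SD", "tiny")
    return frame.concat(zn)


# ---------------------------------------------------------------------------
# shape archetypes
# ---------------------------------------------------------------------------

def make_shape_cloud(
    archetype: str,
    n: int = 400,
    axis_ratios: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Point clouds with exactly controlled gyration-eigenvalue structure.

    A random Gaussian cloud is whitened so its gyration tensor is exactly
    isotropic, then scaled along the principal axes; the eigenvalue
    degeneracies (prolate 1:1:3, oblate 1:3:3, line, sphere) are therefore
    exact to machine precision, not just statistical.
    """
    rng = np.random.default_rng(seed)
    if archetype == "line":
        t = np.sort(rng.random(n)) * 30.0
        u = _unit(rng)[0]
        return np.outer(t, u)
    ratios = {
        "sphere": (1.0, 1.0, 1.0),
        "prolate": (1.0, 1.0, 3.0),
        "oblate": (1.0, 3.0, 3.0),
    }.get(archetype, axis_ratios)
    if ratios is None:
        raise ValueError(f"unknown shape archetype {archetype!r}")
    if axis_ratios is not None:
        ratios = axis_ratios
    x = rng.normal(size=(max(n, 4), 3))
    x -= x.mean(axis=0)
    s = x.T @ x
    lam, vec = np.linalg.eigh(s)
    white = x @ vec / np.sqrt(lam)
    return white * np.asarray(ratios, dtype=float)


# ---------------------------------------------------------------------------
# cargo exposure states
# ---------------------------------------------------------------------------

def _filler_ball(center: np.ndarray, radius: float, avoid: np.ndarray,
                 spacing: float = 2.5, clearance: float = 2.6) -> np.ndarray:
    """Close-packed filler bead positions inside a ball, avoiding a solute."""
    k = int(np.ceil(radius / spacing))
    axes = np.arange(-k, k + 1) * spacing
    pts = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"),
                   axis=-1).reshape(-1, 3) + center
    pts = pts[np.linalg.norm(pts - center, axis=1) <= radius]
    if len(avoid):
        d = np.linalg.norm(pts[:, None, :] - avoid[None, :, :], axis=2)
        pts = pts[d.min(axis=1) >= clearance]
    return pts


def make_cargo_states(state: str, seed: int = 0) -> Frame:
    """DiI embedding fixtures: ``buried`` or ``exposed`` headgroup.

    ``buried``: the whole dye is enclosed in a close-packed shell of
    hydrophobic M1-type beads, leaving no probe-accessible surface on the
    headgroup (the fully encapsulated state).  ``exposed``: the headgroup
    faces open solvent while the alkyl tails stay buried in a small M1
    cluster (the post-disassembly state, tails insoluble).
    """
    rng = np.random.default_rng(seed)
    top = build_dii_topology()
    xyz = dii_reference_coords(top)
    dii = frame_from_topologies([top], [xyz])
    head = dii.has_flag("headgroup")
    tail = dii.has_flag("tail")
    if state == "buried":
        centre = xyz.mean(axis=0)
        r = np.linalg.norm(xyz - centre, axis=1).max() + 7.0
        filler = _filler_ball(centre, r, xyz)
    elif state == "exposed":
        tail_pts = xyz[tail]
        centre = tail_pts.mean(axis=0)
        r = np.linalg.norm(tail_pts - centre, axis=1).max() + 7.0
        filler = _filler_ball(centre, r, xyz)
        # keep the head face open: drop filler close to any head bead
        d_head = np.linalg.norm(
            filler[:, None, :] - xyz[head][None, :, :], axis=2).min(axis=1)
        filler = filler[d_head >= 5.5]
    else:
        raise ValueError(f"unknown cargo state {state!r}")
    filler += rng.normal(scale=0.05, size=filler.shape)
    cloud = _cloud_frame(filler, "P1", "M1", "EST", "P2", "regular",
                         group_size=2 if len(filler) % 2 == 0 else None)
    return dii.concat(cloud)
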