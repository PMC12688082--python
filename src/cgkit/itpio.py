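"""GROMACS ITP/TOP molecule-definition text, written from and read back into
:class:`~cgkit.topology.CGTopology`.

Internal units (angstrom, kcal/mol) are converted to the GROMACS dialect
(nm, kJ/mol) on write and back on read.  Metadata the ITP format cannot hold
(size class, heavy-atom count, role, flags) is carried in structured trailing
comments (``;@ key=value ...``) so a write/read cycle is lossless; the files
remain valid GROMACS input.
"""

from __future__ import annotations

import math

from .topology import Angle, Bead, Bond, CGTopology, Dihedral
from .units import (ang_to_nm, bond_k_from_kj_nm, bond_k_to_kj_nm,
                    kcal_to_kj, kj_to_kcal, nm_to_ang)

__all__ = ["write_topology", "read_topology", "write_system_top"]


def write_topology(top: CGTopology, nrexcl: int = 1) -> str:
    """Render a parameterized topology as ITP molecule-definition text.

    Refuses to write if any bonded term still has an empty parameter slot.
    """
    missing = top.missing_terms()
    if missing:
        raise ValueError(
            "cannot write topology with unparameterized terms: "
            + "; ".join(missing))
    top.validate()
    lines = [
        f"; cgkit molecule definition: {top.name}",
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{top.name}  {nrexcl}",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  resid  atom  cgnr  charge  mass",
    ]
    for n, b in enumerate(top.beads, start=1):
        meta = (f";@ size={b.size_class} heavy={b.heavy_atoms} "
                f"role={b.role}")
        if b.flags:
            meta += " flags=" + ",".join(sorted(b.flags))
        lines.append(
            f"{n:5d} {b.type:>6s} {b.resid:5d} {b.resname:>5s} "
            f"{b.name:>5s} {n:5d} {b.charge:8.3f} {b.mass:8.3f}  {meta}")
    if top.bonds:
        lines += ["", "[ bonds ]", ";  i  j  funct  b0(nm)  k(kJ/mol/nm2)"]
        for b in top.bonds:
            meta = ";@ ring=1" if b.ring else ""
            lines.append(
                f"{b.i + 1:5d} {b.j + 1:5d}  1  {ang_to_nm(b.length):.6f} "
                f"{bond_k_to_kj_nm(b.k):.4f}  {meta}".rstrip())
    if top.angles:
        lines += ["", "[ angles ]", ";  i  j  k  funct  theta0  k(kJ/mol)"]
        for a in top.angles:
            lines.append(
                f"{a.i + 1:5d} {a.j + 1:5d} {a.k_idx + 1:5d}  2  "
                f"{a.theta:.4f} {kcal_to_kj(a.k):.4f}")
    if top.dihedrals:
        lines += ["", "[ dihedrals ]",
                  ";  i  j  k  l  funct  phi0  k(kJ/mol)"]
        for d in top.dihedrals:
            funct = 2 if d.improper else 1
            lines.append(
                f"{d.i + 1:5d} {d.j + 1:5d} {d.k_idx + 1:5d} "
                f"{d.l + 1:5d}  {funct}  {d.phi:.4f} {kcal_to_kj(d.k):.4f}")
    if top.exclusions:
        lines += ["", "[ exclusions ]"]
        for i, j in top.exclusions:
            lines.append(f"{i + 1:5d} {j + 1:5d}")
    return "\n".join(lines) + "\n"


def _parse_meta(comment: str) -> dict[str, str]:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_topology(text: str) -> CGTopology:
    """Parse ITP molecule-definition text written by :func:`write_topology`."""
    section = None
    top = CGTopology(name="")
    for raw in text.splitlines():
        meta = {}
        if ";@" in raw:
            line, _, tail = raw.partition(";@")
            meta = _parse_meta(tail)
        else:
            line = raw.partition(";")[0]
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        parts = line.split()
        if section == "moleculetype":
            top.name = parts[0]
        elif section == "atoms":
            (_, btype, resnr, resname, aname, _, charge, mass) = parts[:8]
            top.beads.append(Bead(
                name=aname, type=btype,
                size_class=meta.get("size", "regular"),
                charge=float(charge),
                heavy_atoms=int(meta.get("heavy", 0)),
                resid=int(resnr), resname=resname,
                role=meta.get("role", "SC"), mass=float(mass),
                flags=frozenset(
                    meta["flags"].split(",")) if "flags" in meta
                else frozenset()))
        elif section == "bonds":
            i, j, _, b0, k = parts[:5]
            top.bonds.append(Bond(
                int(i) - 1, int(j) - 1, length=nm_to_ang(float(b0)),
                k=bond_k_from_kj_nm(float(k)),
                ring=meta.get("ring") == "1"))
        elif section == "angles":
            i, j, k_, funct, th, kk = parts[:6]
            top.angles.append(Angle(
                int(i) - 1, int(j) - 1, int(k_) - 1,
                theta=float(th), k=kj_to_kcal(float(kk))))
        elif section == "dihedrals":
            i, j, k_, l, funct, phi, kk = parts[:7]
            top.dihedrals.append(Dihedral(
                int(i) - 1, int(j) - 1, int(k_) - 1, int(l) - 1,
                phi=float(phi), k=kj_to_kcal(float(kk)),
                improper=funct == "2"))
        elif section == "exclusions":
            top.exclusions.append((int(parts[0]) - 1, int(parts[1]) - 1))
    top.validate()
    return top


def write_system_top(
    molecule_counts: dict[str, int],
    includes: list[str],
    system_name: str = "cgkit system",
) -> str:
    """Render a GROMACS system-level .top file referencing molecule ITPs."""
    lines = [f'#include "{p}"' for p in includes]
    lines += ["", "[ system ]", system_name, "", "[ molecules ]",
              "; name  count"]
    for name, count in molecule_counts.items():
        if count < 0:
            raise ValueError(f"negative molecule count for {name}")
        if count:
            lines.append(f"{name}  {count}")
    return "\n".join(lines) + "\n"


def topologies_equal(a: CGTopology, b: CGTopology, tol: float = 1e-6) -> bool:
    """Structural equality of two topologies within a numeric tolerance."""
    if a.name != b.name or a.n_beads != b.n_beads:
        return False
    for x, y in zip(a.beads, b.beads):
        if (x.name, x.type, x.resid, x.resname, x.role, x.size_class,
                x.heavy_atoms, x.flags) != (
                y.name, y.type, y.resid, y.resname, y.role, y.size_class,
                y.heavy_atoms, y.flags):
            return False
        if not (math.isclose(x.charge, y.charge, abs_tol=tol)
                and math.isclose(x.mass, y.mass, abs_tol=1e-3)):
            return False
    if len(a.bonds) != len(b.bonds) or len(a.angles) != len(b.angles) \
            or len(a.dihedrals) != len(b.dihedrals):
        return False
    for x, y in zip(a.bonds, b.bonds):
        if (x.i, x.j, x.ring) != (y.i, y.j, y.ring):
            return False
        if not (math.isclose(x.length, y.length, abs_tol=1e-4)
                and math.isclose(x.k, y.k, rel_tol=1e-4)):
            return False
    for x, y in zip(a.angles, b.angles):
        if (x.i, x.j, x.k_idx) != (y.i, y.j, y.k_idx):
            return False
        if not (math.isclose(x.theta, y.theta, abs_tol=1e-3)
                and math.isclose(x.k, y.k, rel_tol=1e-4)):
            return False
    for x, y in zip(a.dihedrals, b.dihedrals):
        if (x.i, x.j, x.k_idx, x.l, x.improper) != (
                y.i, y.j, y.k_idx, y.l, y.improper):
            return False
        if not (math.isclose(x.phi, y.phi, abs_tol=1e-3)
                and math.isclose(x.k, y.k, rel_tol=1e-4)):
            return False
    return a.exclusions == b.exclusions
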