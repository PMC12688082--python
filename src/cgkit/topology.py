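"""Coarse-grained (Martini-3-style) models of the P1 copolypeptide and the DiI dye.

The P1 polymer is a random copolymer of three glutamic-acid-derived monomers:

* **M1** — hydrophobic ester side chain (drives micelle-core formation),
* **M2** — hydrophilic oligo(ethylene-glycol) side chain,
* **M3** — OEG side chain terminated by a benzene-sulfonamide ligand that is
  specifically recognised by the Zn site of carbonic anhydrase II.

Each monomer maps heavy atoms onto Martini beads at the conventional
4:1 (regular), 3:1 (small) and 2:1 (tiny) ratios, with one documented
exception: the M3 secondary-amide linker bead absorbs six heavy atoms so the
downstream OEG segment keeps its own beads.

Two bead-typing variants are provided.  The *nonstandard* variant uses a few
deliberately more polar types (P3 for the M3 amide, TN6d for the
benzene-sulfonamide ring bead and for the conjugated DiI linker/first tail
beads); the *strict_standard* variant replaces exactly those types with the
standard Martini 3 choices and nothing else.

The DiI carbocyanine head carries its +1 formal charge as two +0.5 partial
charges, one on each indolenine nitrogen bead, reflecting the resonant charge
distribution.  The figure-level bead reading shipped here is: per indolenine
half, three TC5 benzene beads, one SC3 gem-dimethyl bead and one SQ2 (+0.5)
C=N bead; a single conjugated-bridge bead joins the halves; each alkyl tail is
five beads (a conjugated first bead followed by four C1 beads).
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .units import CLASS_MAPPING, CLASS_MASSES

__all__ = [
    "Bead",
    "Bond",
    "Angle",
    "Dihedral",
    "CGTopology",
    "ChainBounds",
    "ChainSpec",
    "ModelVariant",
    "NONSTANDARD",
    "STRICT_STANDARD",
    "BALANCED_COMPOSITIONS",
    "generate_chain_set",
    "build_polymer_topology",
    "build_dii_topology",
    "assign_bonded_parameters",
    "dii_reference_coords",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class Bead:
    """One CG interaction site."""

    name: str
    type: str
    size_class: str              # regular | small | tiny
    charge: float
    heavy_atoms: int
    resid: int = 1               # monomer index within the molecule
    resname: str = ""            # M1 | M2 | M3 | DII | ...
    role: str = "SC"             # BB (backbone) | SC (side chain)
    mass: float | None = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.mass is None:
            self.mass = CLASS_MASSES[self.size_class]


@dataclass
class Bond:
    i: int
    j: int
    length: float | None = None      # angstrom
    k: float | None = None           # kcal/mol/A^2
    ring: bool = False

    @property
    def parameterized(self) -> bool:
        return self.length is not None and self.k is not None


@dataclass
class Angle:
    i: int
    j: int
    k_idx: int
    theta: float | None = None       # degrees
    k: float | None = None           # kcal/mol/rad^2

    @property
    def parameterized(self) -> bool:
        return self.theta is not None and self.k is not None


@dataclass
class Dihedral:
    i: int
    j: int
    k_idx: int
    l: int
    phi: float | None = None         # degrees
    k: float | None = None           # kcal/mol
    improper: bool = True

    @property
    def parameterized(self) -> bool:
        return self.phi is not None and self.k is not None


@dataclass
class CGTopology:
    """CG model of one molecule: beads plus bonded terms."""

    name: str
    beads: list[Bead] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    angles: list[Angle] = field(default_factory=list)
    dihedrals: list[Dihedral] = field(default_factory=list)
    exclusions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def total_charge(self) -> float:
        return float(sum(b.charge for b in self.beads))

    def indices_with_flag(self, flag: str) -> list[int]:
        return [i for i, b in enumerate(self.beads) if flag in b.flags]

    @property
    def parameterized(self) -> bool:
        return not self.missing_terms()

    def missing_terms(self) -> list[str]:
        out = []
        for n, term in enumerate(self.bonds):
            if not term.parameterized:
                out.append(f"bond {n} ({term.i}-{term.j})")
        for n, term in enumerate(self.angles):
            if not term.parameterized:
                out.append(f"angle {n} ({term.i}-{term.j}-{term.k_idx})")
        for n, term in enumerate(self.dihedrals):
            if not term.parameterized:
                out.append(
                    f"dihedral {n} ({term.i}-{term.j}-{term.k_idx}-{term.l})")
        return out

    def validate(self) -> None:
        n = self.n_beads
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond {b.i}-{b.j} references missing bead")
        for a in self.angles:
            for idx in (a.i, a.j, a.k_idx):
                if not 0 <= idx < n:
                    raise ValueError(f"angle references missing bead {idx}")
        for d in self.dihedrals:
            for idx in (d.i, d.j, d.k_idx, d.l):
                if not 0 <= idx < n:
                    raise ValueError(f"dihedral references missing bead {idx}")

    def copy(self) -> "CGTopology":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# model variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelVariant:
    """Bead-typing variant; the two variants differ only in ``overrides``.

    ``overrides`` maps (resname, bead name) -> replacement Martini type
    relative to the nonstandard (canonical) typing.
    """

    tag: str
    overrides: dict = field(default_factory=dict, hash=False, compare=False)

    def bead_type(self, resname: str, bead_name: str, base_type: str) -> str:
        return self.overrides.get((resname, bead_name), base_type)


#: Canonical model: the small set of deliberately-more-polar bead choices.
NONSTANDARD = ModelVariant("nonstandard", {})

#: Strictly standard Martini 3 typing; replaces exactly the documented sites.
STRICT_STANDARD = ModelVariant(
    "strict_standard",
    {
        ("M3", "AMD"): "P2",    # secondary amide: guideline P2, not P3
        ("M3", "ARS"): "TC5",   # benzene-sulfonamide ring bead: aromatic TC5
        ("DII", "BRG"): "TC1",  # conjugated bridge: TC1, not TN6d
        ("DII", "T1A"): "TC1",  # first tail beads: TC1, not TN6d
        ("DII", "T1B"): "TC1",
    },
)

VARIANTS = {v.tag: v for v in (NONSTANDARD, STRICT_STANDARD)}


def get_variant(tag: str | ModelVariant) -> ModelVariant:
    if isinstance(tag, ModelVariant):
        return tag
    try:
        return VARIANTS[tag]
    except KeyError:
        raise ValueError(
            f"unknown model variant {tag!r}; choose from {sorted(VARIANTS)}"
        ) from None


# ---------------------------------------------------------------------------
# monomer templates
# ---------------------------------------------------------------------------
# Each entry: list of (name, type, size_class, charge, heavy_atoms, role,
# flags), followed by intra-monomer bonds/angles given as name pairs/triples.
# Bead 0 of every monomer is the backbone bead; the disordered polypeptide
# backbone is uniformly coil-type P2.

_MONOMER_BEADS = {
    "M1": [
        ("BB", "P2", "regular", 0.0, 4, "BB", ()),
        ("EST", "P2", "regular", 0.0, 4, "SC", ()),       # ester linker
        ("ALK", "C2", "small", 0.0, 3, "SC", ()),         # short alkyl
    ],
    "M2": [
        ("BB", "P2", "regular", 0.0, 4, "BB", ()),
        ("EST", "P2", "regular", 0.0, 4, "SC", ()),
        ("EO1", "SN3r", "small", 0.0, 3, "SC", ()),       # OEG
        ("EO2", "SN3r", "small", 0.0, 3, "SC", ()),
    ],
    "M3": [
        ("BB", "P2", "regular", 0.0, 4, "BB", ()),
        # secondary amide linker; 6:1 mapping preserves the OEG segment
        ("AMD", "P3", "regular", 0.0, 6, "SC", ()),
        ("EO1", "SN3r", "small", 0.0, 3, "SC", ()),
        ("EO2", "SN3r", "small", 0.0, 3, "SC", ()),
        ("AMN", "TN4a", "tiny", 0.0, 2, "SC", ()),        # split-amide N bead
        ("AR1", "TC5", "tiny", 0.0, 2, "SC", ()),
        ("AR2", "TC5", "tiny", 0.0, 2, "SC", ()),
        # carbonyl-conjugated benzene-sulfonamide ring bead
        ("ARS", "TN6d", "tiny", 0.0, 2, "SC", ("benzene_sulfonamide",)),
        # terminal sulfonamide: single highly polar bead; the bCA-II binding site
        ("SFN", "P6", "regular", 0.0, 4, "SC", ("ligand_site",)),
    ],
}

_MONOMER_BONDS = {
    "M1": [("BB", "EST", False), ("EST", "ALK", False)],
    "M2": [("BB", "EST", False), ("EST", "EO1", False), ("EO1", "EO2", False)],
    "M3": [
        ("BB", "AMD", False), ("AMD", "EO1", False), ("EO1", "EO2", False),
        ("EO2", "AMN", False), ("AMN", "AR1", False),
        ("AR1", "AR2", True), ("AR2", "ARS", True), ("ARS", "AR1", True),
        ("ARS", "SFN", False),
    ],
}

_MONOMER_ANGLES = {
    "M1": [("BB", "EST", "ALK")],
    "M2": [("BB", "EST", "EO1"), ("EST", "EO1", "EO2")],
    "M3": [("BB", "AMD", "EO1"), ("AMD", "EO1", "EO2"),
           ("EO1", "EO2", "AMN"), ("EO2", "AMN", "AR1"),
           ("AR2", "ARS", "SFN")],
}

MONOMER_LABELS = ("M1", "M2", "M3")


def monomer_heavy_atom_check(label: str) -> None:
    """Verify the template's heavy-atom counts against the size-class mapping."""
    for name, _, size, _, heavy, _, _ in _MONOMER_BEADS[label]:
        expect = CLASS_MAPPING[size]
        if heavy != expect and not (label == "M3" and name == "AMD"):
            raise ValueError(
                f"{label}.{name}: {heavy} heavy atoms inconsistent with "
                f"{size} ({expect}:1) mapping")


# ---------------------------------------------------------------------------
# chain generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainBounds:
    """Per-chain composition bounds (inclusive)."""

    n_m1: tuple[int, int] = (5, 6)
    n_m2: tuple[int, int] = (4, 4)
    n_m3: tuple[int, int] = (1, 2)

    def validate(self) -> None:
        for attr in ("n_m1", "n_m2", "n_m3"):
            lo, hi = getattr(self, attr)
            if lo < 0 or hi < lo:
                raise ValueError(
                    f"infeasible composition bound {attr}=({lo}, {hi})")


DEFAULT_BOUNDS = ChainBounds()

#: Default composition-balanced 4-chain set (mean length 11 monomers).
BALANCED_COMPOSITIONS = ((5, 4, 1), (6, 4, 2), (5, 4, 2), (6, 4, 1))


@dataclass(frozen=True)
class ChainSpec:
    """Monomer sequence of a single P1 chain."""

    sequence: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {m: self.sequence.count(m) for m in MONOMER_LABELS}

    @property
    def n_monomers(self) -> int:
        return len(self.sequence)

    def validate(self, bounds: ChainBounds = DEFAULT_BOUNDS) -> None:
        unknown = set(self.sequence) - set(MONOMER_LABELS)
        if unknown:
            raise ValueError(f"unknown monomer label(s): {sorted(unknown)}")
        c = self.counts
        for label, attr in (("M1", "n_m1"), ("M2", "n_m2"), ("M3", "n_m3")):
            lo, hi = getattr(bounds, attr)
            if not lo <= c[label] <= hi:
                raise ValueError(
                    f"chain has {c[label]} {label} monomers, outside "
                    f"bound [{lo}, {hi}]")


def generate_chain_set(
    n_chains: int = 4,
    bounds: ChainBounds = DEFAULT_BOUNDS,
    seed: int = 0,
    balanced: bool = True,
) -> list[ChainSpec]:
    """Draw random-copolymer chain sequences under the composition bounds.

    With ``balanced=True`` (the default) compositions cycle through the
    balanced set ``{(5,4,1), (6,4,2), (5,4,2), (6,4,1)}`` so a default
    4-chain set averages 11 monomers per chain; otherwise per-chain counts
    are drawn uniformly within the bounds.  Monomer order is a uniform
    permutation under the seed in both modes.
    """
    if n_chains < 0:
        raise ValueError("n_chains must be >= 0")
    bounds.validate()
    rng = np.random.default_rng(seed)
    chains = []
    for i in range(n_chains):
        if balanced and bounds == DEFAULT_BOUNDS:
            n1, n2, n3 = BALANCED_COMPOSITIONS[i % len(BALANCED_COMPOSITIONS)]
        else:
            n1 = int(rng.integers(bounds.n_m1[0], bounds.n_m1[1] + 1))
            n2 = int(rng.integers(bounds.n_m2[0], bounds.n_m2[1] + 1))
            n3 = int(rng.integers(bounds.n_m3[0], bounds.n_m3[1] + 1))
        seq = ["M1"] * n1 + ["M2"] * n2 + ["M3"] * n3
        order = rng.permutation(len(seq))
        chain = ChainSpec(tuple(seq[k] for k in order))
        chain.validate(bounds)
        chains.append(chain)
    return chains


# ---------------------------------------------------------------------------
# topology builders
# ---------------------------------------------------------------------------

def build_polymer_topology(
    chain: ChainSpec,
    variant: str | ModelVariant = NONSTANDARD,
    name: str = "P1",
) -> CGTopology:
    """Assemble the CG topology of one P1 chain from monomer templates.

    The backbone beads form a linear path; each monomer's side chain branches
    off its backbone bead.  The M3 terminal sulfonamide bead carries the
    ``ligand_site`` flag marking the specific bCA-II binding site.
    """
    var = get_variant(variant)
    chain.validate(ChainBounds((0, 10**9), (0, 10**9), (0, 10**9)))
    top = CGTopology(name=name)
    bb_indices = []
    for resid, label in enumerate(chain.sequence, start=1):
        if label not in _MONOMER_BEADS:
            raise ValueError(f"unknown monomer label {label!r}")
        local = {}
        for (bname, btype, size, q, heavy, role, flags) in _MONOMER_BEADS[label]:
            idx = top.n_beads
            local[bname] = idx
            top.beads.append(Bead(
                name=bname, type=var.bead_type(label, bname, btype),
                size_class=size, charge=q, heavy_atoms=heavy,
                resid=resid, resname=label, role=role,
                flags=frozenset(flags)))
        bb_indices.append(local["BB"])
        for a, b, ring in _MONOMER_BONDS[label]:
            top.bonds.append(Bond(local[a], local[b], ring=ring))
        for a, b, c in _MONOMER_ANGLES[label]:
            top.angles.append(Angle(local[a], local[b], local[c]))
    # backbone path
    for a, b in itertools.pairwise(bb_indices):
        top.bonds.append(Bond(a, b))
    for a, b, c in zip(bb_indices, bb_indices[1:], bb_indices[2:]):
        top.angles.append(Angle(a, b, c))
    top.validate()
    return top


def build_dii_topology(variant: str | ModelVariant = NONSTANDARD) -> CGTopology:
    """CG topology of the DiI carbocyanine dye.

    The +1 formal charge of the conjugated head is split into two +0.5
    partial charges on the SQ2 nitrogen beads; all head beads carry the
    ``headgroup`` flag (the SASA-tracked group) and tail beads the ``tail``
    flag.  The two alkyl tails are symmetric (five beads each).
    """
    var = get_variant(variant)
    top = CGTopology(name="DII")

    def add(name, btype, size, q, heavy, flags):
        top.beads.append(Bead(
            name=name, type=var.bead_type("DII", name, btype),
            size_class=size, charge=q, heavy_atoms=heavy,
            resid=1, resname="DII", role="SC", flags=frozenset(flags)))
        return top.n_beads - 1

    idx = {}
    for half in ("A", "B"):
        for ring_bead in ("R1", "R2", "R3"):
            idx[ring_bead + half] = add(
                ring_bead + half, "TC5", "tiny", 0.0, 2, ("headgroup",))
        idx["R4" + half] = add("R4" + half, "SC3", "small", 0.0, 3,
                               ("headgroup",))
        idx["NQ" + half] = add("NQ" + half, "SQ2", "small", 0.5, 3,
                               ("headgroup",))
    idx["BRG"] = add("BRG", "TN6d", "tiny", 0.0, 2, ("headgroup",))
    for half in ("A", "B"):
        idx["T1" + half] = add("T1" + half, "TN6d", "tiny", 0.0, 2, ("tail",))
        for t in range(2, 6):
            idx[f"T{t}{half}"] = add(f"T{t}{half}", "C1", "regular", 0.0, 4,
                                     ("tail",))

    def bond(a, b, ring=False):
        top.bonds.append(Bond(idx[a], idx[b], ring=ring))

    for h in ("A", "B"):
        bond("R1" + h, "R2" + h, ring=True)
        bond("R2" + h, "R3" + h, ring=True)
        bond("R3" + h, "R1" + h, ring=True)
        bond("R3" + h, "R4" + h, ring=True)
        bond("R4" + h, "NQ" + h, ring=True)
        bond("NQ" + h, "R1" + h, ring=True)
        bond("NQ" + h, "T1" + h)
        for t in range(1, 5):
            bond(f"T{t}{h}", f"T{t + 1}{h}")
    bond("NQA", "BRG")
    bond("BRG", "NQB")
    top.angles.append(Angle(idx["NQA"], idx["BRG"], idx["NQB"]))
    for h in ("A", "B"):
        for t in range(1, 4):
            top.angles.append(
                Angle(idx[f"T{t}{h}"], idx[f"T{t + 1}{h}"], idx[f"T{t + 2}{h}"]))
    # keep the conjugated bridge planar
    top.dihedrals.append(
        Dihedral(idx["R4A"], idx["NQA"], idx["NQB"], idx["R4B"],
                 improper=True))
    top.validate()
    return top


# ---------------------------------------------------------------------------
# bonded-parameter assignment
# ---------------------------------------------------------------------------
# Default bond lengths by size-class pair (angstrom) and harmonic force
# constants (kcal/mol/A^2), derived from idealized CG geometry and Martini
# analog groups.  These stand in for distances measured on energy-minimized
# atomistic structures; callers may override per-bond via reference geometry.

DEFAULT_BOND_LENGTHS = {
    ("regular", "regular"): 3.9,
    ("regular", "small"): 3.6,
    ("small", "small"): 3.3,
    ("regular", "tiny"): 3.4,
    ("small", "tiny"): 3.1,
    ("tiny", "tiny"): 2.9,
}
DEFAULT_BOND_K = 2.99          # ~1250 kJ/mol/nm^2
RING_BOND_K = 11.95            # ~5000 kJ/mol/nm^2, rigid aromatic frames
DEFAULT_ANGLE = (150.0, 5.98)  # degrees, kcal/mol/rad^2 (~25 kJ)
DEFAULT_DIHEDRAL = (180.0, 11.95)


def _class_pair(top: CGTopology, bond: Bond) -> tuple[str, str]:
    a = top.beads[bond.i].size_class
    b = top.beads[bond.j].size_class
    return tuple(sorted((a, b)))


def assign_bonded_parameters(
    top: CGTopology,
    reference_geometry: dict[tuple[int, int], float] | np.ndarray | None = None,
) -> CGTopology:
    """Fill every empty bonded-parameter slot of ``top`` (returns a copy).

    Bond lengths come, in order of preference, from an explicit reference
    distance (a ``{(i, j): length}`` table or an ``(n, 3)`` coordinate array
    from which bonded distances are measured), then from the shipped
    size-class default table.  Angle and dihedral parameters default to their
    analog-group values.  A bond with neither a reference distance nor a
    table default raises, naming the offending term.
    """
    out = top.copy()
    ref: dict[tuple[int, int], float] = {}
    if reference_geometry is not None:
        if isinstance(reference_geometry, dict):
            for (i, j), d in reference_geometry.items():
                ref[(min(i, j), max(i, j))] = float(d)
        else:
            coords = np.asarray(reference_geometry, dtype=float)
            if coords.shape != (top.n_beads, 3):
                raise ValueError(
                    f"reference coordinates shape {coords.shape} does not "
                    f"match bead count {top.n_beads}")
            for b in out.bonds:
                d = float(np.linalg.norm(coords[b.i] - coords[b.j]))
                ref[(min(b.i, b.j), max(b.i, b.j))] = d

    missing = []
    for n, b in enumerate(out.bonds):
        if b.length is None:
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in ref:
                b.length = ref[key]
            else:
                pair = _class_pair(out, b)
                if pair not in DEFAULT_BOND_LENGTHS:
                    missing.append(f"bond {n} ({b.i}-{b.j}, classes {pair})")
                    continue
                b.length = DEFAULT_BOND_LENGTHS[pair]
        if b.k is None:
            b.k = RING_BOND_K if b.ring else DEFAULT_BOND_K
    if missing:
        raise ValueError(
            "no default or reference distance for: " + "; ".join(missing))

    for a in out.angles:
        if a.theta is None:
            a.theta = DEFAULT_ANGLE[0]
        if a.k is None:
            a.k = DEFAULT_ANGLE[1]
    for d in out.dihedrals:
        if d.phi is None:
            d.phi = DEFAULT_DIHEDRAL[0]
        if d.k is None:
            d.k = DEFAULT_DIHEDRAL[1]
    return out


# ---------------------------------------------------------------------------
# reference geometry for DiI (idealized, for SASA and placement)
# ---------------------------------------------------------------------------

def dii_reference_coords(top: CGTopology | None = None) -> np.ndarray:
    """Idealized 3D coordinates for the DiI template (angstrom).

    The conjugated head is laid out planar — two indolenine rings bridged
    through the central bead — with the two alkyl tails extended away from
    the head on the same side, mimicking the membrane-dye geometry.
    """
    if top is None:
        top = build_dii_topology()
    names = [b.name for b in top.beads]
    pos = {}
    r = 2.9  # tiny-bead ring bond length
    for half, sgn in (("A", -1.0), ("B", 1.0)):
        cx = sgn * 4.6  # ring-centre offset from bridge
        # 5-ring bead (NQ) sits toward the bridge, benzene ring away from it
        pos["NQ" + half] = np.array([cx - sgn * 2.2, 1.2, 0.0])
        pos["R4" + half] = np.array([cx - sgn * 1.4, -1.8, 0.9])
        pos["R1" + half] = np.array([cx + sgn * 0.8, 1.6, 0.0])
        pos["R2" + half] = np.array([cx + sgn * 2.8, 0.4, 0.0])
        pos["R3" + half] = np.array([cx + sgn * 1.9, -1.7, 0.0])
        # tail from the nitrogen bead, extended in -z
        t0 = pos["NQ" + half] + np.array([0.0, 0.8, -2.8])
        for t in range(1, 6):
            step = 3.1 if t == 1 else 3.6
            pos[f"T{t}{half}"] = t0 + np.array(
                [sgn * 0.4 * t, 0.3 * t, -step * (t - 1) - 0.0])
        _ = r
    pos["BRG"] = np.array([0.0, 1.8, 0.0])
    return np.array([pos[n] for n in names])
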