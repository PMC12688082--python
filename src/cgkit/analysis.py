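"""Trajectory analyses for CG polymer nanoassemblies.

Implements the analysis suite used to characterise self-assembly, cargo
loading and protein-triggered disassembly:

* entity-level DBSCAN aggregation clustering (eps 8 A, min_samples 5, with
  the minimum bead-bead distance between entities as the metric, under
  periodic minimum image),
* cylindrical density profiles across the aggregate centre of mass
  (6 A diameter, 0.5 A bins, trailing-window averaged),
* gyration-tensor shape metrics: the tensor
  ``S_ab = sum_i (r_a,i - r_a,com)(r_b,i - r_b,com)`` with eigenvalues
  ``l1 <= l2 <= l3``, asphericity
  ``a = [(l2-l1)^2 + (l3-l1)^2 + (l3-l2)^2] / [2 (l1+l2+l3)^2]`` and
  prolateness
  ``p = (2l1-l2-l3)(2l2-l1-l3)(2l3-l1-l2) / [2 (l1^2+l2^2+l3^2
  - l1 l2 - l1 l3 - l2 l3)^(3/2)]``
  (a in [0, 1]; p = +1 perfectly prolate, -1 fully oblate, defined as 0 for
  a degenerate all-equal spectrum),
* solvent-accessible surface area of CG bead groups (Shrake-Rupley sphere
  sampling), used to track cargo-headgroup exposure,
* micelle-core size histograms from M1-side-chain clustering.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN
from sklearn.exceptions import EfficiencyWarning
from sklearn.neighbors import sort_graph_by_row_values

from .frames import Frame
from .units import CLASS_RADII

__all__ = [
    "ClusterParams", "ClusterResult", "GyrationTensor", "ShapeParams",
    "DensityProfile", "cluster_entities", "cluster_timeseries",
    "micelle_core_sizes", "cylinder_density_profile", "gyration_shape",
    "bead_sasa", "sasa_per_bead", "fibonacci_sphere",
]

NOISE = -1


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterParams:
    """Aggregation-clustering parameters."""

    eps: float = 8.0              # angstrom
    min_samples: int = 5
    entity: str = "peptide"       # "peptide" | "m1_sidechain"

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.entity not in ("peptide", "m1_sidechain"):
            raise ValueError(f"unknown entity definition {self.entity!r}")


@dataclass
class ClusterResult:
    labels: np.ndarray            # per entity; NOISE (-1) for unassigned
    entity_keys: list             # identity of each entity
    entity_members: list          # bead index arrays, parallel to labels

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != NOISE]))

    @property
    def sizes(self) -> dict[int, int]:
        return dict(Counter(int(l) for l in self.labels if l != NOISE))

    @property
    def largest(self) -> int:
        s = self.sizes
        return max(s.values()) if s else 0


def entities_from_frame(frame: Frame, entity: str) -> tuple[list, list]:
    """Entity membership: (keys, bead-index arrays) for an entity definition.

    ``peptide``: one entity per P1 molecule (all of its beads).
    ``m1_sidechain``: one entity per M1 monomer's side-chain bead group.
    """
    at = frame.atoms
    if entity == "peptide":
        mask = at["molname"] == "P1"
        groups = at[mask].groupby("molid", sort=True).indices
        keys = sorted(groups)
        return keys, [np.sort(at.index[mask].to_numpy()[groups[k]])
                      for k in keys]
    mask = (at["resname"] == "M1") & (at["role"] == "SC")
    sub = at[mask]
    grouped = sub.groupby(["molid", "resid"], sort=True)
    keys, members = [], []
    for key, idx in grouped.indices.items():
        keys.append(key)
        members.append(np.sort(sub.index.to_numpy()[idx]))
    return keys, members


def _entity_min_distance_graph(
    frame: Frame, members: list[np.ndarray], eps: float,
) -> sparse.csr_matrix:
    """Sparse entity-entity graph of minimum bead-bead distances <= eps."""
    n_ent = len(members)
    all_idx = np.concatenate(members)
    entity_of = np.concatenate(
        [np.full(len(m), e) for e, m in enumerate(members)])
    pts = frame.coords[all_idx]
    if frame.box is not None:
        pts = np.mod(pts, frame.box)
        # guard against coordinates exactly on the upper box face
        pts = np.where(pts >= frame.box, 0.0, pts)
        tree = cKDTree(pts, boxsize=frame.box)
    else:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    rows, cols, vals = [], [], []
    if len(pairs):
        ea, eb = entity_of[pairs[:, 0]], entity_of[pairs[:, 1]]
        inter = ea != eb
        if inter.any():
            d = pts[pairs[inter, 0]] - pts[pairs[inter, 1]]
            if frame.box is not None:
                d -= frame.box * np.round(d / frame.box)
            dist = np.linalg.norm(d, axis=1)
            key = np.minimum(ea[inter], eb[inter]) * n_ent \
                + np.maximum(ea[inter], eb[inter])
            order = np.lexsort((dist, key))
            key_s, dist_s = key[order], dist[order]
            first = np.ones(len(key_s), dtype=bool)
            first[1:] = key_s[1:] != key_s[:-1]
            for k, dmin in zip(key_s[first], dist_s[first]):
                i, j = divmod(int(k), n_ent)
                dmin = max(float(dmin), 1e-9)
                rows += [i, j]
                cols += [j, i]
                vals += [dmin, dmin]
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_ent, n_ent))


def cluster_entities(frame: Frame, params: ClusterParams | None = None
                     ) -> ClusterResult:
    """DBSCAN aggregation clustering of one frame.

    Entities (whole peptides or M1 side-chain groups) are the samples; the
    metric is the minimum bead-bead distance between two entities under
    periodic minimum image.  Entities in no dense neighbourhood are noise
    (label -1); a fully dispersed frame therefore has zero clusters.
    """
    params = params or ClusterParams()
    if frame.n_beads == 0:
        raise ValueError("cannot cluster an empty frame")
    keys, members = entities_from_frame(frame, params.entity)
    if not members:
        raise ValueError(
            f"frame contains no {params.entity!r} entities")
    graph = _entity_min_distance_graph(frame, members, params.eps)
    if graph.nnz == 0:
        # no entity pair within eps: every entity is its own neighbourhood
        if params.min_samples <= 1:
            labels = np.arange(len(members))
        else:
            labels = np.full(len(members), NOISE)
        return ClusterResult(labels=labels, entity_keys=keys,
                             entity_members=members)
    graph = sort_graph_by_row_values(graph, warn_when_not_sorted=False)
    with warnings.catch_warnings():
        # sklearn's sparse-precomputed path re-sorts after inserting the
        # diagonal and warns about it; harmless here
        warnings.simplefilter("ignore", category=EfficiencyWarning)
        labels = DBSCAN(eps=params.eps, min_samples=params.min_samples,
                        metric="precomputed").fit_predict(graph)
    return ClusterResult(labels=labels, entity_keys=keys,
                         entity_members=members)


def cluster_timeseries(frames: list[Frame],
                       params: ClusterParams | None = None) -> pd.DataFrame:
    """Per-frame cluster statistics: count, largest size, all sizes."""
    if not frames:
        raise ValueError("empty trajectory")
    params = params or ClusterParams()
    rows = []
    for fr in frames:
        res = cluster_entities(fr, params)
        rows.append({
            "time_ps": fr.time_ps,
            "n_clusters": res.n_clusters,
            "largest": res.largest,
            "sizes": tuple(sorted(res.sizes.values(), reverse=True)),
        })
    return pd.DataFrame(rows)


def micelle_core_sizes(frame: Frame,
                       params: ClusterParams | None = None) -> dict[int, int]:
    """Histogram of micelle-core sizes (M1 side-chain groups per core)."""
    if params is None:
        params = ClusterParams(entity="m1_sidechain")
    elif params.entity != "m1_sidechain":
        params = ClusterParams(params.eps, params.min_samples, "m1_sidechain")
    res = cluster_entities(frame, params)
    return dict(Counter(res.sizes.values()))


# ---------------------------------------------------------------------------
# shape metrics
# ---------------------------------------------------------------------------

@dataclass
class GyrationTensor:
    matrix: np.ndarray            # 3x3, A^2 (summed, unweighted)
    eigenvalues: np.ndarray       # ascending, l1 <= l2 <= l3
    n_beads: int
    centroid: np.ndarray


@dataclass
class ShapeParams:
    asphericity: float            # in [0, 1]
    prolateness: float            # in [-1, 1]; 0 for degenerate spectra
    degenerate: bool = False


def gyration_shape(coords: np.ndarray
                   ) -> tuple[GyrationTensor, ShapeParams]:
    """Gyration tensor and shape descriptors of a bead selection.

    The tensor is the unweighted second-moment sum about the centroid; the
    asphericity and prolateness depend only on eigenvalue ratios so the
    missing 1/N normalisation is immaterial.  For a spherically degenerate
    spectrum (all eigenvalues equal) the prolateness expression is 0/0 and is
    returned as 0 with ``degenerate=True``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) < 2:
        raise ValueError("shape analysis needs at least 2 points")
    com = coords.mean(axis=0)
    d = coords - com
    s_mat = d.T @ d
    lam = np.linalg.eigvalsh(s_mat)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all points coincident; shape undefined")
    l1, l2, l3 = lam
    aspher = ((l2 - l1) ** 2 + (l3 - l1) ** 2 + (l3 - l2) ** 2) \
        / (2.0 * total ** 2)
    m = l1 * l1 + l2 * l2 + l3 * l3 - l1 * l2 - l1 * l3 - l2 * l3
    if m <= 1e-12 * total ** 2:
        shape = ShapeParams(float(aspher), 0.0, degenerate=True)
    else:
        num = (2 * l1 - l2 - l3) * (2 * l2 - l1 - l3) * (2 * l3 - l1 - l2)
        prol = num / (2.0 * m ** 1.5)
        shape = ShapeParams(float(aspher), float(np.clip(prol, -1.0, 1.0)))
    return GyrationTensor(s_mat, lam, len(coords), com), shape


# ---------------------------------------------------------------------------
# cylindrical density profile
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    bin_centers: np.ndarray       # angstrom, relative to aggregate COM
    counts: dict[str, np.ndarray]  # per-group mean bead count per bin
    diameter: float
    bin_width: float
    axis: int
    n_frames: int

    def as_frame(self) -> pd.DataFrame:
        data = {"position": self.bin_centers}
        data.update(self.counts)
        return pd.DataFrame(data)


def cylinder_density_profile(
    frames: list[Frame],
    groups: dict[str, object],
    diameter: float = 6.0,
    bin_width: float = 0.5,
    axis: int = 0,
    window_ns: float | None = 50.0,
    com_selection=None,
) -> DensityProfile:
    """Bead-count profile along a cylinder through the aggregate COM.

    Per frame, the centre of mass of the aggregate (by default all P1 and
    DII beads) defines a cylinder of the given diameter aligned with
    ``axis``; beads of each group inside the cylinder are histogrammed along
    the axis in ``bin_width`` bins and the histograms averaged over the
    trailing ``window_ns`` of the trajectory (all frames if timestamps do
    not span the window).  Group selectors are callables mapping a Frame to
    a boolean mask.
    """
    if not frames:
        raise ValueError("empty trajectory window")
    if window_ns is not None:
        t_end = frames[-1].time_ps
        frames = [f for f in frames
                  if f.time_ps >= t_end - window_ns * 1000.0] or frames
    if com_selection is None:
        def com_selection(fr):
            return fr.atoms["molname"].isin(["P1", "DII"]).to_numpy()
    radius = diameter / 2.0
    radial_axes = [a for a in range(3) if a != axis]

    # fixed symmetric bin edges wide enough for every frame
    half = 0.0
    for fr in frames:
        sel = np.asarray(com_selection(fr), dtype=bool)
        ref = fr.coords[sel] if sel.any() else fr.coords
        com = ref.mean(axis=0)
        d = fr.coords - com
        if fr.box is not None:
            d -= fr.box * np.round(d / fr.box)
        half = max(half, np.abs(d[:, axis]).max(initial=0.0))
    n_bins = max(int(np.ceil(half / bin_width)), 1)
    edges = np.arange(-n_bins, n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = {g: np.zeros(len(centers)) for g in groups}
    for fr in frames:
        sel = np.asarray(com_selection(fr), dtype=bool)
        ref = fr.coords[sel] if sel.any() else fr.coords
        com = ref.mean(axis=0)
        d = fr.coords - com
        if fr.box is not None:
            d -= fr.box * np.round(d / fr.box)
        r2 = d[:, radial_axes[0]] ** 2 + d[:, radial_axes[1]] ** 2
        in_cyl = r2 <= radius ** 2
        for gname, gsel in groups.items():
            mask = np.asarray(gsel(fr), dtype=bool) & in_cyl
            if not mask.any():
                warnings.warn(
                    f"group {gname!r}: empty selection in cylinder at "
                    f"t={fr.time_ps} ps; contributing zeros")
            counts[gname] += np.histogram(d[mask, axis], bins=edges)[0]
    for g in counts:
        counts[g] /= len(frames)
    return DensityProfile(centers, counts, diameter, bin_width, axis,
                          len(frames))


def sel_resname_role(resname: str, role: str | None = None):
    """Selector factory for density-profile groups."""
    def _sel(frame: Frame):
        mask = frame.atoms["resname"] == resname
        if role is not None:
            mask &= frame.atoms["role"] == role
        return mask.to_numpy()
    return _sel


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi)])


def _bead_radii(frame: Frame, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(frame.n_beads)
    for i, cls in enumerate(frame.atoms["size_class"]):
        if cls not in radii:
            raise ValueError(f"no SASA radius defined for size class {cls!r}")
        out[i] = radii[cls]
    return out


def sasa_per_bead(
    frame: Frame,
    targets: np.ndarray | None = None,
    radii: dict[str, float] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley accessible area (A^2) of each target bead.

    Every bead is a sphere of its size-class radius; the probe sphere
    (default 1.4 A, water) is rolled by sampling ``n_points`` quasi-uniform
    points on each expanded sphere and counting those outside every other
    expanded sphere.  All beads in the frame occlude, targets or not.
    """
    radii_map = CLASS_RADII if radii is None else radii
    r = _bead_radii(frame, radii_map) + probe
    coords = frame.coords
    if targets is None:
        targets = np.arange(frame.n_beads)
    else:
        targets = np.asarray(targets)
        if targets.dtype == bool:
            targets = np.flatnonzero(targets)
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(targets))
    for t, i in enumerate(targets):
        ri = r[i]
        neigh = [j for j in tree.query_ball_point(coords[i], ri + r.max())
                 if j != i
                 and np.linalg.norm(coords[j] - coords[i]) < ri + r[j]]
        pts = coords[i] + ri * unit
        if neigh:
            dif = pts[:, None, :] - coords[neigh][None, :, :]
            buried = (np.einsum("pjk,pjk->pj", dif, dif)
                      < (r[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[t] = 4.0 * np.pi * ri * ri * frac
    return areas


def bead_sasa(
    frame: Frame,
    targets: np.ndarray,
    radii: dict[str, float] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Total accessible area (A^2) of a target bead set within the frame."""
    return float(sasa_per_bead(frame, targets, radii, probe, n_points).sum())
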