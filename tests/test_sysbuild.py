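"""System construction: placement, cargo insertion, docking, run parameters."""

import numpy as np
import pytest
from scipy.stats import chisquare

from cgkit.ffpatch import make_synthetic_zn_protein
from cgkit.fixtures import make_micelle
from cgkit.sysbuild import (build_conformation, emit_run_parameters,
                            insert_cargo, place_proteins_near_ligands,
                            place_unimers, solvation_counts, water_lattice)
from cgkit.topology import (assign_bonded_parameters, build_dii_topology,
                            build_polymer_topology, generate_chain_set)


def min_intermolecular_distance(frame, only=None):
    """Brute-force minimum-image distance check between molecules.

    ``only``: restrict to pairs where at least one bead matches this
    molecule-name mask (the other molecule may be anything).
    """
    molid = frame.atoms["molid"].to_numpy()
    diff = frame.coords[:, None, :] - frame.coords[None, :, :]
    if frame.box is not None:
        diff -= frame.box * np.round(diff / frame.box)
    dm = np.linalg.norm(diff, axis=2)
    mask = molid[:, None] != molid[None, :]
    if only is not None:
        sel = (frame.atoms["molname"] == only).to_numpy()
        mask &= sel[:, None] | sel[None, :]
    return dm[mask].min()


class TestPlaceUnimers:
    def test_min_separation_holds_by_brute_force(self):
        frame = place_unimers(10, box=[100.0] * 3, seed=1)
        n_mols = frame.atoms["molid"].nunique()
        assert n_mols == 10
        assert min_intermolecular_distance(frame) >= 3.5

    def test_zero_molecules_gives_empty_frame_with_box(self):
        frame = place_unimers(0, box=[50.0] * 3, seed=1)
        assert frame.n_beads == 0

    def test_chain_type_ratio_two_one_one_one(self):
        frame = place_unimers(320, box=[400.0] * 3, seed=2)
        sizes = frame.atoms.groupby("molid").size()
        by_len = sizes.value_counts()
        # four chain types in proportion 2:1:1:1
        assert sorted(by_len.values) == [64, 64, 64, 128]

    def test_same_seed_reproduces_frame(self):
        a = place_unimers(8, box=[90.0] * 3, seed=5)
        b = place_unimers(8, box=[90.0] * 3, seed=5)
        assert np.array_equal(a.coords, b.coords)
        c = place_unimers(8, box=[90.0] * 3, seed=6)
        assert not np.array_equal(a.coords, c.coords)

    def test_centres_are_uniform_by_octant_chi_square(self):
        frame = place_unimers(320, box=[400.0] * 3, seed=3)
        coms = frame.atoms.join(
            __import__("pandas").DataFrame(frame.coords,
                                           columns=["x", "y", "z"])
        ).groupby("molid")[["x", "y", "z"]].mean().to_numpy()
        octant = ((np.mod(coms, 400.0) >= 200.0)
                  * np.array([1, 2, 4])).sum(axis=1)
        observed = np.bincount(octant, minlength=8)
        stat, p = chisquare(observed)
        assert p > 1e-4  # non-strict uniformity check

    def test_packing_infeasible_raises_helpful_error(self):
        with pytest.raises(ValueError, match="box"):
            place_unimers(50, box=[20.0] * 3, seed=1)


@pytest.fixture(scope="module")
def loaded():
    frame = make_micelle(10, seed=7)
    dii = assign_bonded_parameters(build_dii_topology())
    return frame, insert_cargo(frame, dii, 5, seed=8)


@pytest.fixture(scope="module")
def docked():
    frame = make_micelle(12, seed=10)
    prot, xyz = make_synthetic_zn_protein(seed=0)
    n = 6
    out = place_proteins_near_ligands(frame, prot, xyz, n, seed=11)
    return frame, out, n


class TestInsertCargo:
    def test_adds_exactly_n_molecules(self, loaded):
        frame, out = loaded
        assert out.n_beads - frame.n_beads == 5 * 21
        assert (out.atoms["molname"] == "DII").sum() == 105

    def test_cargo_outside_aggregate_convex_region(self, loaded):
        from scipy.spatial import Delaunay

        frame, out = loaded
        hull = Delaunay(frame.coords)
        dii = out.coords[(out.atoms["molname"] == "DII").to_numpy()]
        assert np.all(hull.find_simplex(dii) < 0)

    def test_overlap_respects_min_separation(self, loaded):
        # the aggregate's own chains interpenetrate by construction; the
        # inserted cargo must keep min_sep from everything
        _, out = loaded
        assert min_intermolecular_distance(out, only="DII") >= 3.5

    def test_zero_count_returns_input_unchanged(self):
        frame = make_micelle(6, seed=1)
        dii = assign_bonded_parameters(build_dii_topology())
        assert insert_cargo(frame, dii, 0) is frame


class TestProteinPlacement:
    def test_each_zn_within_binding_window_of_a_ligand(self, docked):
        frame, out, n = docked
        zn = np.flatnonzero((out.atoms["name"] == "ZN").to_numpy())
        assert len(zn) == n
        lig = np.flatnonzero(out.has_flag("ligand_site"))
        d = np.linalg.norm(
            out.coords[zn][:, None, :] - out.coords[lig][None, :, :], axis=2)
        in_window = (d >= 5.0) & (d <= 10.0)
        assert np.all(in_window.any(axis=1))

    def test_no_overlap_with_assembly(self, docked):
        _, out, _ = docked
        assert min_intermolecular_distance(out, only="PROT") >= 3.5 - 1e-9

    def test_requesting_more_than_exposed_ligands_errors(self):
        frame = make_micelle(4, seed=12)
        prot, xyz = make_synthetic_zn_protein(seed=0)
        with pytest.raises(ValueError, match="exposed ligand"):
            place_proteins_near_ligands(frame, prot, xyz, 50, seed=1)

    def test_zero_proteins_is_identity(self):
        frame = make_micelle(4, seed=12)
        prot, xyz = make_synthetic_zn_protein(seed=0)
        assert place_proteins_near_ligands(frame, prot, xyz, 0) is frame


class TestRunParameters:
    def test_production_protocol_fields(self):
        rp, mdp = emit_run_parameters("production")
        assert rp.timestep_fs == 10.0
        assert rp.neighbor_update == 20
        assert rp.lj_cutoff_nm == rp.coulomb_cutoff_nm == 1.1
        assert rp.epsilon_r == 15.0
        assert rp.temperature_K == 303.0 and rp.tau_t_ps == 0.5
        assert rp.pressure_bar == 1.0 and rp.tau_p_ps == 4.0
        assert rp.compressibility_bar == 4.5e-5
        assert "dt                       = 0.01" in mdp
        assert "epsilon_r                = 15" in mdp
        assert "coulombtype              = Reaction-Field" in mdp
        assert "pcoupl                   = Parrinello-Rahman" in mdp

    def test_minimization_uses_steepest_descent_5000_steps(self):
        rp, mdp = emit_run_parameters("minimize")
        assert rp.integrator == "steep" and rp.nsteps == 5000
        assert "integrator               = steep" in mdp

    def test_equilibration_carries_positional_restraints(self):
        rp, mdp = emit_run_parameters("equilibrate")
        assert rp.posres_fc_kcal_A2 == 0.1
        assert rp.nsteps * rp.timestep_fs == pytest.approx(200_000.0)  # 200 ps
        assert "-DPOSRES" in mdp and "41.84" in mdp

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            emit_run_parameters("anneal")


class TestSolvation:
    def test_emitted_system_is_net_neutral(self):
        frame = make_micelle(8, seed=3)
        dii = assign_bonded_parameters(build_dii_topology())
        loaded = insert_cargo(frame, dii, 3, seed=4)
        counts = solvation_counts(loaded)
        q = loaded.total_charge + counts["NA"] - counts["CL"]
        assert q == pytest.approx(0.0)
        assert counts["CL"] == 3  # one per +1 DiI
        assert counts["W"] > 0

    def test_water_lattice_avoids_solute(self):
        frame = make_micelle(6, seed=5)
        pts = water_lattice(frame, 500)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(np.mod(frame.coords, frame.box)).query(pts)
        assert d.min() >= 3.5


def test_conformation_respects_bond_lengths():
    # the grower satisfies a spanning tree of the bond graph exactly; ring
    # closures cannot all hold and are relaxed by the MD engine instead
    top = assign_bonded_parameters(
        build_polymer_topology(generate_chain_set(1, seed=1)[0]))
    xyz = build_conformation(top, seed=2)
    matched = sum(
        np.isclose(np.linalg.norm(xyz[b.i] - xyz[b.j]), b.length, rtol=1e-6)
        for b in top.bonds)
    assert matched >= top.n_beads - 1
    for b in top.bonds:
        assert np.linalg.norm(xyz[b.i] - xyz[b.j]) < 3 * b.length
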