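"""Fixture generators satisfy their geometric predicates (oracle-checked)."""

import numpy as np
import pytest

from cgkit.fixtures import (make_cargo_states, make_disassembly_series,
                            make_dispersed, make_micelle,
                            make_multicore_aggregate, make_shape_cloud)


def pairwise_min_image(coords_a, coords_b, box=None):
    d = coords_a[:, None, :] - coords_b[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=2)


class TestMicelle:
    def test_layer_assignment_by_construction(self):
        fr = make_micelle(10, seed=2, with_box=False)
        at = fr.atoms
        r = np.linalg.norm(fr.coords, axis=1)
        m1 = ((at["resname"] == "M1") & (at["role"] == "SC")).to_numpy()
        bb = (at["role"] == "BB").to_numpy()
        assert np.all(r[m1] <= 15.0 + 1e-9)
        assert np.all((r[bb] >= 15.0 - 1e-9) & (r[bb] <= 22.0 + 1e-9))
        lig = fr.has_flag("ligand_site")
        assert np.allclose(r[lig], 30.0)

    def test_nonincreasing_radii_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_micelle(5, radii=(20.0, 18.0, 30.0))

    def test_same_seed_identical_frame(self):
        a = make_micelle(8, seed=9)
        b = make_micelle(8, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert a.atoms.equals(b.atoms)


class TestMulticore:
    def test_cores_separated_beyond_clustering_threshold(self):
        fr = make_multicore_aggregate(3, seed=1, with_box=False)
        at = fr.atoms
        m1 = ((at["resname"] == "M1") & (at["role"] == "SC")).to_numpy()
        x = fr.coords[m1][:, 0]
        # three cores along x at 0 / 44 / 88: nearest inter-core gap > 8
        groups = [np.abs(x - c * 44.0) < 20.0 for c in range(3)]
        for a, b in ((0, 1), (1, 2)):
            da = fr.coords[m1][groups[a]]
            db = fr.coords[m1][groups[b]]
            assert pairwise_min_image(da, db).min() > 8.0

    def test_bridged_variant_merges_cores(self):
        from cgkit.analysis import ClusterParams, cluster_entities

        sep = make_multicore_aggregate(4, seed=2)
        bri = make_multicore_aggregate(4, bridged=True, seed=2)
        p = ClusterParams(entity="m1_sidechain")
        assert cluster_entities(sep, p).n_clusters == 4
        assert cluster_entities(bri, p).n_clusters < 4


class TestDisassemblySeries:
    def test_detached_micelles_are_isolated_by_distance_oracle(self):
        traj = make_disassembly_series([40, 20], micelle_size=20, seed=3)
        fr = traj[-1]
        molid = fr.atoms["molid"].to_numpy()
        # the aggregate sits at low y, the detached micelle 150 A away
        com_y = {m: fr.coords[molid == m, 1].mean() for m in set(molid)}
        y0 = min(com_y.values())
        agg = [m for m, y in com_y.items() if y < y0 + 75.0]
        det = [m for m in com_y if m not in agg]
        assert len(det) > 0
        da = fr.coords[np.isin(molid, agg)]
        db = fr.coords[np.isin(molid, det)]
        assert pairwise_min_image(da, db, fr.box).min() > 8.0

    def test_validation_of_step_arguments(self):
        with pytest.raises(ValueError, match="multiple"):
            make_disassembly_series([30, 20], micelle_size=20)
        with pytest.raises(ValueError, match="non-increasing"):
            make_disassembly_series([20, 40], micelle_size=20)

    def test_protein_bound_variant_zn_in_binding_window(self):
        traj = make_disassembly_series([40, 20], micelle_size=20, seed=6,
                                       with_proteins=True)
        for fr in traj:
            zn = np.flatnonzero((fr.atoms["resname"] == "ZN").to_numpy())
            lig = np.flatnonzero(fr.has_flag("ligand_site"))
            assert len(zn) > 0
            d = pairwise_min_image(fr.coords[zn], fr.coords[lig]).min(axis=1)
            assert np.all((d >= 5.0) & (d <= 10.0))


class TestShapeClouds:
    def test_eigenvalue_structure_is_exact(self):
        s = np.linalg.svd(make_shape_cloud("prolate", seed=0),
                          compute_uv=False)
        lam = np.sort(s ** 2)
        assert lam[0] == pytest.approx(lam[1], rel=1e-12)
        assert lam[2] == pytest.approx(9 * lam[1], rel=1e-9)
        s = np.linalg.svd(make_shape_cloud("oblate", seed=0),
                          compute_uv=False)
        lam = np.sort(s ** 2)
        assert lam[1] == pytest.approx(lam[2], rel=1e-12)

    def test_line_points_are_collinear(self):
        cloud = make_shape_cloud("line", n=50, seed=4)
        c = cloud - cloud.mean(axis=0)
        assert np.linalg.matrix_rank(c, tol=1e-8) == 1

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            make_shape_cloud("banana")


class TestCargoStates:
    def test_deterministic_under_seed(self):
        a = make_cargo_states("buried", seed=5)
        b = make_cargo_states("buried", seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_states_use_real_dii_typing(self):
        fr = make_cargo_states("exposed", seed=1)
        dii = fr.atoms[fr.atoms["molname"] == "DII"]
        assert len(dii) == 21
        assert (dii["type"] == "SQ2").sum() == 2
        assert fr.has_flag("headgroup").sum() == 11

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="cargo state"):
            make_cargo_states("floating")


def test_dispersed_chains_far_apart():
    fr = make_dispersed(8, seed=7)
    molid = fr.atoms["molid"].to_numpy()
    for a in range(8):
        for b in range(a + 1, 8):
            d = pairwise_min_image(fr.coords[molid == a],
                                   fr.coords[molid == b], fr.box)
            assert d.min() > 8.0
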