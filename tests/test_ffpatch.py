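"""Force-field patches: protein-water scaling, Zn cross term, Zn site."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cgkit.ffpatch import (CrossTermSpec, NonbondedTable,
                           add_zn_coordination, add_zn_ligand_crossterm,
                           make_synthetic_zn_protein, scale_protein_water,
                           synthetic_base_params)
from cgkit.units import kcal_to_kj


@pytest.fixture
def base():
    return synthetic_base_params()


class TestProteinWaterScaling:
    def test_epsilon_ratio_is_the_scaling_factor(self, base):
        patched = scale_protein_water(base, ["TP1"], 1.10)
        ratio = patched.get_pair("WTP1", "W")[1] / base.get_pair("TP1", "W")[1]
        assert ratio == pytest.approx(1.10, rel=1e-12)

    def test_duplicated_self_and_cross_rows_present(self, base):
        patched = scale_protein_water(base, ["TP1"], 1.10)
        assert patched.has_pair("WTP1", "WTP1")
        assert patched.has_pair("WTP1", "TP1")
        assert patched.get_pair("WTP1", "WTP1") == base.get_pair("TP1", "TP1")

    def test_non_water_cross_terms_copied_unchanged(self, base):
        patched = scale_protein_water(base, ["TP1"], 1.10)
        for other in ("P6", "C1", "TN6d"):
            assert patched.get_pair("WTP1", other) \
                == base.get_pair("TP1", other)

    def test_identity_factor_copies_without_change(self, base):
        patched = scale_protein_water(base, ["TP1"], 1.0)
        assert patched.get_pair("WTP1", "W") == base.get_pair("TP1", "W")

    def test_base_rows_untouched(self, base):
        patched = scale_protein_water(base, ["TP1", "P1"], 1.10)
        for key, val in base.pairs.items():
            assert patched.pairs[key] == val

    def test_idempotent(self, base):
        once = scale_protein_water(base, ["TP1"], 1.10)
        twice = scale_protein_water(once, ["TP1"], 1.10)
        assert twice.pairs == once.pairs and twice.types == once.types

    def test_errors(self, base):
        with pytest.raises(ValueError, match="unknown protein bead"):
            scale_protein_water(base, ["XX9"], 1.10)
        with pytest.raises(ValueError, match="factor"):
            scale_protein_water(base, ["TP1"], -0.5)


class TestZnLigandCrossTerm:
    def test_default_spec_written_in_kj_units(self, base):
        patched = add_zn_ligand_crossterm(base)
        sigma, eps = patched.get_pair("SD", "P6")
        assert (sigma, eps) == (5.0, 15.0)
        text = patched.to_text()
        row = [l for l in text.splitlines()
               if l.split()[:2] in (["P6", "SD"], ["SD", "P6"])][0]
        assert float(row.split()[4]) == pytest.approx(62.76, abs=1e-6)
        assert float(row.split()[3]) == pytest.approx(0.5, abs=1e-12)

    def test_potential_minimum_at_sixth_root_of_two_sigma(self, base):
        # independent oracle: numerically minimize the LJ potential
        patched = add_zn_ligand_crossterm(base)
        sigma, eps = patched.get_pair("SD", "P6")

        def lj(r):
            return 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)

        res = minimize_scalar(lj, bounds=(3.0, 12.0), method="bounded")
        assert res.x == pytest.approx(2 ** (1 / 6) * sigma, abs=1e-4)
        assert res.fun == pytest.approx(-eps, rel=1e-8)

    def test_reapplication_is_noop_conflict_is_error(self, base):
        once = add_zn_ligand_crossterm(base)
        twice = add_zn_ligand_crossterm(once)
        assert twice.pairs == once.pairs
        with pytest.raises(ValueError, match="conflicting"):
            add_zn_ligand_crossterm(once, CrossTermSpec("SD", "P6", 6.0, 10.0))

    def test_unknown_type_rejected(self, base):
        with pytest.raises(ValueError, match="not defined"):
            add_zn_ligand_crossterm(base, CrossTermSpec("SD", "QQ", 5.0, 15.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CrossTermSpec("SD", "P6", -5.0, 15.0)
        with pytest.raises(ValueError):
            CrossTermSpec("SD", "P6", 5.0, 0.0)

    def test_unit_round_trip_through_file(self, base):
        patched = add_zn_ligand_crossterm(base)
        back = NonbondedTable.from_text(patched.to_text())
        s, e = back.get_pair("SD", "P6")
        assert s == pytest.approx(5.0, rel=1e-6)
        assert e == pytest.approx(15.0, rel=1e-6)
        assert ("P6", "SD") in back.overrides


class TestZnCoordination:
    def test_three_bonds_at_coordination_distance(self):
        prot, _ = make_synthetic_zn_protein(seed=0)
        n0 = len(prot.bonds)
        patched = add_zn_coordination(prot)
        new = [b for b in patched.bonds[n0:]]
        assert len(new) == 3
        assert all(b.length == pytest.approx(2.4) for b in new)
        zn = [b for b in patched.beads if b.name == "ZN"][0]
        assert zn.type == "SD"
        rids = sorted({patched.beads[b.i].resid for b in new}
                      | {patched.beads[b.j].resid for b in new} - {1})
        assert set(rids) >= {93, 95, 188}

    def test_reapplication_is_noop(self):
        prot, _ = make_synthetic_zn_protein(seed=0)
        once = add_zn_coordination(prot)
        twice = add_zn_coordination(once)
        assert len(twice.bonds) == len(once.bonds)

    def test_missing_residues_listed(self):
        prot, _ = make_synthetic_zn_protein(seed=0)
        prot.beads = [b for b in prot.beads if b.resid not in (95, 188)]
        prot.bonds = []
        with pytest.raises(ValueError) as err:
            add_zn_coordination(prot)
        assert "H95" in str(err.value) and "H188" in str(err.value)
        assert "H93" not in str(err.value)

    def test_missing_zn_bead_named(self):
        prot, _ = make_synthetic_zn_protein(seed=0)
        prot.beads = [b for b in prot.beads if b.name != "ZN"]
        prot.bonds = []
        with pytest.raises(ValueError, match="Zn bead"):
            add_zn_coordination(prot)

    def test_histidine_beads_sit_at_coordination_distance(self):
        prot, xyz = make_synthetic_zn_protein(seed=3)
        his = [i for i, b in enumerate(prot.beads) if b.resname == "HIS"]
        d = np.linalg.norm(xyz[his] - xyz[0], axis=1)
        assert np.allclose(d, 2.4, atol=0.05)
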