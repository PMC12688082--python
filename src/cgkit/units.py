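"""Unit conventions and conversions.

Internal units are angstrom (length) and kcal/mol (energy) throughout the
package; GROMACS-dialect writers convert to nm, kJ/mol and ps on output and
readers convert back on input.
"""

KCAL_TO_KJ = 4.184  # thermochemical calorie, exact
ANG_TO_NM = 0.1
FS_TO_PS = 1e-3

#: Martini size-class vdW radii (half the class sigma), angstrom.
CLASS_RADII = {"regular": 2.35, "small": 2.05, "tiny": 1.7}

#: Martini size-class bead masses, u.
CLASS_MASSES = {"regular": 72.0, "small": 54.0, "tiny": 36.0}

#: Heavy atoms mapped per bead for each size class.
CLASS_MAPPING = {"regular": 4, "small": 3, "tiny": 2}


def kcal_to_kj(x: float) -> float:
    return x * KCAL_TO_KJ


def kj_to_kcal(x: float) -> float:
    return x / KCAL_TO_KJ


def ang_to_nm(x: float) -> float:
    return x * ANG_TO_NM


def nm_to_ang(x: float) -> float:
    return x / ANG_TO_NM


def bond_k_to_kj_nm(k_kcal_ang2: float) -> float:
    """Harmonic bond force constant kcal/mol/A^2 -> kJ/mol/nm^2."""
    return k_kcal_ang2 * KCAL_TO_KJ * 100.0


def bond_k_from_kj_nm(k_kj_nm2: float) -> float:
    return k_kj_nm2 / (KCAL_TO_KJ * 100.0)
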