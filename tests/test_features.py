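"""Shrake-Rupley SASA and rASA: analytic checks, invariances, burial."""
import dataclasses

import numpy as np
import pytest

from isopeptide_detect.features import (
    PROBE_RADIUS,
    VDW_RADII,
    compute_rasa,
    compute_sasa,
)
from isopeptide_detect.structure_io import Atom, Residue, Structure
from isopeptide_detect.synthetic import PlantSpec, make_positive
from oracles import two_sphere_exposed_area


def atom_structure(positions, element="C", res_name="ALA"):
    """One residue per atom, for direct SASA bookkeeping."""
    chains = {"A": [
        Residue(chain_id="A", seq_id=i + 1, icode="", res_name=res_name,
                atoms={"X": Atom(name="X", element=element, coord=np.asarray(p, float))})
        for i, p in enumerate(positions)
    ]}
    return Structure(id="atoms", chains=chains)


def test_isolated_atom_matches_analytic_sphere():
    st = atom_structure([[0.0, 0.0, 0.0]])
    sasa = compute_sasa(st, n_points=500)
    r = VDW_RADII["C"] + PROBE_RADIUS
    analytic = 4.0 * np.pi * r * r
    assert sasa[("A", 1, "")] == pytest.approx(analytic, rel=0.02)


def test_distant_atoms_unoccluded():
    r = VDW_RADII["C"] + PROBE_RADIUS
    st = atom_structure([[0, 0, 0], [2 * r + 0.5, 0, 0]])
    sasa = compute_sasa(st, n_points=500)
    analytic = 4.0 * np.pi * r * r
    assert sasa[("A", 1, "")] == pytest.approx(analytic, rel=0.02)
    assert sasa[("A", 2, "")] == pytest.approx(analytic, rel=0.02)


@pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.0])
def test_two_sphere_overlap_matches_spherical_cap(d):
    st = atom_structure([[0, 0, 0], [d, 0, 0]])
    sasa = compute_sasa(st, n_points=2000)
    r = VDW_RADII["C"] + PROBE_RADIUS
    expected = two_sphere_exposed_area(r, d)
    assert sasa[("A", 1, "")] == pytest.approx(expected, rel=0.03)
    assert sasa[("A", 2, "")] == pytest.approx(expected, rel=0.03)


def test_occlusion_monotone_under_added_atoms(rng):
    """Adding occluders never increases any residue's SASA."""
    base_pos = [[0, 0, 0], [3.0, 0, 0]]
    st = atom_structure(base_pos)
    base = compute_sasa(st, n_points=500)
    extra = base_pos + [[1.5, 2.5, 0]]
    st2 = atom_structure(extra)
    more = compute_sasa(st2, n_points=500)
    for key in base:
        assert more[key] <= base[key] + 1e-9


def test_sasa_rigid_invariance(ideal_plant, rng):
    from isopeptide_detect._geom import random_rigid_transform
    from test_matcher import transform_structure

    structure, _ = ideal_plant
    base = compute_sasa(structure, n_points=500)
    rot, trans = random_rigid_transform(rng)
    moved = transform_structure(structure, rot, trans)
    got = compute_sasa(moved, n_points=500)
    # the point lattice is fixed in the lab frame, so rotation re-samples
    # each sphere: total area is stable to <0.5%, per-residue jitter ~1-2%
    assert sum(got.values()) == pytest.approx(sum(base.values()), rel=0.005)
    for key in base:
        assert got[key] == pytest.approx(base[key], rel=0.05, abs=2.0)


def test_buried_triad_much_less_accessible_than_exposed(corpus_dir):
    buried, truth = make_positive(PlantSpec(noise_sigma=0.0, burial="buried", seed=5))
    exposed, _ = make_positive(PlantSpec(noise_sigma=0.0, burial="exposed", seed=5))

    def site(st):
        return tuple(
            st.get_residue(("A", truth[k], ""))
            for k in ("r1_bond", "r_cat", "r2_bond")
        )

    r_buried = compute_rasa(buried, site(buried))
    r_exposed = compute_rasa(exposed, site(exposed))
    assert r_buried < 0.07
    assert r_exposed > 0.4
    assert r_buried < r_exposed


def test_rasa_converged_at_500_points(ideal_plant):
    structure, truth = ideal_plant
    site = tuple(
        structure.get_residue(("A", truth[k], ""))
        for k in ("r1_bond", "r_cat", "r2_bond")
    )
    a = compute_rasa(structure, site, n_points=500)
    b = compute_rasa(structure, site, n_points=2000)
    assert abs(a - b) < 0.02


def test_sasa_cross_checked_against_biotite(ideal_plant):
    """Independent implementation route: biotite's Shrake-Rupley."""
    import biotite.structure as struc

    structure, _ = ideal_plant
    atoms = []
    for res in structure.iter_residues():
        for atom in res.atoms.values():
            atoms.append((res, atom))
    arr = struc.AtomArray(len(atoms))
    for i, (res, atom) in enumerate(atoms):
        arr.coord[i] = atom.coord
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.seq_id
        arr.res_name[i] = res.res_name
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
        arr.hetero[i] = not res.is_standard
    bio = struc.sasa(arr, point_number=1000, vdw_radii="Single")
    ours = compute_sasa(structure, n_points=1000)
    per_res_bio: dict = {}
    for i, (res, _) in enumerate(atoms):
        per_res_bio[res.key] = per_res_bio.get(res.key, 0.0) + float(bio[i])
    for key, value in ours.items():
        assert value == pytest.approx(per_res_bio[key], rel=0.08, abs=3.0)


def test_unknown_residue_type_errors(ideal_plant):
    structure, truth = ideal_plant
    site = list(
        structure.get_residue(("A", truth[k], ""))
        for k in ("r1_bond", "r_cat", "r2_bond")
    )
    weird = dataclasses.replace(site[0], res_name="XYZ")
    sasa = compute_sasa(structure)
    sasa[weird.key] = 1.0
    with pytest.raises(Exception, match="XYZ"):
        compute_rasa(structure, (weird, site[1], site[2]), sasa=sasa)
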