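"""Bond-length Z-score, pseudo-dihedrals, and the KDE outlier models."""
import dataclasses
import itertools

import numpy as np
import pytest

from isopeptide_detect._geom import dihedral
from isopeptide_detect.geometry import (
    ANGLE_PAIRS,
    DihedralKDE,
    GeometryError,
    GeometryReference,
    assess,
    bond_length,
    combine_flags,
    pseudo_dihedrals,
    zscore,
)
from isopeptide_detect.synthetic import (
    PlantSpec,
    build_triad_atoms,
    make_positive,
    sample_reference_geometries,
    write_reference_file,
    _make_residue,
)
from oracles import dihedral_atan2, kde_log_likelihood_direct


def triad_site(triad_type="Lys-Asn-Asp", length=1.33, dihedrals=(-120.0, 130.0, 180.0)):
    coords = build_triad_atoms(triad_type, length, dihedrals)
    lys = _make_residue("A", 1, "LYS", coords["bond_lys"])
    names = {"Lys-Asn-Asp": ("ASP", "ASN"), "Lys-Asp-Glu": ("GLU", "ASP"),
             "Lys-Asn-Glu": ("GLU", "ASN")}[triad_type]
    cat = _make_residue("A", 2, names[0], coords["catalytic"])
    acc = _make_residue("A", 3, names[1], coords["bond_acceptor"])
    return (lys, cat, acc)


@pytest.fixture(scope="module")
def reference():
    lengths, samples = sample_reference_geometries(n_per_topology=500, seed=7201)
    return GeometryReference.fit(lengths, samples)


def test_bond_length_direct_distance():
    site = triad_site(length=1.33)
    assert bond_length(site) == pytest.approx(1.33, abs=1e-9)
    site2 = triad_site(length=1.80)
    assert bond_length(site2) == pytest.approx(1.80, abs=1e-9)


def test_bond_length_missing_atom_unmeasurable():
    site = triad_site()
    broken = dataclasses.replace(
        site[2], atoms={k: v for k, v in site[2].atoms.items() if k != "CG"}
    )
    assert bond_length((site[0], site[1], broken)) is None


def test_zscore_boundary_semantics():
    assert zscore(1.33, 1.33, 0.05) == (0.0, False)
    z, out = zscore(1.33 + 4 * 0.05, 1.33, 0.05)
    assert z == pytest.approx(4.0) and not out  # exactly 4 is not an outlier
    _, out = zscore(1.33 + 4.0001 * 0.05, 1.33, 0.05)
    assert out
    _, out = zscore(1.33 - 5 * 0.05, 1.33, 0.05)
    assert out  # two-sided


def test_zscore_linear_in_length():
    z1, _ = zscore(1.43, 1.33, 0.05)
    z2, _ = zscore(1.53, 1.33, 0.05)
    assert z2 - z1 == pytest.approx(2.0)


def test_pseudo_dihedrals_reproduce_plant_spec():
    for angles in [(-120.0, 130.0, 180.0), (-75.0, 150.0, 0.0), (-60.0, 140.0, 180.0)]:
        got = pseudo_dihedrals(triad_site(dihedrals=angles))
        assert got["phi"] == pytest.approx(angles[0], abs=1e-6)
        assert got["psi"] == pytest.approx(angles[1], abs=1e-6)
        assert abs(got["omega"]) == pytest.approx(abs(angles[2]), abs=1e-6)


def test_planar_cis_trans_cases():
    trans = [np.array(p, float) for p in
             [(-1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)]]
    assert abs(dihedral(*trans)) == pytest.approx(180.0)
    cis = [np.array(p, float) for p in
           [(0, 1, 0), (1, 1, 0), (1, 0, 0), (0, 0, 0)]]
    assert dihedral(*cis) == pytest.approx(0.0)


def test_dihedral_matches_independent_formula(rng):
    for _ in range(50):
        pts = rng.normal(size=(4, 3)) * 5
        assert dihedral(*pts) == pytest.approx(dihedral_atan2(*pts), abs=1e-9)


def test_mirroring_negates_all_pseudo_dihedrals():
    site = triad_site(dihedrals=(-120.0, 130.0, 170.0))
    orig = pseudo_dihedrals(site)
    mirrored = tuple(
        dataclasses.replace(res, atoms={
            n: dataclasses.replace(a, coord=-a.coord) for n, a in res.atoms.items()
        })
        for res in site
    )
    got = pseudo_dihedrals(mirrored)
    for key in ("phi", "psi", "omega"):
        assert got[key] == pytest.approx(-orig[key], abs=1e-9)


def test_kde_refuses_too_few_samples(rng):
    with pytest.raises(GeometryError):
        DihedralKDE(rng.normal(size=(10, 2)))


def test_kde_calibration_and_centroid(reference):
    """~5% of training points flag themselves; the centroid never does."""
    for (topology, pair), kde in reference.kdes.items():
        frac = float(np.mean(kde.train_log_likelihood < kde.cutoff))
        assert 0.03 <= frac <= 0.07, (topology, pair, frac)
    kde = reference.kdes[("CnaA-like", ("phi", "psi"))]
    centroid = np.array([-120.0, 130.0])
    assert kde.log_likelihood(centroid)[0] > kde.cutoff


def test_far_query_flagged_and_kernel_sum_oracle(reference, rng):
    kde = reference.kdes[("CnaA-like", ("phi", "psi"))]
    far = np.array([-120.0 + 6 * 12.0, 130.0 - 6 * 12.0])
    assert kde.is_outlier(far)
    pts = np.column_stack([rng.uniform(-180, 180, 20), rng.uniform(-180, 180, 20)])
    ours = kde.log_likelihood(pts)
    oracle = kde_log_likelihood_direct(kde, pts)
    np.testing.assert_allclose(ours, oracle, atol=1e-9)


def test_kde_integrates_to_one_on_angle_domain(reference):
    kde = reference.kdes[("CnaB-like", ("omega", "phi"))]  # straddles the cut
    grid = np.arange(-179.5, 180.0, 1.0)
    gx, gy = np.meshgrid(grid, grid)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    total = np.sum(np.exp(kde.log_likelihood(pts))) * 1.0 * 1.0
    assert total == pytest.approx(1.0, rel=0.02)


def test_flag_logic_truth_table():
    for z_out, p1, p2, p3 in itertools.product([False, True], repeat=4):
        flag = combine_flags(z_out, [p1, p2, p3])
        assert flag == ("outlier" if (z_out or p1 or p2 or p3) else "ok")


def test_assess_in_distribution_ok(reference):
    site = triad_site(dihedrals=(-120.0, 130.0, 180.0), length=1.33)
    report = assess(site, "CnaA-like", reference)
    assert report.overall_flag == "ok"
    assert not report.zscore_outlier
    assert not any(report.pair_outliers.values())


def test_assess_stretched_bond_flags_zscore_only(reference):
    stretched = 1.33 + 6 * reference.bond_length_sd
    site = triad_site(dihedrals=(-120.0, 130.0, 180.0), length=stretched)
    report = assess(site, "CnaA-like", reference)
    assert report.zscore_outlier and report.overall_flag == "outlier"


def test_assess_rotated_omega_flags_dihedral_only(reference):
    """Length fine but pseudo-omega 90 degrees off: geometry sub-optimal."""
    site = triad_site(dihedrals=(-120.0, 130.0, 90.0), length=1.33)
    report = assess(site, "CnaA-like", reference)
    assert not report.zscore_outlier
    flagged = {p for p, v in report.pair_outliers.items() if v}
    assert ("omega", "psi") in flagged and ("omega", "phi") in flagged
    assert not report.pair_outliers[("phi", "psi")]
    assert report.overall_flag == "outlier"


def test_missing_atoms_skip_pairs_without_flagging(reference):
    site = triad_site()
    broken = dataclasses.replace(
        site[0], atoms={k: v for k, v in site[0].atoms.items() if k != "CD"}
    )
    report = assess((broken, site[1], site[2]), "CnaA-like", reference)
    assert report.dihedrals["phi"] is None
    assert report.pair_likelihoods[("phi", "psi")] is None
    assert not report.pair_outliers[("phi", "psi")]


def test_reference_file_roundtrip(tmp_path, reference):
    path = tmp_path / "ref.tsv"
    write_reference_file(path, n_per_topology=500, seed=7201)
    loaded = GeometryReference.from_file(path)
    assert loaded.bond_length_mean == pytest.approx(reference.bond_length_mean, abs=1e-3)
    assert loaded.bond_length_sd == pytest.approx(reference.bond_length_sd, abs=1e-3)
    for key in reference.kdes:
        assert loaded.kdes[key].cutoff == pytest.approx(
            reference.kdes[key].cutoff, abs=0.02
        )
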