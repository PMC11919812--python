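"""Template search: correctness against brute force, invariances, reduction."""
import dataclasses

import numpy as np
import pytest

from isopeptide_detect._geom import random_rigid_transform
from isopeptide_detect.matcher import (
    MatchHit,
    SearchConfig,
    exclude_by_identity,
    find_matches,
    reduce_to_best,
    site_flank_sequence,
)
from isopeptide_detect.structure_io import Structure
from isopeptide_detect.synthetic import PlantSpec, make_negative, make_positive
from isopeptide_detect.templates import TemplateLibrary
from oracles import brute_force_matches, kabsch_rmsd_svd


def transform_structure(structure: Structure, rot, trans) -> Structure:
    chains = {}
    for cid, residues in structure.chains.items():
        new = []
        for res in residues:
            r = dataclasses.replace(res, atoms={
                n: dataclasses.replace(a, coord=rot @ a.coord + trans)
                for n, a in res.atoms.items()
            })
            new.append(r)
        chains[cid] = new
    return Structure(id=structure.id, chains=chains)


def test_ideal_plant_self_matches_at_zero_rmsd(ideal_plant, library, search_config):
    structure, truth = ideal_plant
    hits = find_matches(structure, library, search_config)
    assert hits
    best = min(hits, key=lambda h: h.rmsd)
    assert best.rmsd == pytest.approx(0.0, abs=1e-6)
    assert {r.seq_id for r in best.site} == {
        truth["r1_bond"], truth["r_cat"], truth["r2_bond"]
    }
    assert best.topology == truth["type"]


def test_rmsd_invariant_under_rigid_transform(ideal_plant, library, search_config, rng):
    structure, _ = ideal_plant
    base = {h.site_key: h.rmsd for h in find_matches(structure, library, search_config)}
    for _ in range(3):
        rot, trans = random_rigid_transform(rng)
        moved = transform_structure(structure, rot, trans)
        got = {h.site_key: h.rmsd for h in find_matches(moved, library, search_config)}
        assert set(got) == set(base)
        for k in base:
            assert abs(got[k] - base[k]) < 1e-6


@pytest.mark.parametrize("sigma,burial", [(0.0, "buried"), (0.3, "exposed")])
def test_matches_equal_brute_force(sigma, burial, library, search_config):
    """The pruned search returns exactly the brute-force hit set."""
    for seed in (3, 4):
        structure, _ = make_positive(
            PlantSpec(noise_sigma=sigma, burial=burial, seed=seed)
        )
        hits = {
            (h.template_id, h.site_key): h.rmsd
            for h in find_matches(structure, library, search_config)
        }
        oracle = brute_force_matches(structure, library, search_config)
        assert set(hits) == set(oracle)
        for k in hits:
            assert abs(hits[k] - oracle[k]) < 1e-6


def test_mean_min_rmsd_nondecreasing_in_noise(library, search_config):
    sigmas = (0.0, 0.1, 0.3, 0.5)
    means = []
    for sigma in sigmas:
        vals = []
        for seed in range(40):
            st, _ = make_positive(
                PlantSpec(noise_sigma=sigma, burial="exposed", seed=2000 + seed)
            )
            hits = find_matches(st, library, search_config)
            assert hits, f"plant lost at sigma={sigma}"
            vals.append(min(h.rmsd for h in hits))
        means.append(np.mean(vals))
    assert all(a <= b + 1e-12 for a, b in zip(means, means[1:])), means


def _fake_hit(rmsd, template_id, site):
    return MatchHit(site=site, template_id=template_id, rmsd=rmsd,
                    topology="CnaA-like", triad_type="Lys-Asn-Asp",
                    matched_atoms=[])


def test_reduce_to_best_minimum_and_tiebreak(ideal_plant):
    structure, truth = ideal_plant
    site = tuple(
        structure.get_residue(("A", truth[k], ""))
        for k in ("r1_bond", "r_cat", "r2_bond")
    )
    other = tuple(structure.chains["A"][:3])
    hits = [
        _fake_hit(0.8, "tC", site), _fake_hit(0.5, "tB", site),
        _fake_hit(0.9, "tA", site), _fake_hit(0.4, "tZ", other),
    ]
    best = reduce_to_best(hits)
    assert len(best) == 2  # disjoint sites both retained
    by_site = {h.site_key: h for h in best}
    assert by_site[hits[0].site_key].rmsd == 0.5
    # ties break lexicographically by template id
    tie = reduce_to_best([_fake_hit(0.5, "tB", site), _fake_hit(0.5, "tA", site)])
    assert tie[0].template_id == "tA"
    for h in best:
        assert all(h.rmsd <= x.rmsd for x in hits if x.site_key == h.site_key)


def test_exclude_by_identity_self_match_removed(ideal_plant, library):
    structure, _ = ideal_plant
    hits = find_matches(structure, library)
    assert hits
    # template flanks are random draws: low identity, everything retained
    assert exclude_by_identity(hits, structure, library) == hits
    # give the best template the target's own flank: 100% identity, removed
    best = min(hits, key=lambda h: h.rmsd)
    flank = site_flank_sequence(structure, best)
    doctored = []
    for t in library:
        t2 = dataclasses.replace(t)
        if t.id == best.template_id:
            t2.flank_sequence = flank
        doctored.append(t2)
    doctored_lib = TemplateLibrary(templates=doctored, version=library.version)
    kept = exclude_by_identity(hits, structure, doctored_lib)
    assert best.template_id not in {h.template_id for h in kept}


def test_negative_structures_have_no_hits(library, search_config):
    for seed in (1, 2):
        decoy = make_negative(80, seed=seed, library=library, config=search_config)
        assert find_matches(decoy, library, search_config) == []


def test_negative_generation_deterministic(library, search_config):
    a = make_negative(40, seed=9, library=library, config=search_config)
    b = make_negative(40, seed=9, library=library, config=search_config)
    for ra, rb in zip(a.iter_residues(), b.iter_residues()):
        assert ra.res_name == rb.res_name
        for name in ra.atoms:
            assert np.array_equal(ra.atoms[name].coord, rb.atoms[name].coord)


def test_kabsch_agrees_with_svd_oracle(rng):
    for _ in range(5):
        p = rng.normal(size=(12, 3)) * 4
        q = p + rng.normal(size=(12, 3)) * 0.3
        from isopeptide_detect._geom import kabsch_rmsd

        assert kabsch_rmsd(p, q) == pytest.approx(kabsch_rmsd_svd(p, q), abs=1e-9)
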