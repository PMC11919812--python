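"""Constrained template search over a target structure.

For each template the search enumerates triples of target residues whose
types match the template's three roles, builds the atom correspondence by
name, prunes assignments whose pairwise inter-atom distances deviate from
the template's by more than ``distance_tolerance``, and scores surviving
correspondences by optimal-superposition (Kabsch) RMSD.  Chemically
symmetric carboxylate oxygens (Asp OD1/OD2, Glu OE1/OE2) are tried under
both namings and the lower-RMSD assignment kept, because deposited naming
is arbitrary.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._geom import kabsch_rmsd
from .structure_io import Residue, Structure
from .templates import ROLES, Template, TemplateLibrary, flank_identity

# roles in enumeration order
_SYMMETRIC_PAIRS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclasses.dataclass
class SearchConfig:
    rmsd_cutoff: float = 2.0        # Angstrom, report matches up to this RMSD
    distance_tolerance: float = 3.0  # Angstrom, pairwise-distance pruning slack
    max_hits_per_site: int = 1000

    def __post_init__(self) -> None:
        if min(self.rmsd_cutoff, self.distance_tolerance) <= 0 or self.max_hits_per_site <= 0:
            raise ValueError("all SearchConfig parameters must be positive")


@dataclasses.dataclass
class MatchHit:
    site: tuple[Residue, Residue, Residue]  # (bond_lys, catalytic, bond_acceptor)
    template_id: str
    rmsd: float
    topology: str
    triad_type: str
    matched_atoms: list[tuple[str, str, str]]  # (role, template atom, target atom)

    @property
    def site_key(self) -> frozenset:
        """Unordered residue-triple identity used for best-hit reduction."""
        return frozenset(res.key for res in self.site)


def _name_mappings(res_name: str, atom_names: list[str]) -> list[dict[str, str]]:
    """Template-atom -> target-atom name maps, including carboxylate swaps."""
    identity = {n: n for n in atom_names}
    pair = _SYMMETRIC_PAIRS.get(res_name)
    if pair and pair[0] in atom_names and pair[1] in atom_names:
        swapped = dict(identity)
        swapped[pair[0]], swapped[pair[1]] = pair[1], pair[0]
        return [identity, swapped]
    return [identity]


def _role_candidates(
    structure: Structure, template: Template, role: str
) -> list[tuple[Residue, np.ndarray]]:
    """Residues of the right type holding all template atoms, with the target
    coordinate block for every admissible atom-name assignment."""
    res_name = template.res_name(role)
    atom_names = [a.atom_name for a in template.role_atoms(role)]
    out = []
    for res in structure.iter_residues():
        if not res.is_standard or res.res_name != res_name:
            continue
        for mapping in _name_mappings(res_name, atom_names):
            coords = []
            for name in atom_names:
                atom = res.atoms.get(mapping[name])
                if atom is None:
                    break
                coords.append(atom.coord)
            else:
                out.append((res, np.array(coords)))
    return out


def find_matches(
    structure: Structure, library: TemplateLibrary, config: SearchConfig | None = None
) -> list[MatchHit]:
    """All template placements with RMSD <= ``config.rmsd_cutoff``.

    Per (template, residue triple) only the best symmetric-atom assignment is
    reported.  Residue-type matching is strict per role; the three residues
    may lie on different chains but must be distinct.
    """
    config = config or SearchConfig()
    hits: list[MatchHit] = []
    for template in library:
        t_coords = template.coords()
        t_dist = squareform(pdist(t_coords))
        role_atoms = {role: [a.atom_name for a in template.role_atoms(role)] for role in ROLES}
        sizes = {role: len(role_atoms[role]) for role in ROLES}
        offsets = {}
        off = 0
        for role in ROLES:
            offsets[role] = off
            off += sizes[role]
        cands = {role: _role_candidates(structure, template, role) for role in ROLES}
        if not all(cands.values()):
            continue
        best: dict[frozenset, MatchHit] = {}
        for (r1, c1), (r2, c2), (r3, c3) in itertools.product(
            cands["bond_lys"], cands["catalytic"], cands["bond_acceptor"]
        ):
            if len({r1.key, r2.key, r3.key}) != 3:
                continue
            coords = np.vstack([c1, c2, c3])
            # pairwise-distance pruning against the template's internal distances
            d = squareform(pdist(coords))
            if np.max(np.abs(d - t_dist)) > config.distance_tolerance:
                continue
            rmsd = kabsch_rmsd(t_coords, coords)
            if rmsd > config.rmsd_cutoff:
                continue
            key = frozenset((r1.key, r2.key, r3.key))
            prev = best.get(key)
            if prev is None or rmsd < prev.rmsd:
                matched = []
                for role, res, block in (
                    ("bond_lys", r1, c1), ("catalytic", r2, c2), ("bond_acceptor", r3, c3)
                ):
                    for i, t_name in enumerate(role_atoms[role]):
                        # recover target atom name from the coordinate block
                        t_atom = next(
                            a.name for a in res.atoms.values()
                            if np.array_equal(a.coord, block[i])
                        )
                        matched.append((role, t_name, t_atom))
                best[key] = MatchHit(
                    site=(r1, r2, r3),
                    template_id=template.id,
                    rmsd=rmsd,
                    topology=template.topology,
                    triad_type=template.triad_type,
                    matched_atoms=matched,
                )
        hits.extend(best.values())
    hits.sort(key=lambda h: (h.site[0].key, h.template_id))
    return hits


def reduce_to_best(hits: list[MatchHit]) -> list[MatchHit]:
    """One hit per residue triple: the minimum-RMSD match, ties broken by
    lexicographic template id."""
    best: dict[frozenset, MatchHit] = {}
    for hit in hits:
        key = hit.site_key
        prev = best.get(key)
        if prev is None or (hit.rmsd, hit.template_id) < (prev.rmsd, prev.template_id):
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.site[0].key, h.template_id))


def site_flank_sequence(structure: Structure, hit: MatchHit, window: int = 20) -> str:
    """Target-site flank: from ``window`` residues upstream of the first triad
    residue to ``window`` downstream of the last, in modeled-sequence space
    (position within the chain), truncated at chain ends.

    Built on the chain of the bond-forming lysine; triad residues on other
    chains do not extend the window.
    """
    chain_id = hit.site[0].chain_id
    chain = structure.chains[chain_id]
    positions = [
        i for i, res in enumerate(chain)
        if any(res.key == s.key for s in hit.site)
    ]
    lo = max(0, min(positions) - window)
    hi = min(len(chain), max(positions) + window + 1)
    return "".join(res.one_letter() for res in chain[lo:hi])


def exclude_by_identity(
    hits: list[MatchHit],
    structure: Structure,
    library: TemplateLibrary,
    threshold_pct: float = 30.0,
) -> list[MatchHit]:
    """Drop hits whose template flank aligns to the target-site flank with
    identity strictly above ``threshold_pct`` (training/evaluation mode, to
    prevent self-matching inflation)."""
    by_id = {t.id: t for t in library}
    kept = []
    for hit in hits:
        template = by_id[hit.template_id]
        target_flank = site_flank_sequence(structure, hit)
        if flank_identity(template.flank_sequence, target_flank) > threshold_pct:
            continue
        kept.append(hit)
    return kept
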