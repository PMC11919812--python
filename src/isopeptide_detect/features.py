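"""Classifier features: template RMSD (pass-through) and triad rASA.

Solvent accessibility is computed with the Shrake-Rupley algorithm on a
deterministic Fibonacci point lattice (default 500 points per atom, water
probe 1.4 A), then normalized per residue by the Rost-Sander maximum
accessible area for that amino-acid type.  A buried triad (low rASA) is a
physical prerequisite for intramolecular isopeptide-bond formation, which
is what makes this feature discriminative.
"""
from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from ._geom import fibonacci_sphere
from .structure_io import Residue, Structure

PROBE_RADIUS = 1.4  # Angstrom, water probe
_DEFAULT_RADIUS = 1.70

_HYDROGENS = {"H", "D"}


def _load_table(name: str) -> dict[str, float]:
    text = resources.files("isopeptide_detect.data").joinpath(name).read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


VDW_RADII = _load_table("vdw_radii.tsv")
ROST_SANDER_MAX = _load_table("rost_sander.tsv")


@dataclasses.dataclass
class SiteFeatures:
    rmsd: float
    r_asa: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rmsd, self.r_asa], dtype=float)


class SasaError(Exception):
    pass


def compute_sasa(
    structure: Structure, n_points: int = 500, probe: float = PROBE_RADIUS
) -> dict[tuple[str, int, str], float]:
    """Per-residue absolute solvent-accessible surface area (A^2).

    All heavy atoms of the structure (including HETATM ligands, which
    genuinely bury residues) act as occluders; hydrogens are ignored.
    Residues with no heavy atoms map to ``nan``.
    """
    atoms: list[tuple[tuple[str, int, str], np.ndarray, float]] = []
    for res in structure.iter_residues():
        for atom in res.atoms.values():
            if atom.element in _HYDROGENS:
                continue
            radius = VDW_RADII.get(atom.element, _DEFAULT_RADIUS)
            atoms.append((res.key, atom.coord, radius))
    if not atoms:
        raise SasaError("structure has no heavy atoms")
    centers = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms]) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(centers)
    max_radius = radii.max()
    sasa: dict[tuple[str, int, str], float] = {res.key: 0.0 for res in structure.iter_residues()}
    counts: dict[tuple[str, int, str], int] = {k: 0 for k in sasa}
    for i, (key, center, _) in enumerate(atoms):
        r_i = radii[i]
        points = center + r_i * sphere
        neighbors = [j for j in tree.query_ball_point(center, r_i + max_radius) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            # (n_points, n_neighbors) distances; a point is accessible iff it
            # lies outside every neighbor's expanded sphere
            diff = points[:, None, :] - centers[nb][None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            accessible = np.all(dist2 >= (radii[nb] ** 2)[None, :], axis=1)
            n_acc = int(accessible.sum())
        else:
            n_acc = n_points
        area = 4.0 * np.pi * r_i * r_i * n_acc / n_points
        sasa[key] += area
        counts[key] += 1
    for key, n in counts.items():
        if n == 0:
            sasa[key] = float("nan")
    return sasa


def compute_rasa(
    structure: Structure,
    site: tuple[Residue, Residue, Residue],
    sasa: dict | None = None,
    n_points: int = 500,
) -> float:
    """Mean relative accessible surface area over the three triad residues.

    Per residue: SASA / Rost-Sander maximum for its amino-acid type.  The
    whole structure provides the occlusion context.
    """
    if sasa is None:
        sasa = compute_sasa(structure, n_points=n_points)
    values = []
    for res in site:
        maximum = ROST_SANDER_MAX.get(res.res_name)
        if maximum is None:
            raise SasaError(f"no Rost-Sander maximum for residue type {res.res_name}")
        values.append(sasa[res.key] / maximum)
    return float(np.mean(values))
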