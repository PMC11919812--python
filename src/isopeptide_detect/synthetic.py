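"""Parametric generator of synthetic test structures.

Everything the detector consumes can be generated here from standard bond
lengths and angles: PDB files with planted isopeptide-bond triads (ideal or
noised, exposed or buried under an occluding shell), decoy structures
guaranteed free of triad geometry, matching template libraries, reference
geometry distributions, and a complete evaluation corpus.  All generation
is deterministic given the seed.

The planted triads are built in internal coordinates (natural-extension
placement from tabulated bond lengths/angles), so the requested isopeptide
bond length and pseudo-dihedrals are reproduced exactly in the noise-free
limit.  Decoy chains are self-avoiding random walks dressed with standard
side chains and rejection-validated against the template library.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from ._geom import place_atom
from .matcher import SearchConfig, find_matches
from .structure_io import (
    Atom,
    Residue,
    Structure,
    TSV_COLUMNS,
    write_pdb,
)
from .templates import (
    ROLES,
    Template,
    TemplateAtom,
    TemplateLibrary,
    TRIAD_TYPES,
    save_library,
)

# Dihedral-distribution centers per topology: CnaA-like bonds are modeled
# trans about the isopeptide C-N bond, CnaB-like bonds cis.
TOPOLOGY_ANGLES = {
    "CnaA-like": {"phi": -120.0, "psi": 130.0, "omega": 180.0},
    "CnaB-like": {"phi": -75.0, "psi": 150.0, "omega": 0.0},
}
ANGLE_SD = {"phi": 12.0, "psi": 12.0, "omega": 8.0}
BOND_LENGTH_MEAN = 1.33   # Angstrom, amide C-N
BOND_LENGTH_SD = 0.05

TEMPLATE_ATOMS = {
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ASN": ("CB", "CG", "OD1"),
    "ASP_acceptor": ("CB", "CG", "OD1"),
    "ASP_catalytic": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
}

_AA_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_FLANK_POOL = "ACDEFGHIKLMNPQRSTVWY"
_DECOY_POOL = "AGSVTLKNDE"


class GenerationError(Exception):
    pass


def _wrap(angle: float) -> float:
    angle = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if angle == -180.0 else angle


@dataclasses.dataclass
class PlantSpec:
    """Parameters of one planted positive site."""

    triad_type: str = "Lys-Asn-Asp"
    topology: str = "CnaA-like"
    noise_sigma: float = 0.0       # Angstrom, isotropic per-atom
    bond_length: float = BOND_LENGTH_MEAN
    dihedrals: tuple[float, float, float] | None = None  # (phi, psi, omega), deg
    burial: str = "buried"         # "buried" | "exposed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.triad_type not in TRIAD_TYPES:
            raise GenerationError(f"unknown triad_type {self.triad_type!r}")
        if self.topology not in TOPOLOGY_ANGLES:
            raise GenerationError(f"unknown topology {self.topology!r}")
        if self.noise_sigma < 0 or self.bond_length <= 0:
            raise GenerationError("noise_sigma must be >= 0 and bond_length > 0")
        if self.burial not in ("buried", "exposed"):
            raise GenerationError(f"unknown burial mode {self.burial!r}")
        if self.dihedrals is None:
            c = TOPOLOGY_ANGLES[self.topology]
            self.dihedrals = (c["phi"], c["psi"], c["omega"])


# --- triad construction in internal coordinates -----------------------------

def build_triad_atoms(
    triad_type: str, bond_length: float, dihedrals: tuple[float, float, float]
) -> dict[str, dict[str, np.ndarray]]:
    """Atom coordinates of an idealized bonded triad.

    Returns a mapping role -> {atom_name -> coord}.  The cross-link chain
    CD-CE-NZ-C(acyl)-CB-CA reproduces the requested pseudo phi/omega/psi
    exactly; the catalytic carboxylate is placed with one oxygen at
    hydrogen-bond distance of NZ, as in the catalytic arrangement of the
    bond-forming machinery.
    """
    phi, psi, omega = (float(a) for a in dihedrals)
    lys_name, acc_name, cat_name = TRIAD_TYPES[triad_type]

    lys: dict[str, np.ndarray] = {}
    lys["N"] = np.array([0.0, 0.0, 0.0])
    lys["CA"] = np.array([1.458, 0.0, 0.0])
    a = np.radians(69.5)
    lys["CB"] = lys["CA"] + 1.53 * np.array([np.cos(a), np.sin(a), 0.0])
    lys["C"] = place_atom(lys["CB"], lys["N"], lys["CA"], 1.52, 111.0, -120.0)
    lys["O"] = place_atom(lys["N"], lys["CA"], lys["C"], 1.23, 120.5, 180.0)
    lys["CG"] = place_atom(lys["N"], lys["CA"], lys["CB"], 1.52, 114.0, 180.0)
    lys["CD"] = place_atom(lys["CA"], lys["CB"], lys["CG"], 1.52, 111.5, 180.0)
    lys["CE"] = place_atom(lys["CB"], lys["CG"], lys["CD"], 1.52, 111.5, 180.0)
    lys["NZ"] = place_atom(lys["CG"], lys["CD"], lys["CE"], 1.47, 112.0, 180.0)

    acc: dict[str, np.ndarray] = {}
    acyl = place_atom(lys["CD"], lys["CE"], lys["NZ"], bond_length, 122.0, phi)
    acc["CG"] = acyl
    acc["CB"] = place_atom(lys["CE"], lys["NZ"], acyl, 1.51, 116.0, omega)
    acc["OD1"] = place_atom(lys["CE"], lys["NZ"], acyl, 1.23, 121.0, _wrap(omega + 180.0))
    acc["CA"] = place_atom(lys["NZ"], acyl, acc["CB"], 1.53, 112.5, psi)
    acc["N"] = place_atom(acyl, acc["CB"], acc["CA"], 1.46, 110.0, -65.0)
    acc["C"] = place_atom(acyl, acc["CB"], acc["CA"], 1.52, 110.0, 175.0)
    acc["O"] = place_atom(acc["CB"], acc["CA"], acc["C"], 1.23, 120.5, 0.0)

    # catalytic carboxylate: OX1 hydrogen-bonded to NZ, rotated away from the
    # acceptor arm so the two never collide
    cat: dict[str, np.ndarray] = {}
    ox1 = place_atom(lys["CD"], lys["CE"], lys["NZ"], 2.9, 115.0, _wrap(phi + 120.0))
    c_acyl = place_atom(lys["CE"], lys["NZ"], ox1, 1.25, 118.0, 60.0)
    ox2 = place_atom(lys["NZ"], ox1, c_acyl, 1.25, 122.0, 150.0)
    c_prev = place_atom(lys["NZ"], ox1, c_acyl, 1.52, 118.0, -30.0)
    if cat_name == "ASP":
        cat["OD1"], cat["CG"], cat["OD2"], cat["CB"] = ox1, c_acyl, ox2, c_prev
        cat["CA"] = place_atom(ox1, c_acyl, c_prev, 1.53, 113.0, 175.0)
        cat["N"] = place_atom(c_acyl, c_prev, cat["CA"], 1.46, 110.0, -60.0)
        cat["C"] = place_atom(c_acyl, c_prev, cat["CA"], 1.52, 110.0, 60.0)
        cat["O"] = place_atom(c_prev, cat["CA"], cat["C"], 1.23, 120.5, 0.0)
    else:  # GLU
        cat["OE1"], cat["CD"], cat["OE2"], cat["CG"] = ox1, c_acyl, ox2, c_prev
        cat["CB"] = place_atom(ox1, c_acyl, cat["CG"], 1.52, 112.0, 180.0)
        cat["CA"] = place_atom(c_acyl, cat["CG"], cat["CB"], 1.53, 112.0, 180.0)
        cat["N"] = place_atom(cat["CG"], cat["CB"], cat["CA"], 1.46, 110.0, -60.0)
        cat["C"] = place_atom(cat["CG"], cat["CB"], cat["CA"], 1.52, 110.0, 60.0)
        cat["O"] = place_atom(cat["CB"], cat["CA"], cat["C"], 1.23, 120.5, 0.0)

    return {"bond_lys": lys, "catalytic": cat, "bond_acceptor": acc}


def _make_residue(
    chain_id: str, seq_id: int, res_name: str, coords: dict[str, np.ndarray]
) -> Residue:
    atoms = {
        name: Atom(name=name, element=name[0], coord=np.asarray(c, dtype=float))
        for name, c in coords.items()
    }
    return Residue(
        chain_id=chain_id, seq_id=seq_id, icode="", res_name=res_name, atoms=atoms
    )


# --- decoy chain machinery --------------------------------------------------

def _self_avoiding_walk(
    n: int,
    rng: np.random.Generator,
    start: np.ndarray,
    step: float = 3.8,
    min_sep: float = 4.0,
    forbidden: np.ndarray | None = None,
    forbidden_sep: float = 8.0,
) -> np.ndarray:
    """CA trace of a compact self-avoiding walk; restarts on dead ends."""
    for _ in range(200):
        pts = [np.asarray(start, dtype=float)]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        ok = True
        for _i in range(n - 1):
            for _try in range(60):
                cand_dir = direction + 0.9 * rng.standard_normal(3)
                cand_dir /= np.linalg.norm(cand_dir)
                cand = pts[-1] + step * cand_dir
                prev = np.array(pts[:-1]) if len(pts) > 1 else None
                if prev is not None and np.min(
                    np.linalg.norm(prev - cand, axis=1)
                ) < min_sep:
                    continue
                if forbidden is not None and np.min(
                    np.linalg.norm(forbidden - cand, axis=1)
                ) < forbidden_sep:
                    continue
                pts.append(cand)
                direction = cand_dir
                break
            else:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise GenerationError("self-avoiding walk: rejection budget exhausted")


_SIDE_CHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 111.0, "chi1")],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.52, 111.0, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.52, 111.0, "chi1+120")],
    "THR": [("OG1", ("N", "CA", "CB"), 1.42, 111.0, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.52, 111.0, "chi1+120")],
    "LEU": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.52, 111.0, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.52, 111.0, "chi2+120")],
    "LYS": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.5, "chi2"),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.5, "chi3"),
            ("NZ", ("CG", "CD", "CE"), 1.47, 112.0, "chi4")],
    "ASN": [("CG", ("N", "CA", "CB"), 1.52, 113.0, "chi1"),
            ("OD1", ("CA", "CB", "CG"), 1.23, 121.0, "chi2"),
            ("ND2", ("CA", "CB", "CG"), 1.33, 117.0, "chi2+180")],
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 113.0, "chi1"),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, "chi2"),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, "chi2+180")],
    "GLU": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("CD", ("CA", "CB", "CG"), 1.52, 113.0, "chi2"),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.0, "chi3"),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, "chi3+180")],
}
_ROTAMERS = np.array([-60.0, 60.0, 180.0])


def _dress_chain(
    ca_trace: np.ndarray,
    sequence: str,
    chain_id: str,
    seq_ids: list[int],
    rng: np.random.Generator,
    side_chains: bool = True,
) -> list[Residue]:
    """Backbone + (optionally) side chains around a CA trace."""
    residues = []
    n = len(ca_trace)
    for i, letter in enumerate(sequence):
        ca = ca_trace[i]
        d_next = ca_trace[i + 1] - ca if i + 1 < n else ca - ca_trace[i - 1]
        d_next = d_next / np.linalg.norm(d_next)
        d_prev = ca_trace[i - 1] - ca if i > 0 else -d_next
        d_prev = d_prev / np.linalg.norm(d_prev)
        perp = np.cross(d_next, d_prev)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d_next, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-6:
                perp = np.array([1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        coords: dict[str, np.ndarray] = {"CA": ca}
        coords["N"] = ca + 1.46 * _normalize(d_prev + 0.35 * perp)
        coords["C"] = ca + 1.52 * _normalize(d_next + 0.35 * perp)
        coords["O"] = coords["C"] + 1.23 * perp
        res_name = _AA_ONE_TO_THREE.get(letter, "ALA")
        if res_name != "GLY":
            bisector = -(d_prev + d_next)
            if np.linalg.norm(bisector) < 1e-6:
                bisector = perp
            coords["CB"] = ca + 1.53 * _normalize(_normalize(bisector) - 0.8 * perp)
        if side_chains and res_name in _SIDE_CHAINS:
            chis = {f"chi{k}": float(rng.choice(_ROTAMERS)) for k in range(1, 5)}
            for name, (pa, pb, pc), r, theta, tors in _SIDE_CHAINS[res_name]:
                base, _, offset = tors.partition("+")
                angle = chis[base] + (float(offset) if offset else 0.0)
                coords[name] = place_atom(
                    coords[pa], coords[pb], coords[pc], r, theta, _wrap(angle)
                )
        residues.append(_make_residue(chain_id, seq_ids[i], res_name, coords))
    return residues


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _burial_shell(
    triad_coords: np.ndarray,
    spacing: float = 2.2,
    inner: float = 2.5,
    outer: float = 5.5,
) -> Residue:
    """Close-packed carbon matrix burying the triad (single HETATM residue).

    Carbon occluders sit on a cubic lattice filling the shell between
    ``inner`` and ``outer`` Angstrom from the nearest triad atom, emulating
    the hydrophobic core packing around a real bond.  At 2.2 A spacing every
    probe-accessible point of the triad lies within a blocked region, so the
    residual triad rASA is near zero.
    """
    lo = triad_coords.min(axis=0) - outer
    hi = triad_coords.max(axis=0) + outer
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    from scipy.spatial import cKDTree

    dist, _ = cKDTree(triad_coords).query(grid)
    pts = grid[(dist >= inner) & (dist <= outer)]
    atoms = {
        f"C{i}": Atom(name=f"C{i}", element="C", coord=p) for i, p in enumerate(pts)
    }
    res = Residue(
        chain_id="Z", seq_id=9001, icode="", res_name="SHL", atoms=atoms,
        is_standard=False,
    )
    return res


# --- public generators ------------------------------------------------------

LYS_INDEX, CAT_INDEX, ACC_INDEX = 22, 24, 32  # triad slots in the 55-residue chain
_CHAIN_LENGTH = 55


def make_positive(spec: PlantSpec) -> tuple[Structure, dict]:
    """A structure with one planted isopeptide bond plus its ground truth.

    The triad occupies three slots of a 55-residue chain whose remaining
    residues are a backbone-only decoy walk placed well away from the site
    (so flank residues provide sequence context and bulk but cannot form
    spurious triads).  ``burial="buried"`` wraps the triad in a closed
    carbon shell; noise is applied i.i.d. to every atom afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    triad = build_triad_atoms(spec.triad_type, spec.bond_length, spec.dihedrals)
    lys_name, acc_name, cat_name = TRIAD_TYPES[spec.triad_type]
    triad_coords = np.vstack(
        [np.array(list(d.values())) for d in triad.values()]
    )
    center = triad_coords.mean(axis=0)

    n_flank = _CHAIN_LENGTH - 3
    flank_letters = "".join(rng.choice(list(_FLANK_POOL), size=n_flank))
    start = center + np.array([30.0, 0.0, 0.0])
    trace = _self_avoiding_walk(
        n_flank, rng, start, forbidden=triad_coords, forbidden_sep=16.0
    )
    flank_ids = [
        i + 1 for i in range(_CHAIN_LENGTH) if i not in (LYS_INDEX, CAT_INDEX, ACC_INDEX)
    ]
    flank_residues = _dress_chain(
        trace, flank_letters, "A", flank_ids, rng, side_chains=False
    )

    residues_by_id = {r.seq_id: r for r in flank_residues}
    residues_by_id[LYS_INDEX + 1] = _make_residue("A", LYS_INDEX + 1, lys_name, triad["bond_lys"])
    residues_by_id[CAT_INDEX + 1] = _make_residue("A", CAT_INDEX + 1, cat_name, triad["catalytic"])
    residues_by_id[ACC_INDEX + 1] = _make_residue("A", ACC_INDEX + 1, acc_name, triad["bond_acceptor"])
    chain_a = [residues_by_id[i] for i in sorted(residues_by_id)]

    chains: dict[str, list[Residue]] = {"A": chain_a}
    if spec.burial == "buried":
        chains["Z"] = [_burial_shell(triad_coords)]

    if spec.noise_sigma > 0:
        for residues in chains.values():
            for res in residues:
                for atom in res.atoms.values():
                    atom.coord = atom.coord + rng.normal(
                        0.0, spec.noise_sigma, size=3
                    )

    structure = Structure(
        id=f"planted_{spec.seed}", chains=chains, source_format="PDB"
    )
    truth = {
        "structure_id": structure.id,
        "chain": "A",
        "r1_bond": LYS_INDEX + 1,
        "r_cat": CAT_INDEX + 1,
        "r2_bond": ACC_INDEX + 1,
        "r1_bond_name": lys_name,
        "r_cat_name": cat_name,
        "r2_bond_name": acc_name,
        "type": spec.topology,
        "template": "",
    }
    return structure, truth


def make_negative(
    n_residues: int,
    seed: int,
    library: TemplateLibrary | None = None,
    config: SearchConfig | None = None,
) -> Structure:
    """A decoy structure guaranteed (by rejection) to contain no triad
    matching any template of ``library`` at the given search settings."""
    if n_residues < 20:
        raise GenerationError("decoys need n_residues >= 20")
    if library is None:
        library = default_template_library()
    config = config or SearchConfig()
    for attempt in range(20):
        rng = np.random.default_rng(seed + 100_000 * attempt)
        trace = _self_avoiding_walk(n_residues, rng, np.zeros(3))
        letters = "".join(rng.choice(list(_DECOY_POOL), size=n_residues))
        residues = _dress_chain(
            trace, letters, "A", list(range(1, n_residues + 1)), rng, side_chains=True
        )
        structure = Structure(id=f"decoy_{seed}", chains={"A": residues})
        if not find_matches(structure, library, config):
            return structure
    raise GenerationError("decoy rejection budget exhausted")


# --- template library and geometry reference --------------------------------

def _template_from_triad(
    tid: str, triad_type: str, topology: str, flank: str
) -> Template:
    coords = build_triad_atoms(
        triad_type,
        BOND_LENGTH_MEAN,
        tuple(TOPOLOGY_ANGLES[topology][k] for k in ("phi", "psi", "omega")),
    )
    lys_name, acc_name, cat_name = TRIAD_TYPES[triad_type]
    names = {
        "bond_lys": ("LYS", TEMPLATE_ATOMS["LYS"]),
        "bond_acceptor": (acc_name, TEMPLATE_ATOMS[
            "ASP_acceptor" if acc_name == "ASP" else acc_name
        ]),
        "catalytic": (cat_name, TEMPLATE_ATOMS[
            "ASP_catalytic" if cat_name == "ASP" else cat_name
        ]),
    }
    atoms = []
    for role in ROLES:
        res_name, atom_names = names[role]
        for atom_name in atom_names:
            atoms.append(
                TemplateAtom(
                    residue_role=role,
                    res_name=res_name,
                    atom_name=atom_name,
                    coord=coords[role][atom_name],
                )
            )
    return Template(
        id=tid, topology=topology, triad_type=triad_type, atoms=atoms,
        flank_sequence=flank,
    )


def default_template_library(seed: int = 7101) -> TemplateLibrary:
    """Six ideal-geometry templates: 2 topologies x 3 triad types.

    Flank sequences are random draws standing in for the template parents'
    real sequence context; they are what the identity-exclusion rule aligns
    against.
    """
    rng = np.random.default_rng(seed)
    templates = []
    for topology in TOPOLOGY_ANGLES:
        for triad_type in TRIAD_TYPES:
            short = {"Lys-Asn-Asp": "knd", "Lys-Asp-Glu": "kde",
                     "Lys-Asn-Glu": "kne"}[triad_type]
            tid = f"t-{topology.split('-')[0].lower()}-{short}"
            flank = "".join(rng.choice(list(_FLANK_POOL), size=43))
            templates.append(_template_from_triad(tid, triad_type, topology, flank))
    return TemplateLibrary(templates=templates, version="synthetic-1")


def sample_reference_geometries(
    n_per_topology: int = 500, seed: int = 7201
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Reference bond lengths and per-topology (phi, psi, omega) samples.

    Angles are drawn from per-topology normal distributions (wrapped into
    (-180, 180]); bond lengths from N(1.33, 0.05) Angstrom.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.normal(BOND_LENGTH_MEAN, BOND_LENGTH_SD, size=2 * n_per_topology)
    samples = {}
    for topology, centers in TOPOLOGY_ANGLES.items():
        cols = []
        for name in ("phi", "psi", "omega"):
            draw = rng.normal(centers[name], ANGLE_SD[name], size=n_per_topology)
            cols.append(np.array([_wrap(a) for a in draw]))
        samples[topology] = np.column_stack(cols)
    return lengths, samples


def write_reference_file(
    path: str | Path, n_per_topology: int = 500, seed: int = 7201
) -> None:
    lengths, samples = sample_reference_geometries(n_per_topology, seed)
    lines = ["\t".join(["topology", "phi", "psi", "omega", "bond_length"])]
    i = 0
    for topology in TOPOLOGY_ANGLES:
        for row in samples[topology]:
            lines.append(
                f"{topology}\t{row[0]:.4f}\t{row[1]:.4f}\t{row[2]:.4f}"
                f"\t{lengths[i]:.4f}"
            )
            i += 1
    Path(path).write_text("\n".join(lines) + "\n")


def sample_plant_spec(
    rng: np.random.Generator, noise_sigma: float, seed: int
) -> PlantSpec:
    """Draw one positive-site specification from the reference distributions."""
    topology = ("CnaA-like", "CnaB-like")[int(rng.integers(2))]
    triad_type = list(TRIAD_TYPES)[int(rng.integers(3))]
    centers = TOPOLOGY_ANGLES[topology]
    dihedrals = tuple(
        _wrap(rng.normal(centers[k], ANGLE_SD[k])) for k in ("phi", "psi", "omega")
    )
    length = float(rng.normal(BOND_LENGTH_MEAN, BOND_LENGTH_SD))
    return PlantSpec(
        triad_type=triad_type,
        topology=topology,
        noise_sigma=noise_sigma,
        bond_length=length,
        dihedrals=dihedrals,
        burial="buried",
        seed=seed,
    )


def make_corpus(
    out_dir: str | Path,
    n_pos: int = 20,
    n_neg: int = 50,
    seed: int = 42,
    noise_sigma: float = 0.2,
    n_neg_residues: int = 60,
) -> Path:
    """A self-consistent evaluation corpus on disk.

    Layout: ``structures/`` with PDB files, ``truth.tsv`` mirroring the
    prediction-table schema, ``templates/`` with the library, and
    ``geometry_ref.tsv`` with the reference distributions.
    """
    if n_pos < 1 or n_neg < 1:
        raise GenerationError("corpus needs n_pos, n_neg >= 1")
    out_dir = Path(out_dir)
    struct_dir = out_dir / "structures"
    struct_dir.mkdir(parents=True, exist_ok=True)
    library = default_template_library()
    save_library(library, out_dir / "templates")
    write_reference_file(out_dir / "geometry_ref.tsv")

    rng = np.random.default_rng(seed)
    truth_rows = []
    for i in range(n_pos):
        spec = sample_plant_spec(rng, noise_sigma, seed=seed + 1000 + i)
        structure, truth = make_positive(spec)
        structure.id = f"pos_{i:03d}"
        truth["structure_id"] = structure.id
        write_pdb(structure, struct_dir / f"{structure.id}.pdb")
        truth_rows.append(truth)
    for i in range(n_neg):
        structure = make_negative(n_neg_residues, seed=seed + 5000 + i, library=library)
        structure.id = f"neg_{i:03d}"
        write_pdb(structure, struct_dir / f"{structure.id}.pdb")

    lines = ["\t".join(TSV_COLUMNS)]
    for row in truth_rows:
        lines.append(
            "\t".join(str(row.get(col, "NA")) for col in TSV_COLUMNS)
        )
    (out_dir / "truth.tsv").write_text("\n".join(lines) + "\n")
    return out_dir


def simulate_training_features(
    n_per_class: int = 500, seed: int = 2024
) -> tuple[list, list]:
    """Feature draws emulating matched-site statistics for model fitting.

    Positives: low RMSD, strongly buried; negatives: high RMSD, partly
    exposed.  Values are clipped at zero to respect feature domains.
    """
    from .features import SiteFeatures

    rng = np.random.default_rng(seed)
    pos = [
        SiteFeatures(
            rmsd=max(0.0, rng.normal(0.3, 0.1)),
            r_asa=max(0.0, rng.normal(0.1, 0.05)),
        )
        for _ in range(n_per_class)
    ]
    neg = [
        SiteFeatures(
            rmsd=max(0.0, rng.normal(1.5, 0.2)),
            r_asa=max(0.0, rng.normal(0.5, 0.1)),
        )
        for _ in range(n_per_class)
    ]
    return pos, neg
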