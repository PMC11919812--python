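"""Triad template library: on-disk format, loading, validation, flank identity.

A template is the set of labeled side-chain atoms of one isopeptide-bond
triad (bond-forming Lys, catalytic Asp/Glu, bond-accepting Asn/Asp), stored
as a PDB-fragment file so it stays viewable in molecular viewers.  The
residue role is encoded in the chain id (A = bond_lys, B = catalytic,
C = bond_acceptor) and a leading ``REMARK 400 ISOPEP`` line carries the
metadata sidecar (topology, triad type, flank sequence).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal, get_sequence_identity

ROLES = ("bond_lys", "catalytic", "bond_acceptor")
_CHAIN_TO_ROLE = {"A": "bond_lys", "B": "catalytic", "C": "bond_acceptor"}
_ROLE_TO_CHAIN = {v: k for k, v in _CHAIN_TO_ROLE.items()}

TRIAD_TYPES = {
    # triad_type -> (bond_lys, bond_acceptor, catalytic) residue names
    "Lys-Asn-Asp": ("LYS", "ASN", "ASP"),
    "Lys-Asp-Glu": ("LYS", "ASP", "GLU"),
    "Lys-Asn-Glu": ("LYS", "ASN", "GLU"),
}
TOPOLOGIES = ("CnaA-like", "CnaB-like")


class TemplateError(Exception):
    pass


@dataclasses.dataclass
class TemplateAtom:
    residue_role: str
    res_name: str
    atom_name: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise TemplateError(f"atom {self.atom_name}: non-finite coordinates")


@dataclasses.dataclass
class Template:
    id: str
    topology: str
    triad_type: str
    atoms: list[TemplateAtom]
    flank_sequence: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise TemplateError(f"{self.id}: unknown topology {self.topology!r}")
        if self.triad_type not in TRIAD_TYPES:
            raise TemplateError(f"{self.id}: unknown triad_type {self.triad_type!r}")
        roles = {a.residue_role for a in self.atoms}
        if roles != set(ROLES):
            raise TemplateError(
                f"{self.id}: roles {sorted(roles)} != expected {sorted(ROLES)}"
            )
        lys, acc, cat = TRIAD_TYPES[self.triad_type]
        expected = {"bond_lys": lys, "bond_acceptor": acc, "catalytic": cat}
        for atom in self.atoms:
            if atom.res_name != expected[atom.residue_role]:
                raise TemplateError(
                    f"{self.id}: residue {atom.res_name} in role {atom.residue_role} "
                    f"contradicts triad_type {self.triad_type}"
                )

    def role_atoms(self, role: str) -> list[TemplateAtom]:
        return [a for a in self.atoms if a.residue_role == role]

    def res_name(self, role: str) -> str:
        lys, acc, cat = TRIAD_TYPES[self.triad_type]
        return {"bond_lys": lys, "bond_acceptor": acc, "catalytic": cat}[role]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclasses.dataclass
class TemplateLibrary:
    templates: list[Template]
    version: str = "synthetic-1"

    def __post_init__(self) -> None:
        if not self.templates:
            raise TemplateError("template library is empty")
        ids = [t.id for t in self.templates]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TemplateError(f"duplicate template ids: {dupes}")

    def __iter__(self):
        return iter(self.templates)

    def __len__(self) -> int:
        return len(self.templates)


def _parse_template_file(path: Path) -> Template:
    topology = triad_type = flank = tid = None
    atoms: list[TemplateAtom] = []
    for line in path.read_text().splitlines():
        if line.startswith("REMARK 400 ISOPEP"):
            for token in line.split()[3:]:
                key, _, value = token.partition("=")
                if key == "topology":
                    topology = value
                elif key == "triad_type":
                    triad_type = value
                elif key == "flank":
                    flank = value
                elif key == "id":
                    tid = value
        elif line.startswith(("ATOM", "HETATM")):
            chain = line[21]
            role = _CHAIN_TO_ROLE.get(chain)
            if role is None:
                raise TemplateError(f"{path.name}: unknown residue role chain {chain!r}")
            atoms.append(
                TemplateAtom(
                    residue_role=role,
                    res_name=line[17:20].strip(),
                    atom_name=line[12:16].strip(),
                    coord=np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    ),
                )
            )
    if topology is None or triad_type is None or flank is None:
        raise TemplateError(f"{path.name}: missing ISOPEP metadata line")
    return Template(
        id=tid or path.stem,
        topology=topology,
        triad_type=triad_type,
        atoms=atoms,
        flank_sequence=flank,
    )


def load_library(dir_path: str | Path) -> TemplateLibrary:
    """Load all ``*.pdb`` template fragments from a directory.

    Loading is atomic: every malformed file is reported (by name) and the
    whole load fails rather than silently skipping templates.
    """
    dir_path = Path(dir_path)
    files = sorted(dir_path.glob("*.pdb"))
    if not files:
        raise TemplateError(f"no template files in {dir_path}")
    templates: list[Template] = []
    errors: list[str] = []
    for f in files:
        try:
            templates.append(_parse_template_file(f))
        except (TemplateError, ValueError, IndexError) as exc:
            errors.append(f"{f.name}: {exc}")
    if errors:
        raise TemplateError("invalid template files:\n" + "\n".join(errors))
    version_file = dir_path / "VERSION"
    version = version_file.read_text().strip() if version_file.exists() else "unversioned"
    return TemplateLibrary(templates=templates, version=version)


def save_library(library: TemplateLibrary, dir_path: str | Path) -> None:
    """Write each template as a PDB fragment; inverse of :func:`load_library`."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    (dir_path / "VERSION").write_text(library.version + "\n")
    for t in library:
        lines = [
            f"REMARK 400 ISOPEP id={t.id} topology={t.topology} "
            f"triad_type={t.triad_type} flank={t.flank_sequence}"
        ]
        serial = 1
        for role in ROLES:
            chain = _ROLE_TO_CHAIN[role]
            seq = {"bond_lys": 1, "catalytic": 2, "bond_acceptor": 3}[role]
            for atom in t.role_atoms(role):
                x, y, z = atom.coord
                name = atom.atom_name
                field = f" {name:<3s}" if len(name) < 4 else name
                element = name[0]
                lines.append(
                    f"ATOM  {serial:>5d} {field:<4s}{'':1s}{atom.res_name:>3s} "
                    f"{chain:1s}{seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {element:>2s}"
                )
                serial += 1
        lines.append("END")
        (dir_path / f"{t.id}.pdb").write_text("\n".join(lines) + "\n")


# --- flank sequence identity ------------------------------------------------

_MATRIX = SubstitutionMatrix.std_protein_matrix()  # BLOSUM62


def _as_protein_seq(seq: str) -> ProteinSequence:
    alphabet = ProteinSequence.alphabet
    cleaned = "".join(c if c in alphabet else "X" for c in seq.upper())
    return ProteinSequence(cleaned)


def flank_identity(a: str, b: str) -> float:
    """Percent identity between two flank sequences, in [0, 100].

    Optimal global alignment without end-gap penalties (BLOSUM62, gap open
    10 / extend 1); identity = identical aligned positions / alignment
    length x 100.
    """
    if not a or not b:
        raise ValueError("flank sequences must be non-empty")
    alignment = align_optimal(
        _as_protein_seq(a),
        _as_protein_seq(b),
        _MATRIX,
        gap_penalty=(-10, -1),
        terminal_penalty=False,
    )[0]
    return float(get_sequence_identity(alignment, mode="all") * 100.0)
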